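"""The OCR head's tensor algebra against explicit per-pixel loops, and
the assembled segmenter's ablation/equivalence contracts."""

import numpy as np
import pytest

from rootseg.backbone import BackboneConfig, PixelRepresentationMap
from rootseg.errors import ShapeError
from rootseg.nn import autograd as ag
from rootseg.ocr import (ModelConfig, OCRHead, RootSegmenter,
                         aggregate_context, baseline_ocr_forward,
                         improved_ocr_forward, normalize_regions,
                         region_representations, relation_weights)


class TestNormalizeRegions:
    def test_constant_logits_give_uniform_weights(self):
        logits = np.zeros((1, 2, 4, 4), np.float32)
        m = normalize_regions(logits).data
        assert np.allclose(m, 1.0 / 16)

    def test_two_pixel_softmax_arithmetic(self):
        logits = np.array([[[[0.0, np.log(3.0)]]]], np.float32)  # (1,1,1,2)
        m = normalize_regions(logits).data
        assert np.allclose(m.ravel(), [0.25, 0.75], atol=1e-6)

    def test_dominant_logit_concentrates_weight(self):
        logits = np.zeros((1, 1, 1, 4), np.float32)
        logits[0, 0, 0, 2] = 50.0
        m = normalize_regions(logits).data
        assert m[0, 0, 0, 2] > 0.999

    def test_each_region_slice_sums_to_one(self, rng):
        logits = rng.normal(size=(2, 3, 5, 5)).astype(np.float32)
        m = normalize_regions(logits).data
        assert np.allclose(m.sum(axis=(2, 3)), 1.0, atol=1e-5)


class TestRegionRepresentations:
    def test_one_hot_weights_pick_single_pixel(self, rng):
        x = rng.normal(size=(1, 3, 2, 2)).astype(np.float32)
        m = np.zeros((1, 2, 2, 2), np.float32)
        m[0, 0, 1, 0] = 1.0
        m[0, 1, 0, 1] = 1.0
        f = region_representations(x, m).data
        assert np.allclose(f[0, 0], x[0, :, 1, 0], atol=1e-6)
        assert np.allclose(f[0, 1], x[0, :, 0, 1], atol=1e-6)

    def test_uniform_weights_give_spatial_mean(self, rng):
        x = rng.normal(size=(2, 4, 3, 3)).astype(np.float32)
        m = np.full((2, 2, 3, 3), 1.0 / 9, np.float32)
        f = region_representations(x, m).data
        assert np.allclose(f, x.mean(axis=(2, 3))[:, None, :], atol=1e-6)

    def test_hand_weighted_sum_two_pixels(self):
        x = np.array([[[[1.0, 0.0]], [[0.0, 2.0]]]], np.float32)  # (1,2,1,2)
        m = np.array([[[[0.25, 0.75]]]], np.float32)              # (1,1,1,2)
        f = region_representations(x, m).data
        assert np.allclose(f[0, 0], [0.25, 1.5], atol=1e-6)

    def test_spatial_mismatch_raises(self, rng):
        with pytest.raises(ShapeError):
            region_representations(np.zeros((1, 3, 2, 2), np.float32),
                                   np.zeros((1, 2, 3, 3), np.float32))


class TestRelationWeights:
    def test_identical_scores_give_uniform_relation(self):
        q = np.ones((1, 4, 3), np.float32)
        r = np.ones((1, 2, 3), np.float32)
        w = relation_weights(q, r).data
        assert np.allclose(w, 0.5, atol=1e-6)

    def test_softmax_of_one_three(self):
        q = np.array([[[1.0]]], np.float32)        # (1,1,1)
        r = np.array([[[1.0], [3.0]]], np.float32)  # (1,2,1)
        w = relation_weights(q, r).data
        assert np.allclose(w[0, 0], [0.11920292, 0.88079708], atol=1e-6)

    def test_rows_sum_to_one(self, rng):
        q = rng.normal(size=(2, 9, 4)).astype(np.float32)
        r = rng.normal(size=(2, 3, 4)).astype(np.float32)
        w = relation_weights(q, r).data
        assert np.allclose(w.sum(axis=2), 1.0, atol=1e-5)
        assert (w >= 0).all() and (w <= 1).all()


class TestAggregateContext:
    def test_one_hot_relation_selects_region_vector(self):
        w = np.array([[[0.0, 1.0], [1.0, 0.0]]], np.float32)
        f = np.array([[[1.0, 1.0], [3.0, 5.0]]], np.float32)
        y = aggregate_context(w, f).data
        assert np.allclose(y[0, 0], [3.0, 5.0], atol=1e-6)
        assert np.allclose(y[0, 1], [1.0, 1.0], atol=1e-6)

    def test_hand_arithmetic_convex_mix(self):
        w = np.array([[[0.3, 0.7]]], np.float32)
        f = np.array([[[1.0, 1.0], [3.0, 5.0]]], np.float32)
        y = aggregate_context(w, f).data
        assert np.allclose(y[0, 0], [2.4, 3.8], atol=1e-6)

    def test_single_region_collapse_is_constant_over_pixels(self, rng):
        w = np.ones((1, 6, 1), np.float32)
        f = rng.normal(size=(1, 1, 4)).astype(np.float32)
        y = aggregate_context(w, f).data
        assert np.allclose(y, np.broadcast_to(f[0, 0], (1, 6, 4)), atol=1e-6)


class TestLoopOracles:
    """Explicit triple loops over pixels/regions on tiny tensors."""

    def test_region_representation_matches_loop(self, rng):
        b, d, h, w, k = 2, 4, 3, 3, 2
        x = rng.normal(size=(b, d, h, w)).astype(np.float32)
        logits = rng.normal(size=(b, k, h, w)).astype(np.float32)
        m = normalize_regions(logits).data
        f = region_representations(x, m).data
        for bi in range(b):
            for ki in range(k):
                ref = np.zeros(d)
                for i in range(h):
                    for j in range(w):
                        ref += m[bi, ki, i, j] * x[bi, :, i, j]
                assert np.abs(f[bi, ki] - ref).max() < 1e-5

    def test_relation_and_context_match_loop(self, rng):
        """Identity transforms: w_ik = softmax_k(x_i . f_k), y_i = sum w f."""
        b, d, h, w_, k = 2, 4, 3, 3, 2
        x = rng.normal(size=(b, d, h, w_)).astype(np.float32)
        f = rng.normal(size=(b, k, d)).astype(np.float32)
        q = x.reshape(b, d, h * w_).transpose(0, 2, 1)
        wts = relation_weights(q, f).data
        y = aggregate_context(wts, f).data
        for bi in range(b):
            for i in range(h * w_):
                scores = np.array([q[bi, i] @ f[bi, kk] for kk in range(k)])
                e = np.exp(scores - scores.max())
                ref_w = e / e.sum()
                assert np.abs(wts[bi, i] - ref_w).max() < 1e-5
                ref_y = sum(ref_w[kk] * f[bi, kk] for kk in range(k))
                assert np.abs(y[bi, i] - ref_y).max() < 1e-5

    def test_region_representation_permutation_equivariance(self, rng):
        """Permuting pixels in x and m~ together leaves f unchanged."""
        b, d, h, w, k = 1, 4, 3, 3, 2
        x = rng.normal(size=(b, d, h * w)).astype(np.float32)
        m = rng.random((b, k, h * w)).astype(np.float32)
        m /= m.sum(axis=2, keepdims=True)
        perm = rng.permutation(h * w)
        f1 = region_representations(x.reshape(b, d, h, w),
                                    m.reshape(b, k, h, w)).data
        f2 = region_representations(x[:, :, perm].reshape(b, d, h, w),
                                    m[:, :, perm].reshape(b, k, h, w)).data
        assert np.abs(f1 - f2).max() < 1e-6


@pytest.fixture(scope="module")
def head():
    cfg = ModelConfig(pixel_width=32, key_width=16, context_width=16,
                      fused_width=32)
    return OCRHead(in_channels=120, cfg=cfg, seed=4)


class TestHead:

    def _features(self, rng, b=1, hw=8):
        t = ag.Tensor(rng.normal(size=(b, 120, hw, hw)).astype(np.float32))
        return PixelRepresentationMap(tensor=t, input_hw=(hw * 4, hw * 4))

    def test_input_transform_projects_to_pixel_width(self, head, rng):
        x = head.input_transform(self._features(rng))
        assert x.shape == (1, 32, 8, 8)
        assert np.isfinite(x.data).all()

    def test_input_transform_rejects_wrong_channels(self, head):
        bad = PixelRepresentationMap(
            tensor=ag.Tensor(np.zeros((1, 64, 8, 8), np.float32)),
            input_hw=(32, 32))
        with pytest.raises(ShapeError):
            head.input_transform(bad)

    def test_aux_head_channel_count_follows_num_classes(self, rng):
        for k in (2, 3):
            cfg = ModelConfig(num_classes=k, pixel_width=32, key_width=16,
                              context_width=16, fused_width=32)
            head = OCRHead(120, cfg, seed=0)
            aux = head.aux_head(self._features(rng))
            assert aux.shape == (1, k, 8, 8)

    def test_classify_and_upsample_shape_and_factor(self, head, rng):
        z = ag.Tensor(rng.normal(size=(1, 32, 8, 8)).astype(np.float32))
        out = head.classify_and_upsample(z, (32, 32))
        assert out.shape == (1, 2, 32, 32)
        with pytest.raises(ShapeError, match="multiple"):
            head.classify_and_upsample(z, (30, 30))

    def test_constant_input_yields_constant_upsampled_logits(self, head):
        z = ag.Tensor(np.ones((1, 32, 8, 8), np.float32))
        out = head.classify_and_upsample(z, (32, 32)).data
        for c in range(2):
            assert np.allclose(out[0, c], out[0, c, 0, 0], atol=1e-5)


class TestAssembledModel:
    def test_full_pipeline_smoke_binary_outputs(self, tiny_model):
        x = np.random.default_rng(0).random((1, 3, 64, 64), dtype=np.float32)
        out = tiny_model(x)
        assert out.aux_logits.shape == (1, 2, 64, 64)
        assert out.final_logits.shape == (1, 2, 64, 64)
        assert np.isfinite(out.final_logits.data).all()

    def test_clamped_gates_reproduce_baseline_bitwise(self, tiny_model):
        tiny_model.eval()
        x = np.random.default_rng(1).random((1, 3, 64, 64), dtype=np.float32)
        feats = tiny_model.backbone(x)
        tiny_model.gam.clamp_gates_to_one = True
        try:
            clamped = improved_ocr_forward(tiny_model, feats)
        finally:
            tiny_model.gam.clamp_gates_to_one = False
        base = baseline_ocr_forward(tiny_model, feats)
        assert np.array_equal(clamped.final_logits.data,
                              base.final_logits.data)
        assert np.array_equal(clamped.aux_logits.data, base.aux_logits.data)

    def test_improved_and_baseline_differ_with_open_gates(self, tiny_model):
        tiny_model.eval()
        x = np.random.default_rng(2).random((1, 3, 64, 64), dtype=np.float32)
        feats = tiny_model.backbone(x)
        imp = improved_ocr_forward(tiny_model, feats)
        base = baseline_ocr_forward(tiny_model, feats)
        assert not np.allclose(imp.final_logits.data, base.final_logits.data)

    def test_parameter_census_baseline_plus_gam(self):
        bcfg = BackboneConfig(base_width=8, stage1_width=16)
        mcfg = dict(pixel_width=32, key_width=16, context_width=16,
                    fused_width=32)
        with_gam = RootSegmenter(bcfg, ModelConfig(**mcfg), seed=0)
        without = RootSegmenter(bcfg, ModelConfig(gam_enabled=False, **mcfg),
                                seed=0)
        gam_params = sum(p.data.size for p in with_gam.gam.parameters())
        assert (with_gam.num_parameters()
                == without.num_parameters() + gam_params)
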