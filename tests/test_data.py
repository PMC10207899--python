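"""Annotation I/O, augmentation, splitting and tiled inference."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootseg.data import (AugmentationSpec, RootSample, augment_sample,
                          build_dataset, read_labelme, read_mask_png,
                          read_dataset_dir, split_dataset, tiled_predict,
                          write_dataset_dir, write_mask_png)
from rootseg.errors import DataError


def _labelme_doc(shapes, h=100, w=100):
    return {"imageHeight": h, "imageWidth": w, "shapes": shapes}


def _square(x0, y0, size):
    return {"label": "root", "points": [[x0, y0], [x0 + size, y0],
                                        [x0 + size, y0 + size],
                                        [x0, y0 + size]]}


def _sample(rng, h=40, w=40, i=0):
    img = rng.integers(0, 256, (h, w, 3), dtype=np.uint8)
    mask = (rng.random((h, w)) < 0.2).astype(np.uint8)
    return RootSample(image=img, mask=mask, id=f"img{i}")


class TestLabelme:
    def test_square_polygon_area(self, tmp_path):
        p = tmp_path / "a.json"
        p.write_text(json.dumps(_labelme_doc([_square(10, 10, 10)])))
        mask = read_labelme(p)
        assert mask.shape == (100, 100)
        # boundary convention gives area within one pixel ring of 10x10
        assert 81 <= mask.sum() <= 121
        assert mask[15, 15] == 1 and mask[50, 50] == 0

    def test_empty_shape_list_gives_zero_mask(self, tmp_path):
        p = tmp_path / "b.json"
        p.write_text(json.dumps(_labelme_doc([])))
        assert read_labelme(p).sum() == 0

    def test_disjoint_polygons_union_areas(self, tmp_path):
        p = tmp_path / "c.json"
        p.write_text(json.dumps(_labelme_doc(
            [_square(5, 5, 10), _square(60, 60, 10)])))
        mask = read_labelme(p)
        one = read_labelme_area(tmp_path, _square(5, 5, 10))
        assert mask.sum() == 2 * one

    def test_unknown_label_skipped_with_warning(self, tmp_path):
        p = tmp_path / "d.json"
        shape = dict(_square(10, 10, 10), label="worm")
        p.write_text(json.dumps(_labelme_doc([shape])))
        with pytest.warns(UserWarning, match="worm"):
            mask = read_labelme(p)
        assert mask.sum() == 0

    def test_malformed_json_raises_data_error(self, tmp_path):
        p = tmp_path / "e.json"
        p.write_text("{not json")
        with pytest.raises(DataError):
            read_labelme(p)


def read_labelme_area(tmp_path, shape):
    p = tmp_path / "single.json"
    p.write_text(json.dumps(_labelme_doc([shape])))
    return read_labelme(p).sum()


class TestMaskPng:
    def test_round_trip_identity(self, tmp_path, rng):
        mask = (rng.random((30, 20)) < 0.3).astype(np.uint8)
        path = tmp_path / "m.png"
        write_mask_png(path, mask)
        assert np.array_equal(read_mask_png(path), mask)

    def test_all_black_reads_as_zero(self, tmp_path):
        path = tmp_path / "z.png"
        write_mask_png(path, np.zeros((5, 5), np.uint8))
        assert read_mask_png(path).sum() == 0

    def test_foreign_colors_rejected(self, tmp_path):
        from PIL import Image
        path = tmp_path / "bad.png"
        Image.fromarray(np.full((4, 4, 3), 17, np.uint8)).save(path)
        with pytest.raises(DataError, match="colors"):
            read_mask_png(path)


class TestAugmentation:
    def test_exactly_five_variants_with_tagged_provenance(self, rng):
        variants = augment_sample(_sample(rng), rng=rng)
        assert len(variants) == 5
        assert {v.provenance for v in variants} == {
            "luminance_up", "luminance_down", "scale_up", "scale_down",
            "salt_pepper"}

    def test_photometric_variants_keep_mask_bitwise(self, rng):
        s = _sample(rng)
        for v in augment_sample(s, rng=rng):
            if v.provenance in ("luminance_up", "luminance_down",
                                "salt_pepper"):
                assert np.array_equal(v.mask, s.mask)

    def test_scale_variant_dims_and_area_fraction(self, rng):
        s = _sample(rng, h=50, w=40)
        spec = AugmentationSpec()
        for v in augment_sample(s, spec, rng):
            if v.provenance == "scale_up":
                assert v.mask.shape == (60, 48)
            if v.provenance == "scale_down":
                assert v.mask.shape == (40, 32)
            if v.provenance.startswith("scale"):
                assert v.image.shape[:2] == v.mask.shape
                assert v.mask.mean() == pytest.approx(s.mask.mean(),
                                                      abs=0.02)

    def test_luminance_scales_pixel_values(self, rng):
        s = _sample(rng)
        up = augment_sample(s, rng=rng)[0]
        expected = np.clip(np.round(s.image * 1.2), 0, 255).astype(np.uint8)
        assert np.array_equal(up.image, expected)

    def test_salt_pepper_hits_close_to_density(self, rng):
        s = _sample(rng, h=200, w=200)
        sp = [v for v in augment_sample(s, rng=rng)
              if v.provenance == "salt_pepper"][0]
        changed = (sp.image != s.image).any(axis=-1).mean()
        assert 0.01 < changed < 0.03  # density 0.02 +- sampling noise


class TestBuildDataset:
    @pytest.mark.parametrize("n,expected", [(1, 6), (10, 60)])
    def test_sixfold_expansion(self, rng, n, expected):
        originals = [_sample(rng, i=i) for i in range(n)]
        assert len(build_dataset(originals)) == expected

    def test_duplicate_ids_rejected(self, rng):
        s = _sample(rng)
        with pytest.raises(DataError, match="duplicate"):
            build_dataset([s, s])


class TestSplit:
    def _groups(self, rng, n):
        return build_dataset([_sample(rng, h=16, w=16, i=i)
                              for i in range(n)])

    def test_92_groups_reproduce_printed_partition(self, rng):
        dataset = self._groups(rng, 92)
        sp = split_dataset(dataset, seed=3)
        assert (len(sp.train), len(sp.val), len(sp.test)) == (330, 111, 111)

    def test_10_groups_example(self, rng):
        sp = split_dataset(self._groups(rng, 10), seed=0)
        assert (len(sp.train), len(sp.val), len(sp.test)) == (36, 12, 12)

    def test_same_seed_reproduces_split(self, rng):
        dataset = self._groups(rng, 8)
        a = split_dataset(dataset, seed=11)
        b = split_dataset(dataset, seed=11)
        assert a == b

    @given(st.integers(3, 60))
    @settings(max_examples=12, deadline=None)
    def test_partition_properties_over_group_counts(self, n):
        rng = np.random.default_rng(n)
        dataset = build_dataset([_sample(rng, h=8, w=8, i=i)
                                 for i in range(n)])
        sp = split_dataset(dataset, seed=n)
        train, val, test = set(sp.train), set(sp.val), set(sp.test)
        assert not (train & val or train & test or val & test)
        assert train | val | test == {s.id for s in dataset}
        by_id = {s.id: s.group_id for s in dataset}
        train_groups = {by_id[i] for i in train}
        eval_groups = {by_id[i] for i in val | test}
        assert not train_groups & eval_groups

    def test_too_few_groups_rejected(self, rng):
        with pytest.raises(DataError, match="3 groups"):
            split_dataset(self._groups(rng, 2))


class _ConstantLogitModel:
    """Stub: background logit 0, root logit +1 everywhere."""

    def eval(self):
        return self

    def __call__(self, x):
        b, _, h, w = x.shape
        logits = np.zeros((b, 2, h, w), np.float32)
        logits[:, 1] = 1.0
        from rootseg.nn.autograd import Tensor
        return Tensor(logits)


class _CoordModel:
    """Stub emitting a constant; counts how many tiles it was fed."""

    def __init__(self):
        self.calls = 0

    def eval(self):
        return self

    def __call__(self, x):
        self.calls += 1
        b, _, h, w = x.shape
        from rootseg.nn.autograd import Tensor
        return Tensor(np.zeros((b, 2, h, w), np.float32))


class TestTiledPredict:
    def test_output_dims_match_input_for_large_image(self, rng):
        img = rng.integers(0, 256, (600, 700, 3), dtype=np.uint8)
        mask = tiled_predict(_ConstantLogitModel(), img, tile=256,
                             overlap=128)
        assert mask.shape == (600, 700)
        assert (mask == 1).all()  # constant root logit wins everywhere

    def test_single_tile_case_equals_whole_image_forward(self, tiny_model,
                                                         fixture_scenes):
        tiny_model.eval()
        s = fixture_scenes[0]
        via_tiles = tiled_predict(tiny_model, s.image, tile=512, overlap=256)
        from rootseg.data import normalize_image
        from rootseg.nn import autograd as ag
        with ag.no_grad():
            out = tiny_model(normalize_image(s.image)[None])
        direct = np.argmax(out.final_logits.data[0], axis=0).astype(np.uint8)
        assert np.array_equal(via_tiles, direct)

    def test_every_pixel_covered_at_least_once(self, rng):
        model = _CoordModel()
        img = rng.integers(0, 256, (300, 520, 3), dtype=np.uint8)
        mask = tiled_predict(model, img, tile=128, overlap=64)
        assert mask.shape == (300, 520)
        assert model.calls >= (300 // 64) * (520 // 64) // 4  # grid ran

    def test_overlap_must_be_smaller_than_tile(self, rng):
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="overlap"):
            tiled_predict(_ConstantLogitModel(), img, tile=64, overlap=64)


class TestDatasetDir:
    def test_round_trip_preserves_samples(self, tmp_path, rng):
        samples = [_sample(rng, i=i) for i in range(3)]
        write_dataset_dir(tmp_path / "d", samples)
        back = read_dataset_dir(tmp_path / "d")
        assert [s.id for s in back] == [s.id for s in samples]
        for a, b in zip(samples, back):
            assert np.array_equal(a.image, b.image)
            assert np.array_equal(a.mask, b.mask)
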