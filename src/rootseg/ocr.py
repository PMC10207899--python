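"""Object-contextual-representation head and the assembled segmenter.

The OCR head augments each pixel representation with a context vector
computed against class-region summaries:

  f_k = sum_i m~_ki x_i          (soft object-region representations)
  w_ik = softmax_k phi(x_i)^T psi(f_k)   (pixel-region relation)
  y_i = rho(sum_k w_ik delta(f_k))       (object-contextual representation)
  z_i = g([x_i; y_i])                    (augmented representation)

m~ is a spatial softmax of the auxiliary FCN head's coarse logits, so
each region's weights form a convex combination over pixels.  The
improved variant passes the pixel representations through a Global
Attention Mechanism first; every downstream consumer then sees the
attention-optimized representations.

Static tensor algebra (normalize_regions, region_representations,
relation_weights, aggregate_context) is exposed as plain functions so it
can be checked against explicit per-pixel loops; the learned transforms
live in OCRHead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import BackboneConfig, HRNetV2, PixelRepresentationMap
from .errors import ConfigurationError, ShapeError
from .gam import GamConfig, GlobalAttention
from .nn import autograd as ag


@dataclass(frozen=True)
class ModelConfig:
    """Head widths and attention switches.

    The transform widths follow the canonical OCR head configuration:
    pixel representations 512, key/query and context 256, fused 512.
    ``gam_enabled: False`` yields the attention-free baseline;
    ``fuse_original`` makes the final fusion (z) consume the raw pixel
    representations instead of the attention-optimized ones.
    """

    num_classes: int = 2
    pixel_width: int = 512
    key_width: int = 256
    context_width: int = 256
    fused_width: int = 512
    gam_enabled: bool = True
    gam_reduction: int = 4
    gam_spatial_kernel: int = 7
    fuse_original: bool = False

    def __post_init__(self):
        if self.num_classes < 2:
            raise ConfigurationError(
                f"num_classes must be >= 2, got {self.num_classes}")
        for name in ("pixel_width", "key_width", "context_width",
                     "fused_width"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class SegmentationOutput:
    """Coarse (auxiliary FCN) and final logits, both at input scale."""

    aux_logits: ag.Tensor    # (B, K, H, W)
    final_logits: ag.Tensor  # (B, K, H, W)


# ---------------------------------------------------------------------
# pure tensor algebra (loop-checkable)
# ---------------------------------------------------------------------

def normalize_regions(coarse_logits) -> ag.Tensor:
    """Spatial softmax per region: m~_ki = exp(l_ki) / sum_j exp(l_kj).

    Each region's weight map sums to 1 over pixels, making the region
    representation a convex combination of pixel representations.
    """
    l = ag.as_tensor(coarse_logits)
    b, k, h, w = l.shape
    flat = ag.reshape(l, (b, k, h * w))
    return ag.reshape(ag.softmax(flat, axis=2), (b, k, h, w))


def region_representations(x, m_tilde) -> ag.Tensor:
    """f_k = sum_i m~_ki x_i for each region k.

    x: (B, D, h, w) pixel representations; m_tilde: (B, K, h, w)
    normalized region weights.  Returns (B, K, D).
    """
    x, m = ag.as_tensor(x), ag.as_tensor(m_tilde)
    if x.shape[0] != m.shape[0] or x.shape[-2:] != m.shape[-2:]:
        raise ShapeError(
            f"x {x.shape} and m~ {m.shape} disagree in batch/spatial dims")
    b, d, h, w = x.shape
    k = m.shape[1]
    xf = ag.reshape(x, (b, d, h * w))
    mf = ag.reshape(m, (b, k, h * w))
    return ag.matmul(mf, ag.transpose(xf, (0, 2, 1)))   # (B, K, D)


def relation_weights(queries, keys) -> ag.Tensor:
    """w_ik = softmax over k of q_i . r_k  (un-scaled dot products).

    queries: (B, N, d); keys: (B, K, d).  Rows sum to 1.
    """
    q, r = ag.as_tensor(queries), ag.as_tensor(keys)
    if q.shape[-1] != r.shape[-1]:
        raise ShapeError(f"key width mismatch: {q.shape} vs {r.shape}")
    scores = ag.matmul(q, ag.transpose(r, (0, 2, 1)))   # (B, N, K)
    return ag.softmax(scores, axis=2)


def aggregate_context(w, values) -> ag.Tensor:
    """sum_k w_ik v_k per pixel: (B, N, K) x (B, K, D) -> (B, N, D)."""
    w, v = ag.as_tensor(w), ag.as_tensor(values)
    if w.shape[-1] != v.shape[1]:
        raise ShapeError(f"region count mismatch: {w.shape} vs {v.shape}")
    return ag.matmul(w, v)


# ---------------------------------------------------------------------
# learned head
# ---------------------------------------------------------------------

class _ConvBnRelu1x1(nn.Module):
    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return ag.relu(self.bn(self.conv(x)))


class OCRHead(nn.Module):
    """Learned transforms of the OCR computation (phi, psi, delta, rho, g)."""

    def __init__(self, in_channels: int, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        d, dk, dy, dz = (cfg.pixel_width, cfg.key_width, cfg.context_width,
                         cfg.fused_width)
        self.input_proj = nn.Sequential(
            nn.Conv2d(in_channels, d, 3, 1, 1, bias=False, rng=rng),
            nn.BatchNorm2d(d), nn.ReLU())
        self.aux = nn.Sequential(
            nn.Conv2d(in_channels, d, 3, 1, 1, bias=False, rng=rng),
            nn.BatchNorm2d(d), nn.ReLU(),
            nn.Conv2d(d, cfg.num_classes, 1, rng=rng))
        self.phi = _ConvBnRelu1x1(d, dk, rng)     # pixel query
        self.psi = _ConvBnRelu1x1(d, dk, rng)     # region key
        self.delta = _ConvBnRelu1x1(d, dy, rng)   # region value
        self.rho = _ConvBnRelu1x1(dy, dy, rng)    # context output
        self.fuse = _ConvBnRelu1x1(d + dy, dz, rng)
        self.classifier = nn.Conv2d(dz, cfg.num_classes, 1, rng=rng)

    # -- spec operations ----------------------------------------------
    def input_transform(self, features: PixelRepresentationMap) -> ag.Tensor:
        t = features.tensor
        if t.shape[1] != self.in_channels:
            raise ShapeError(
                f"expected {self.in_channels} backbone channels, "
                f"got {t.shape[1]}")
        return self.input_proj(t)

    def aux_head(self, features: PixelRepresentationMap) -> ag.Tensor:
        t = features.tensor
        if t.shape[1] != self.in_channels:
            raise ShapeError(
                f"expected {self.in_channels} backbone channels, "
                f"got {t.shape[1]}")
        return self.aux(t)

    def _on_regions(self, transform: nn.Module, f: ag.Tensor) -> ag.Tensor:
        """Apply a 1x1 conv transform to region vectors (B, K, D)."""
        b, k, d = f.shape
        img = ag.transpose(f, (0, 2, 1)).reshape(b, d, k, 1)
        out = transform(img)
        return ag.transpose(ag.reshape(out, (b, -1, k)), (0, 2, 1))

    def pixel_region_relation(self, x: ag.Tensor, f: ag.Tensor) -> ag.Tensor:
        """Relation w: (B, N, K) via the phi/psi transforms; rows sum to 1."""
        if f.shape[1] != self.cfg.num_classes:
            raise ShapeError(
                f"expected {self.cfg.num_classes} regions, got {f.shape[1]}")
        b, d, h, w = x.shape
        q = ag.transpose(ag.reshape(self.phi(x), (b, -1, h * w)), (0, 2, 1))
        r = self._on_regions(self.psi, f)
        return relation_weights(q, r)

    def contextual_representations(self, w: ag.Tensor,
                                   f: ag.Tensor,
                                   hw: tuple[int, int]) -> ag.Tensor:
        """Context y (B, D_y, h, w) = rho(sum_k w_ik delta(f_k))."""
        v = self._on_regions(self.delta, f)
        y = aggregate_context(w, v)                       # (B, N, Dy)
        b, n, dy = y.shape
        img = ag.reshape(ag.transpose(y, (0, 2, 1)), (b, dy, *hw))
        return self.rho(img)

    def augment_representations(self, x_used: ag.Tensor,
                                y: ag.Tensor) -> ag.Tensor:
        """Fused z = g([x; y]) over the channel axis."""
        if x_used.shape[-2:] != y.shape[-2:]:
            raise ShapeError(
                f"spatial mismatch: x {x_used.shape} vs y {y.shape}")
        return self.fuse(ag.concat([x_used, y], axis=1))

    def classify_and_upsample(self, z: ag.Tensor,
                              target_hw: tuple[int, int]) -> ag.Tensor:
        h, w = z.shape[-2:]
        th, tw = target_hw
        if th % h or tw % w:
            raise ShapeError(
                f"target {target_hw} is not a multiple of head resolution "
                f"({h}, {w})")
        return ag.resize2d(self.classifier(z), target_hw, "bilinear")


class RootSegmenter(nn.Module):
    """Backbone + (optional GAM) + OCR head, with dual outputs.

    ``forward`` returns coarse auxiliary logits and final logits, both
    bilinearly upsampled to the input scale.  ``use_gam=False`` runs the
    attention-free baseline path with identical weights elsewhere.
    """

    def __init__(self, backbone_cfg: BackboneConfig | None = None,
                 model_cfg: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.backbone_cfg = backbone_cfg or BackboneConfig()
        self.model_cfg = model_cfg or ModelConfig()
        self.backbone = HRNetV2(self.backbone_cfg, seed=seed)
        self.head = OCRHead(self.backbone_cfg.out_channels, self.model_cfg,
                            seed=seed + 1)
        if self.model_cfg.gam_enabled:
            self.gam = GlobalAttention(
                GamConfig(channels=self.model_cfg.pixel_width,
                          reduction_ratio=self.model_cfg.gam_reduction,
                          spatial_kernel=self.model_cfg.gam_spatial_kernel),
                seed=seed + 2)
        else:
            self.gam = None

    def forward_features(self, features: PixelRepresentationMap,
                         use_gam: bool | None = None) -> SegmentationOutput:
        use_gam = (self.gam is not None) if use_gam is None else use_gam
        if use_gam and self.gam is None:
            raise ConfigurationError("model was built without a GAM module")
        x = self.head.input_transform(features)
        x_used = self.gam(x) if use_gam else x
        aux = self.head.aux_head(features)
        m = normalize_regions(aux)
        f = region_representations(x_used, m)
        w = self.head.pixel_region_relation(x_used, f)
        y = self.head.contextual_representations(w, f, x_used.shape[-2:])
        x_fused = x if self.model_cfg.fuse_original else x_used
        z = self.head.augment_representations(x_fused, y)
        final = self.head.classify_and_upsample(z, features.input_hw)
        aux_up = ag.resize2d(aux, features.input_hw, "bilinear")
        return SegmentationOutput(aux_logits=aux_up, final_logits=final)

    def forward(self, images, use_gam: bool | None = None) -> SegmentationOutput:
        return self.forward_features(self.backbone(images), use_gam)

    # -- convenience ---------------------------------------------------
    def predict_proba(self, images) -> np.ndarray:
        """Root-class probabilities (B, H, W) without building a graph."""
        with ag.no_grad():
            out = self.forward(images)
            p = ag.softmax(out.final_logits, axis=1)
        return p.data[:, 1]


def improved_ocr_forward(model: RootSegmenter,
                         features: PixelRepresentationMap) -> SegmentationOutput:
    """Forward pass with the GAM-optimized pixel representations."""
    return model.forward_features(features, use_gam=True)


def baseline_ocr_forward(model: RootSegmenter,
                         features: PixelRepresentationMap) -> SegmentationOutput:
    """Attention-free OCR forward (the ablation path)."""
    return model.forward_features(features, use_gam=False)
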