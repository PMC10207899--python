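"""Global Attention Mechanism: serial channel-then-spatial sigmoid gating.

Given a feature map F1 (C x H x W), the channel submodule permutes so the
channel axis trails, runs a two-layer MLP (C -> C/r -> C, shared across
spatial positions), inverse-permutes and applies a sigmoid to produce a
full 3-D channel attention map Mc.  The gated map F2 = Mc * F1 then feeds
the spatial submodule: a 7x7 conv reducing channels to C/r (BN + ReLU),
a 7x7 conv restoring C channels (BN), and a sigmoid giving Ms, with
F3 = Ms * F2.  Both gates lie strictly in (0, 1), so |F3| <= |F1|
elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError
from .nn import autograd as ag


@dataclass(frozen=True)
class GamConfig:
    channels: int
    reduction_ratio: int = 4
    spatial_kernel: int = 7
    enabled: bool = True

    def __post_init__(self):
        if self.channels <= 0:
            raise ConfigurationError(f"channels must be > 0, got {self.channels}")
        if self.reduction_ratio <= 0 or self.channels % self.reduction_ratio:
            raise ConfigurationError(
                f"reduction_ratio must divide channels "
                f"({self.channels} % {self.reduction_ratio} != 0)")
        if self.spatial_kernel < 3 or self.spatial_kernel % 2 == 0:
            raise ConfigurationError(
                f"spatial_kernel must be odd and >= 3, got {self.spatial_kernel}")


@dataclass
class AttentionMaps:
    """Intermediate products of one attention pass (for inspection)."""

    mc: np.ndarray
    ms: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray


class GlobalAttention(nn.Module):
    """Channel and spatial gating applied in series.

    ``clamp_gates_to_one`` is a test/ablation hook: when set, both
    attention maps are replaced by ones so the module becomes an exact
    identity.
    """

    def __init__(self, config: GamConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c, r, k = config.channels, config.reduction_ratio, config.spatial_kernel
        self.mlp1 = nn.Linear(c, c // r, rng=rng)
        self.mlp2 = nn.Linear(c // r, c, rng=rng)
        self.sconv1 = nn.Conv2d(c, c // r, k, 1, k // 2, bias=False, rng=rng)
        self.sbn1 = nn.BatchNorm2d(c // r)
        self.sconv2 = nn.Conv2d(c // r, c, k, 1, k // 2, bias=False, rng=rng)
        self.sbn2 = nn.BatchNorm2d(c)
        self.clamp_gates_to_one = False

    def _check(self, x: ag.Tensor) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.channels:
            raise ShapeError(
                f"expected (B, {self.config.channels}, H, W), got {x.shape}")

    def channel_attention_map(self, f1) -> ag.Tensor:
        """Mc: full-shape channel attention, values in (0, 1)."""
        f1 = ag.as_tensor(f1)
        self._check(f1)
        perm = ag.transpose(f1, (0, 2, 3, 1))          # channel trails
        hid = ag.relu(self.mlp1(perm))
        back = ag.transpose(self.mlp2(hid), (0, 3, 1, 2))
        return ag.sigmoid(back)

    def spatial_attention_map(self, f2) -> ag.Tensor:
        """Ms: spatial attention from two 7x7 convs, values in (0, 1)."""
        f2 = ag.as_tensor(f2)
        self._check(f2)
        y = ag.relu(self.sbn1(self.sconv1(f2)))
        return ag.sigmoid(self.sbn2(self.sconv2(y)))

    def forward(self, f1) -> ag.Tensor:
        f1 = ag.as_tensor(f1)
        self._check(f1)
        if not np.isfinite(f1.data).all():
            raise ValueError("non-finite values in attention input")
        if self.clamp_gates_to_one:
            return f1
        f2 = self.channel_attention_map(f1) * f1
        return self.spatial_attention_map(f2) * f2

    def attention_maps(self, f1) -> AttentionMaps:
        """Run the full pass and return every intermediate as arrays."""
        f1 = ag.as_tensor(f1)
        with ag.no_grad():
            mc = self.channel_attention_map(f1)
            f2 = mc * f1
            ms = self.spatial_attention_map(f2)
            f3 = ms * f2
        return AttentionMaps(mc=mc.data, ms=ms.data, f1=f1.data,
                             f2=f2.data, f3=f3.data)


def apply_gam(gam: GlobalAttention, f1) -> ag.Tensor:
    """F3 = Ms(Mc(F1) * F1) * (Mc(F1) * F1)."""
    return gam(f1)
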