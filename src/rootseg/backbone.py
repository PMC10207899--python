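"""HRNetV2 backbone: four parallel multi-resolution subnetworks.

The network keeps a high-resolution stream alive end-to-end while
exchanging information with progressively lower-resolution, wider
streams.  Stage 1 is a ResNet-style bottleneck stem; stages 2-4 hold
1, 4 and 3 exchange blocks whose final exchange units fuse all live
resolutions.  The final representation concatenates all four streams,
upsampled to the highest (1/4 input) resolution: 15C channels for a
width-C network (C + 2C + 4C + 8C).

Input images are float32 NCHW in [0, 1]; H and W must be divisible by 32
(stem stride 4 times the deepest branch's additional stride 8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError
from .nn import autograd as ag


@dataclass(frozen=True)
class BackboneConfig:
    """Width and depth layout of the backbone.

    base_width is the channel count C of the highest-resolution branch;
    branch i has C * 2**i channels.  exchange_blocks gives the block
    counts of stages 2-4 (default (1, 4, 3): 8 exchange units in total).
    """

    base_width: int = 48
    stage1_units: int = 4
    stage1_width: int = 64
    exchange_blocks: tuple[int, int, int] = (1, 4, 3)
    units_per_block: int = 4

    def __post_init__(self):
        if self.base_width <= 0:
            raise ConfigurationError(
                f"base_width must be positive, got {self.base_width}")
        if self.base_width % 2 != 0:
            raise ConfigurationError(
                f"base_width must be divisible by 2 (fusion convs halve it), "
                f"got {self.base_width}")
        if self.stage1_units < 1:
            raise ConfigurationError(
                f"stage1_units must be >= 1, got {self.stage1_units}")
        if len(self.exchange_blocks) != 3 or any(
                b < 0 for b in self.exchange_blocks):
            raise ConfigurationError(
                f"exchange_blocks must be 3 non-negative counts, "
                f"got {self.exchange_blocks}")
        if self.units_per_block < 1:
            raise ConfigurationError(
                f"units_per_block must be >= 1, got {self.units_per_block}")

    @property
    def branch_channels(self) -> tuple[int, int, int, int]:
        c = self.base_width
        return (c, 2 * c, 4 * c, 8 * c)

    @property
    def out_channels(self) -> int:
        return sum(self.branch_channels)  # 15 * C


@dataclass
class PixelRepresentationMap:
    """Concatenated multi-resolution features at 1/4 input resolution."""

    tensor: ag.Tensor  # (B, 15C, H/4, W/4)
    input_hw: tuple[int, int]


def _conv_bn_relu(c_in, c_out, k, stride, rng, relu=True):
    mods = [nn.Conv2d(c_in, c_out, k, stride, k // 2, bias=False, rng=rng),
            nn.BatchNorm2d(c_out)]
    if relu:
        mods.append(nn.ReLU())
    return nn.Sequential(*mods)


def _zero_last_bn(block: nn.Sequential) -> nn.Sequential:
    """Zero the closing BN scale so a fresh residual unit starts as identity.

    Standard deep-residual initialization: it keeps early training of the
    many-unit backbone close to a shallower network.
    """
    bn = block._list[-1] if isinstance(block._list[-1], nn.BatchNorm2d) else None
    if bn is not None:
        bn.gamma.data[:] = 0.0
    return block


class Bottleneck(nn.Module):
    """1x1 -> 3x3 -> 1x1 residual unit with 4x expansion (ResNet-50 style)."""

    expansion = 4

    def __init__(self, c_in, width, rng):
        super().__init__()
        c_out = width * self.expansion
        self.conv1 = _conv_bn_relu(c_in, width, 1, 1, rng)
        self.conv2 = _conv_bn_relu(width, width, 3, 1, rng)
        self.conv3 = _zero_last_bn(_conv_bn_relu(width, c_out, 1, 1, rng,
                                                 relu=False))
        self.skip = (None if c_in == c_out
                     else _conv_bn_relu(c_in, c_out, 1, 1, rng, relu=False))

    def forward(self, x):
        idn = x if self.skip is None else self.skip(x)
        return ag.relu(self.conv3(self.conv2(self.conv1(x))) + idn)


class BasicUnit(nn.Module):
    """Two 3x3 convolutions with a residual connection."""

    def __init__(self, c, rng):
        super().__init__()
        self.conv1 = _conv_bn_relu(c, c, 3, 1, rng)
        self.conv2 = _zero_last_bn(_conv_bn_relu(c, c, 3, 1, rng, relu=False))

    def forward(self, x):
        return ag.relu(self.conv2(self.conv1(x)) + x)


class ExchangeUnit(nn.Module):
    """Cross-resolution fusion across all live branches.

    Lower->higher paths use a 1x1 conv + BN then bilinear upsampling;
    higher->lower paths use chains of stride-2 3x3 convs (BN+ReLU on
    intermediates, BN only on the last).  Contributions are summed and
    passed through a ReLU.
    """

    def __init__(self, channels: list[int], rng):
        super().__init__()
        self.n = len(channels)
        paths = nn.ModuleList()
        for i in range(self.n):          # output branch
            row = nn.ModuleList()
            for j in range(self.n):      # input branch
                if j == i:
                    row.append(nn.Sequential())
                elif j > i:              # upsample path
                    row.append(_conv_bn_relu(channels[j], channels[i], 1, 1,
                                             rng, relu=False))
                else:                    # downsample chain
                    steps = []
                    for s in range(i - j):
                        last = s == i - j - 1
                        c_in = channels[j]
                        c_out = channels[i] if last else channels[j]
                        steps.append(_conv_bn_relu(c_in, c_out, 3, 2, rng,
                                                   relu=not last))
                    row.append(nn.Sequential(*steps))
            paths.append(row)
        self.paths = paths

    def forward(self, xs):
        outs = []
        for i in range(self.n):
            acc = None
            hw = xs[i].shape[-2:]
            for j in range(self.n):
                y = self.paths[i][j](xs[j])
                if j > i:
                    y = ag.resize2d(y, hw, "bilinear")
                acc = y if acc is None else acc + y
            outs.append(ag.relu(acc))
        return outs


class ExchangeBlock(nn.Module):
    """Per-branch residual units followed by one exchange unit."""

    def __init__(self, channels: list[int], units: int, rng):
        super().__init__()
        self.branches = nn.ModuleList(
            nn.Sequential(*[BasicUnit(c, rng) for _ in range(units)])
            for c in channels)
        self.exchange = ExchangeUnit(channels, rng)

    def forward(self, xs):
        xs = [b(x) for b, x in zip(self.branches, xs)]
        return self.exchange(xs)


class HRNetV2(nn.Module):
    """The four-stage multi-resolution backbone."""

    def __init__(self, config: BackboneConfig | None = None,
                 seed: int = 0):
        super().__init__()
        cfg = config or BackboneConfig()
        self.config = cfg
        rng = np.random.default_rng(seed)
        chans = cfg.branch_channels

        self.stem = nn.Sequential(_conv_bn_relu(3, 64, 3, 2, rng),
                                  _conv_bn_relu(64, 64, 3, 2, rng))
        units = [Bottleneck(64 if i == 0 else
                            cfg.stage1_width * Bottleneck.expansion,
                            cfg.stage1_width, rng)
                 for i in range(cfg.stage1_units)]
        self.stage1 = nn.Sequential(*units)
        s1_out = cfg.stage1_width * Bottleneck.expansion

        # transitions create one new (halved, doubled-width) branch each
        self.transitions = nn.ModuleList()
        self.stages = nn.ModuleList()
        prev = [s1_out]
        for si, n_blocks in enumerate(cfg.exchange_blocks):
            live = list(chans[:si + 2])
            trans = nn.ModuleList()
            for bi, c in enumerate(live):
                if bi < len(prev):
                    trans.append(nn.Sequential() if prev[bi] == c
                                 else _conv_bn_relu(prev[bi], c, 3, 1, rng))
                else:
                    trans.append(_conv_bn_relu(prev[-1], c, 3, 2, rng))
            self.transitions.append(trans)
            self.stages.append(nn.ModuleList(
                ExchangeBlock(live, cfg.units_per_block, rng)
                for _ in range(n_blocks)))
            prev = live

    def forward(self, images) -> PixelRepresentationMap:
        x = ag.as_tensor(images)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError(f"expected (B, 3, H, W) input, got {x.shape}")
        h, w = x.shape[-2:]
        if h % 32 or w % 32:
            raise ShapeError(
                f"input H and W must be divisible by 32 (stem stride 4, "
                f"deepest branch stride 32); got {h}x{w}")
        y = self.stage1(self.stem(x))
        xs = [y]
        for trans, stage in zip(self.transitions, self.stages):
            nxt = []
            for bi, t in enumerate(trans):
                src = xs[bi] if bi < len(xs) else xs[-1]
                nxt.append(t(src))
            xs = nxt
            for block in stage:
                xs = block(xs)
        hw = xs[0].shape[-2:]
        up = [xs[0]] + [ag.resize2d(t, hw, "bilinear") for t in xs[1:]]
        out = ag.concat(up, axis=1)
        return PixelRepresentationMap(tensor=out, input_hw=(h, w))


def build_backbone(config: BackboneConfig | None = None,
                   seed: int = 0) -> HRNetV2:
    """Construct the backbone (validates the configuration)."""
    return HRNetV2(config, seed=seed)


def backbone_forward(backbone: HRNetV2, images) -> PixelRepresentationMap:
    """Run the backbone on a normalized (B, 3, H, W) batch."""
    return backbone(images)


def count_exchange_units(backbone: HRNetV2) -> int:
    """Number of cross-resolution exchange units actually instantiated."""
    return sum(1 for m in backbone.modules() if isinstance(m, ExchangeUnit))
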