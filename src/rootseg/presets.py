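"""Named configuration presets.

``reference()`` is the full-scale configuration the segmenter is
designed around: HRNetV2-W48, 512-wide OCR head, 512-pixel random crops,
40k iterations of SGDM under polynomial learning-rate decay.

``smoke()`` is a desk-scale preset for exercising the complete training
pipeline on a laptop/CI CPU in minutes: a width-8 backbone with a
32-wide head, 96x96 synthetic scenes with wide high-contrast roots, and
a short, hotter polynomial schedule (deep-residual nets need a larger
initial rate to move in a few hundred iterations).
"""

from __future__ import annotations

from dataclasses import dataclass

from .backbone import BackboneConfig
from .ocr import ModelConfig
from .synthetic import SceneSpec
from .training import LossConfig, OptimConfig, PolyLrSchedule


@dataclass(frozen=True)
class Preset:
    backbone: BackboneConfig
    model: ModelConfig
    optim: OptimConfig
    sched: PolyLrSchedule
    loss: LossConfig
    scene: SceneSpec


def reference(gam_enabled: bool = True) -> Preset:
    """The full-scale training configuration."""
    return Preset(
        backbone=BackboneConfig(),
        model=ModelConfig(gam_enabled=gam_enabled),
        optim=OptimConfig(),
        sched=PolyLrSchedule(),
        loss=LossConfig(),
        scene=SceneSpec(),
    )


def smoke(gam_enabled: bool = True, seed: int = 0,
          max_iter: int = 300) -> Preset:
    """Reduced-width preset that overfits a few small scenes in minutes."""
    ckpt = max(1, max_iter // 3)
    while max_iter % ckpt:
        ckpt -= 1
    return Preset(
        backbone=BackboneConfig(base_width=8, stage1_width=16),
        model=ModelConfig(pixel_width=32, key_width=16, context_width=16,
                          fused_width=32, gam_enabled=gam_enabled),
        optim=OptimConfig(batch_size=8, max_iter=max_iter,
                          ckpt_interval=ckpt, crop=96, seed=seed),
        sched=PolyLrSchedule(lr0=0.1, lr_min=0.001, max_iter=max_iter),
        loss=LossConfig(),
        scene=SceneSpec(width=96, height=96, n_roots=3,
                        root_width_range=(8.0, 16.0), step_length=4.0,
                        root_contrast=0.45, texture_strength=0.04,
                        n_stones=2, n_cracks=1, n_film_patches=0, n_worms=1),
    )
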