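"""YAML configuration: one file describing backbone, head, attention and
training schedule, mirroring the reference hyperparameter table.

Unknown keys raise, so typos in config files fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .data import AugmentationSpec
from .errors import ConfigurationError
from .ocr import ModelConfig
from .presets import Preset
from .synthetic import SceneSpec
from .training import LossConfig, OptimConfig, PolyLrSchedule

_TRAIN_KEYS = {
    "initial_lr", "lr_power", "min_lr", "momentum", "weight_decay",
    "batch_size", "max_iterations", "checkpoint_interval", "crop_size",
    "aux_loss_weight", "main_loss_weight", "seed",
}


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in '{name}' block: {sorted(unknown)}")


def load_config(path) -> Preset:
    """Parse a YAML config into the package's configuration dataclasses."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config root must be a mapping: {path}")
    _check_keys(doc, {"backbone", "model", "gam", "train", "augment",
                      "scene"}, "top level")

    bb = doc.get("backbone", {})
    _check_keys(bb, {"base_width", "stage1_units", "stage1_width",
                     "exchange_blocks", "units_per_block"}, "backbone")
    if "exchange_blocks" in bb:
        bb = dict(bb, exchange_blocks=tuple(bb["exchange_blocks"]))
    backbone = BackboneConfig(**bb)

    md = doc.get("model", {})
    _check_keys(md, {"num_classes", "pixel_width", "key_width",
                     "context_width", "fused_width", "fuse_original"},
                "model")
    gm = doc.get("gam", {})
    _check_keys(gm, {"enabled", "reduction_ratio", "spatial_kernel"}, "gam")
    model = ModelConfig(
        gam_enabled=bool(gm.get("enabled", True)),
        gam_reduction=int(gm.get("reduction_ratio", 4)),
        gam_spatial_kernel=int(gm.get("spatial_kernel", 7)),
        **md)

    tr = doc.get("train", {})
    _check_keys(tr, _TRAIN_KEYS, "train")
    max_iter = int(tr.get("max_iterations", 40000))
    sched = PolyLrSchedule(lr0=float(tr.get("initial_lr", 0.01)),
                           power=float(tr.get("lr_power", 0.9)),
                           lr_min=float(tr.get("min_lr", 0.0001)),
                           max_iter=max_iter)
    optim = OptimConfig(momentum=float(tr.get("momentum", 0.9)),
                        weight_decay=float(tr.get("weight_decay", 0.0005)),
                        batch_size=int(tr.get("batch_size", 4)),
                        max_iter=max_iter,
                        ckpt_interval=int(tr.get("checkpoint_interval", 500)),
                        crop=int(tr.get("crop_size", 512)),
                        seed=int(tr.get("seed", 0)))
    loss = LossConfig(aux_weight=float(tr.get("aux_loss_weight", 0.4)),
                      main_weight=float(tr.get("main_loss_weight", 1.0)))

    aug = doc.get("augment", {})
    _check_keys(aug, set(AugmentationSpec.__dataclass_fields__), "augment")
    AugmentationSpec(**aug)  # validate early; CLI rebuilds from same dict

    sc = doc.get("scene", {})
    _check_keys(sc, set(SceneSpec.__dataclass_fields__), "scene")
    for key in ("root_width_range", "texture_octaves"):
        if key in sc:
            sc = dict(sc, **{key: tuple(sc[key])})
    scene = SceneSpec(**sc)

    return Preset(backbone=backbone, model=model, optim=optim, sched=sched,
                  loss=loss, scene=scene)
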