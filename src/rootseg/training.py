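"""Training engine: dual cross-entropy loss, polynomial LR decay, the
random-crop pipeline and the checkpoint/selection loop.

The objective sums a pixel-wise cross-entropy on the auxiliary (coarse
FCN) output, weighted 0.4, and the same loss on the final output,
weighted 1.0.  Optimization is SGD with momentum 0.9, weight decay
5e-4, batch size 4 and a polynomial learning-rate decay from 0.01 to
1e-4 over 40k iterations (power 0.9) — the reference schedule; every
knob is config-exposed so desk-scale runs can shrink it.

Training samples by iteration, not epoch: each step draws `batch_size`
training images uniformly with replacement and takes one random crop
from each.  Every `ckpt_interval` iterations the model is serialized
and scored by whole-image validation IoU (tiled inference); the best
checkpoint is the one with maximal validation IoU, later iteration
winning ties.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .data import RootSample, normalize_image, tiled_predict
from .errors import ConfigurationError, ShapeError
from .metrics import ConfusionCounts, confusion, iou
from .nn import autograd as ag


@dataclass(frozen=True)
class LossConfig:
    aux_weight: float = 0.4
    main_weight: float = 1.0
    eps: float = 1e-7          # probability clamp for log stability

    def __post_init__(self):
        if self.aux_weight < 0 or self.main_weight < 0:
            raise ConfigurationError("loss weights must be >= 0")
        if not 0 < self.eps <= 1e-3:
            raise ConfigurationError(f"eps must be in (0, 1e-3], got {self.eps}")


@dataclass(frozen=True)
class PolyLrSchedule:
    lr0: float = 0.01
    power: float = 0.9
    lr_min: float = 0.0001
    max_iter: int = 40000

    def __post_init__(self):
        if not self.lr0 > self.lr_min > 0:
            raise ConfigurationError(
                f"need lr0 > lr_min > 0, got {self.lr0}, {self.lr_min}")
        if self.power <= 0:
            raise ConfigurationError(f"power must be > 0, got {self.power}")


@dataclass(frozen=True)
class OptimConfig:
    momentum: float = 0.9
    weight_decay: float = 0.0005
    batch_size: int = 4
    max_iter: int = 40000
    ckpt_interval: int = 500
    crop: int = 512
    seed: int = 0

    def __post_init__(self):
        for name in ("momentum", "weight_decay", "batch_size", "max_iter",
                     "ckpt_interval", "crop"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.max_iter % self.ckpt_interval:
            raise ConfigurationError(
                f"ckpt_interval {self.ckpt_interval} must divide "
                f"max_iter {self.max_iter}")


@dataclass
class CheckpointRecord:
    iteration: int
    weights_path: str | None
    val_iou: float
    state: dict | None = None   # in-memory weights when no out_dir given

    def __post_init__(self):
        if not 0.0 <= self.val_iou <= 1.0:
            raise ValueError(f"val_iou out of [0,1]: {self.val_iou}")


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------

def pixel_ce_loss(probs, labels, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy over pixels (plain arrays).

    probs are root-class probabilities in [0, 1] (clamped to
    [eps, 1-eps]); labels are {0, 1}.
    """
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ShapeError(f"probs {p.shape} and labels {y.shape} differ")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be in {0, 1}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _ce_from_logits(logits: ag.Tensor, labels: np.ndarray,
                    eps: float) -> ag.Tensor:
    """Differentiable mean CE: softmax over the K axis, clamp, -log p_true.

    For K = 2 this equals the binary cross-entropy on the root-class
    probability exactly.
    """
    b, k, h, w = logits.shape
    onehot = np.zeros((b, k, h, w), dtype=np.float32)
    lab = np.asarray(labels).reshape(b, h, w).astype(int)
    for c in range(k):
        onehot[:, c] = lab == c
    p = ag.clamp(ag.softmax(logits, axis=1), eps, 1.0 - eps)
    return -ag.tsum(ag.mul(ag.tlog(p), ag.Tensor(onehot))) * (1.0 / (b * h * w))


def total_loss(aux_logits: ag.Tensor, final_logits: ag.Tensor,
               labels: np.ndarray,
               cfg: LossConfig | None = None) -> ag.Tensor:
    """0.4 * CE(aux) + 1.0 * CE(final), both at label resolution."""
    cfg = cfg or LossConfig()
    if aux_logits.shape != final_logits.shape:
        raise ShapeError(
            f"aux {aux_logits.shape} and final {final_logits.shape} differ")
    l_aux = _ce_from_logits(aux_logits, labels, cfg.eps)
    l_final = _ce_from_logits(final_logits, labels, cfg.eps)
    return cfg.aux_weight * l_aux + cfg.main_weight * l_final


# ---------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------

def poly_lr(iteration: int, sched: PolyLrSchedule | None = None) -> float:
    """Polynomial decay with an additive floor.

    lr = (lr0 - lr_min) * (1 - t/T)^power + lr_min, hitting lr0 at t=0
    and lr_min at t=T exactly; monotone non-increasing in between.
    """
    sched = sched or PolyLrSchedule()
    if not 0 <= iteration <= sched.max_iter:
        raise ValueError(
            f"iteration {iteration} outside [0, {sched.max_iter}]")
    frac = 1.0 - iteration / sched.max_iter
    return (sched.lr0 - sched.lr_min) * frac ** sched.power + sched.lr_min


# ---------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------

def random_crop(sample: RootSample, size: int = 512,
                rng: np.random.Generator | None = None) -> RootSample:
    """A size x size crop at a uniform offset; small inputs reflect-pad."""
    rng = rng or np.random.default_rng(0)
    img, msk = sample.image, sample.mask
    h, w = msk.shape
    if h < size or w < size:
        py, px = max(0, size - h), max(0, size - w)
        img = np.pad(img, ((0, py), (0, px), (0, 0)), mode="reflect")
        msk = np.pad(msk, ((0, py), (0, px)), mode="reflect")
        h, w = msk.shape
    y0 = int(rng.integers(0, h - size + 1))
    x0 = int(rng.integers(0, w - size + 1))
    return RootSample(image=img[y0:y0 + size, x0:x0 + size],
                      mask=msk[y0:y0 + size, x0:x0 + size],
                      id=f"{sample.id}@{y0},{x0}",
                      provenance=sample.provenance,
                      group_id=sample.group_id)


# ---------------------------------------------------------------------
# loop
# ---------------------------------------------------------------------

def _val_iou(model, val_set: Sequence[RootSample], tile: int,
             overlap: int) -> float:
    model.eval()
    pooled = ConfusionCounts(0, 0, 0, 0)
    for s in val_set:
        pred = tiled_predict(model, s.image, tile=tile, overlap=overlap)
        pooled = pooled + confusion(pred, s.mask)
    model.train()
    return iou(pooled)


def train(model, train_set: Sequence[RootSample],
          val_set: Sequence[RootSample],
          cfg: OptimConfig | None = None,
          sched: PolyLrSchedule | None = None,
          loss_cfg: LossConfig | None = None,
          out_dir: str | Path | None = None,
          log_every: int = 50,
          progress: bool = False) -> list[CheckpointRecord]:
    """Run the SGDM loop; returns one CheckpointRecord per interval.

    Checkpoints are written to out_dir as .npz archives when a
    directory is given, otherwise kept in memory on the records.  A
    CSV log (iteration, lr, loss, val_iou) is written alongside.
    """
    cfg = cfg or OptimConfig()
    sched = sched or PolyLrSchedule(max_iter=cfg.max_iter)
    loss_cfg = loss_cfg or LossConfig()
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    if sched.max_iter != cfg.max_iter:
        sched = PolyLrSchedule(sched.lr0, sched.power, sched.lr_min,
                               cfg.max_iter)

    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGDM(model.parameters(), momentum=cfg.momentum,
                  weight_decay=cfg.weight_decay)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    log_rows = []
    records: list[CheckpointRecord] = []
    model.train()

    iterator = range(1, cfg.max_iter + 1)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="train")
    for it in iterator:
        idx = rng.integers(0, len(train_set), size=cfg.batch_size)
        crops = [random_crop(train_set[i], cfg.crop, rng) for i in idx]
        images = np.stack([normalize_image(c.image) for c in crops])
        labels = np.stack([c.mask for c in crops])

        out = model(images)
        loss = total_loss(out.aux_logits, out.final_logits, labels, loss_cfg)
        loss_val = loss.item()
        if not math.isfinite(loss_val):
            raise FloatingPointError(
                f"non-finite loss {loss_val} at iteration {it}; "
                f"lr={poly_lr(it - 1, sched):.3g}")
        opt.zero_grad()
        loss.backward()
        opt.step(poly_lr(it - 1, sched))

        if it % log_every == 0 or it == 1:
            log_rows.append((it, poly_lr(it - 1, sched), loss_val, ""))
        if it % cfg.ckpt_interval == 0:
            v = _val_iou(model, val_set, tile=cfg.crop, overlap=cfg.crop // 2)
            state = model.state_dict()
            if out_path is not None:
                wpath = out_path / f"ckpt_{it:06d}.npz"
                np.savez(wpath, **state)
                rec = CheckpointRecord(it, str(wpath), v)
            else:
                rec = CheckpointRecord(it, None, v,
                                       state={k: a.copy() for k, a
                                              in state.items()})
            records.append(rec)
            log_rows.append((it, poly_lr(it - 1, sched), loss_val, v))

    if out_path is not None:
        with open(out_path / "train_log.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "lr", "loss", "val_iou"])
            w.writerows(log_rows)
    return records


def select_best_checkpoint(records: Sequence[CheckpointRecord]
                           ) -> CheckpointRecord:
    """The record with maximal validation IoU; ties -> later iteration."""
    if not records:
        raise ValueError("no checkpoint records to select from")
    return max(records, key=lambda r: (r.val_iou, r.iteration))
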