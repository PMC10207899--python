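"""Binary segmentation metrics from pooled pixel confusion counts.

Root (mask value 1) is the positive class.  Accuracy uses both classes;
recall/precision/F1/IoU are computed for the root class only.  Degenerate
0/0 ratios (empty ground truth and/or empty prediction) evaluate to 1.0,
so a perfectly empty prediction of an empty image scores perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ShapeError


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies: true/false positives and negatives."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion(pred_mask, gt_mask) -> ConfusionCounts:
    """Exact pixel tallies for a binary prediction/annotation pair."""
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ShapeError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    for name, m in (("prediction", pred), ("ground truth", gt)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask contains non-binary values")
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & gt)),
        fp=int(np.count_nonzero(pred & ~gt)),
        fn=int(np.count_nonzero(~pred & gt)),
        tn=int(np.count_nonzero(~pred & ~gt)),
    )


def _ratio(num: float, den: float) -> float:
    return 1.0 if den == 0 else num / den


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + FN + TN)."""
    return _ratio(c.tp + c.tn, c.total)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 1.0 when there are no positives to find."""
    return _ratio(c.tp, c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 1.0 when nothing was predicted positive."""
    return _ratio(c.tp, c.tp + c.fp)


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall (Dice)."""
    p, r = precision(c), recall(c)
    return _ratio(2.0 * p * r, p + r)


def f1_from_pr(p: float, r: float) -> float:
    """F1 from already-computed precision and recall values."""
    return _ratio(2.0 * p * r, p + r)


def iou(c: ConfusionCounts) -> float:
    """TP / (TP + FP + FN) for the root class; 1.0 on an empty union."""
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def all_metrics(c: ConfusionCounts, digits: int | None = None) -> dict:
    vals = {"accuracy": accuracy(c), "recall": recall(c),
            "precision": precision(c), "f1": f1(c), "iou": iou(c)}
    if digits is not None:
        vals = {k: round(v, digits) for k, v in vals.items()}
    return vals


def evaluate_dataset(predict_fn, samples: Sequence, digits: int = 4,
                     per_image_mean: bool = False) -> dict:
    """Evaluate a predictor over annotated samples.

    predict_fn maps a sample's image (H, W, 3 uint8) to a binary mask.
    By default confusion counts are pooled globally over all pixels of
    all images before the metrics are applied once; ``per_image_mean``
    instead averages per-image metric values.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("cannot evaluate an empty sample list")
    if per_image_mean:
        acc = {k: 0.0 for k in ("accuracy", "recall", "precision", "f1",
                                "iou")}
        for s in samples:
            m = all_metrics(confusion(predict_fn(s.image), s.mask))
            for k in acc:
                acc[k] += m[k]
        return {k: round(v / len(samples), digits) for k, v in acc.items()}
    pooled = ConfusionCounts(0, 0, 0, 0)
    for s in samples:
        pooled = pooled + confusion(predict_fn(s.image), s.mask)
    return all_metrics(pooled, digits=digits)
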