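"""Confusion-matrix segmentation metrics and the BCE+Dice training loss.

Metrics are computed from pooled pixel counts (micro-average over the whole
evaluation set), producing one number per dataset: DSC (== F1), sensitivity,
specificity, accuracy, IoU and precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .nn import Tensor, as_tensor

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "segmentation_metrics", "bce_dice_loss"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts pooled over an evaluation set."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    """The six standard segmentation metrics, each in [0, 1]."""

    dsc: float
    se: float
    sp: float
    acc: float
    iou: float
    prec: float

    def as_dict(self):
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(pred, truth, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold a probability map at ``threshold`` (>= is positive) and
    tally TP/TN/FP/FN against a binary mask."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    uniq = np.unique(truth)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"truth mask must be binary, found values {uniq[:10]}")
    if not np.all(np.isfinite(pred)):
        raise ValueError("non-finite values in prediction")
    pos = pred >= threshold
    t = truth.astype(bool)
    tp = int(np.count_nonzero(pos & t))
    fp = int(np.count_nonzero(pos & ~t))
    fn = int(np.count_nonzero(~pos & t))
    tn = int(np.count_nonzero(~pos & ~t))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int, name: str) -> float:
    """A metric ratio; an empty denominator means the ideal is vacuously met
    (e.g. specificity on an image with no background), reported as 1.0."""
    if den == 0:
        log.debug("metric %s has empty denominator; reporting 1.0", name)
        return 1.0
    return num / den


def segmentation_metrics(c: ConfusionCounts) -> MetricsReport:
    """DSC/SE/SP/ACC/IoU/Prec from pooled confusion counts."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return MetricsReport(
        dsc=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "dsc"),
        se=_ratio(c.tp, c.tp + c.fn, "se"),
        sp=_ratio(c.tn, c.tn + c.fp, "sp"),
        acc=(c.tp + c.tn) / c.total,
        iou=_ratio(c.tp, c.tp + c.fp + c.fn, "iou"),
        prec=_ratio(c.tp, c.tp + c.fp, "prec"),
    )


def bce_dice_loss(pred, truth, w_bce: float = 1.0, w_dice: float = 1.0,
                  eps: float = 1e-7, smooth: float = 1.0) -> Tensor:
    """Weighted sum of pixelwise binary cross-entropy (mean) and soft-Dice
    loss (``1 - Dice`` with additive smoothing).  ``pred`` are probabilities
    in (0, 1); they are clamped by ``eps`` for the logarithms.  Returns a
    scalar Tensor differentiable in ``pred``."""
    pred = as_tensor(pred)
    truth = as_tensor(np.asarray(truth, dtype=pred.dtype)
                      if not isinstance(truth, Tensor) else truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.clip(eps, 1.0 - eps)
    t = truth
    bce = -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()
    inter = (p * t).sum()
    dice = (2.0 * inter + smooth) / (p.sum() + t.sum() + smooth)
    return w_bce * bce + w_dice * (1.0 - dice)
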