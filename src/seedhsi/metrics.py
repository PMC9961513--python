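"""Per-class evaluation metrics for discriminant models.

Sensitivity and specificity are computed one-vs-rest per class.  Class error
is stored in *percent* so that the overall-accuracy aggregation
(``100 - max(class errors)``) operates on a single scale.  Display rounding
is half-away-from-zero to one decimal; computations are never rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InputError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "class_error",
    "overall_accuracy",
    "per_class_report",
    "round_display",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise InputError(f"confusion count {name!r} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class ClassMetrics:
    """Sensitivity/specificity (fractions) and class error (percent) for one class."""

    label: object
    sensitivity: float
    specificity: float
    class_error: float


def confusion_counts(y_true: Sequence, y_pred: Sequence, positive) -> ConfusionCounts:
    """Build one-vs-rest confusion counts treating ``positive`` as the target class."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise InputError("y_true and y_pred must have identical shapes")
    pos_t = yt == positive
    pos_p = yp == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """True positive rate TP / (TP + FN)."""
    denom = c.tp + c.fn
    if denom == 0:
        raise UndefinedMetricError("sensitivity undefined: TP + FN = 0")
    return c.tp / denom


def specificity(c: ConfusionCounts) -> float:
    """True negative rate TN / (TN + FP)."""
    denom = c.tn + c.fp
    if denom == 0:
        raise UndefinedMetricError("specificity undefined: TN + FP = 0")
    return c.tn / denom


def class_error(sens: float, spec: float) -> float:
    """Class error in percent: ``(1 - (sensitivity + specificity) / 2) * 100``."""
    return (1.0 - (sens + spec) / 2.0) * 100.0


def overall_accuracy(class_errors: Iterable[float]) -> float:
    """Overall accuracy in percent: ``100 - max(class errors)``.

    The argument collects class errors across classes and evaluation phases
    (cross-validation and prediction); the worst one sets the accuracy.
    """
    errors = list(class_errors)
    if not errors:
        raise InputError("overall_accuracy requires at least one class error")
    return 100.0 - max(errors)


def per_class_report(y_true, y_pred, classes: Sequence | None = None) -> list[ClassMetrics]:
    """One-vs-rest metrics for every class.

    ``classes`` fixes the class order; defaults to the sorted unique labels of
    ``y_true``.
    """
    yt = np.asarray(y_true)
    if classes is None:
        classes = sorted(np.unique(yt).tolist())
    out = []
    for cls in classes:
        c = confusion_counts(yt, y_pred, cls)
        sens = sensitivity(c)
        spec = specificity(c)
        out.append(ClassMetrics(cls, sens, spec, class_error(sens, spec)))
    return out


def round_display(x: float, decimals: int = 1) -> float:
    """Round half away from zero, for table display only."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
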