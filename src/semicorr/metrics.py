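"""Binary classification statistics: confusion counts, sensitivity,
specificity, accuracy and the Matthews correlation coefficient."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "classification_stats",
    "ClassificationStats",
    "mcc_score",
    "round4",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationStats:
    """Derived statistics; sensitivity/specificity/accuracy are NaN when
    their denominator is empty, MCC falls back to 0 (with a warning)."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


def confusion(observed: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    obs = np.asarray(observed, dtype=int)
    pred = np.asarray(predicted, dtype=int)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-d sequences")
    tp = int(np.sum((obs == 1) & (pred == 1)))
    tn = int(np.sum((obs == 0) & (pred == 0)))
    fp = int(np.sum((obs == 0) & (pred == 1)))
    fn = int(np.sum((obs == 1) & (pred == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def classification_stats(c: ConfusionCounts) -> ClassificationStats:
    """Sensitivity, specificity, accuracy and MCC from a 2x2 table.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); when any
    marginal is zero the coefficient is reported as 0 (the usual convention)
    with a warning.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    acc = (tp + tn) / c.n if c.n else math.nan
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC undefined (zero marginal); reporting 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return ClassificationStats(sens, spec, acc, mcc)


def mcc_score(observed: Sequence[int], predicted: Sequence[int]) -> float:
    """Matthews correlation coefficient of a prediction vector."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return classification_stats(confusion(observed, predicted)).mcc


def round4(x: float) -> float:
    """Round to 4 decimal places, half-up (report formatting)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))
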