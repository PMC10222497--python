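"""System of self-consistent models.

k independent random four-way splits yield k models; every model is then
scored on every split's validation set, giving a k x k matrix of Matthews
correlation coefficients (row i = model i, column j = validation set of
split j). The off-diagonal mean and dispersion measure how robust the
modelling protocol is to the split, which a single train/validation split
cannot show. Cross-split validation compounds are NOT purged of overlap
with model i's training material — instead the pairwise Jaccard overlap of
the validation sets is reported alongside, making the contamination
visible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .descriptor import SemiCorrelationModel
from .metrics import mcc_score
from .splits import FourWaySplit

__all__ = [
    "ConsistencyMatrix",
    "build_matrix",
    "summarize",
    "validation_overlap",
]


@dataclass(frozen=True)
class ConsistencyMatrix:
    """k x k matrix of cross-split validation MCCs; entry (i, j) is model i
    scored on split j's validation set, so the diagonal holds the ordinary
    per-split validation MCCs."""

    mcc: np.ndarray

    @property
    def k(self) -> int:
        return self.mcc.shape[0]


def build_matrix(
    models: Sequence[SemiCorrelationModel],
    splits: Sequence[FourWaySplit],
    profiles: Sequence[Counter],
    labels: Sequence[int],
) -> ConsistencyMatrix:
    """Score every model on every split's validation set."""
    if len(models) != len(splits):
        raise ValueError("need exactly one model per split")
    k = len(models)
    labels = np.asarray(labels, dtype=int)
    mat = np.empty((k, k))
    val_profiles = [
        [profiles[i] for i in split.validation] for split in splits
    ]
    for i, model in enumerate(models):
        for j in range(k):
            _, pred = model.predict_profiles(val_profiles[j])
            mat[i, j] = mcc_score(labels[splits[j].validation], pred)
    return ConsistencyMatrix(mat)


def summarize(matrix: ConsistencyMatrix) -> dict:
    """Off-diagonal mean and population standard deviation (plus the
    all-cells mean as a secondary figure)."""
    m = matrix.mcc
    k = matrix.k
    if k < 2:
        raise ValueError("self-consistency needs k >= 2 splits")
    off = m[~np.eye(k, dtype=bool)]
    # population sd (the cells are an exhaustive enumeration, not a sample);
    # a constant matrix must report exactly 0
    sd = 0.0 if np.ptp(off) == 0 else float(off.std())
    return {
        "mean_offdiag": float(off.mean()),
        "sd_offdiag": sd,
        "mean_all": float(m.mean()),
    }


def validation_overlap(splits: Sequence[FourWaySplit]) -> np.ndarray:
    """Pairwise Jaccard similarity of the k validation sets."""
    if len(splits) < 2:
        raise ValueError("need k >= 2 splits")
    sets = [set(s.validation.tolist()) for s in splits]
    k = len(sets)
    out = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            union = sets[i] | sets[j]
            out[i, j] = len(sets[i] & sets[j]) / len(union) if union else 1.0
    return out
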