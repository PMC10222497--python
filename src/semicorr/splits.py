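"""Random four-way data splits.

Each split partitions the compound table into four roughly equal, disjoint
subsets with distinct roles: the active training set fits the correlation
weights, the passive training set checks that the model transfers to
compounds not used in weight fitting, the calibration set detects the onset
of overtraining, and the validation set is held out entirely to assess
predictivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FourWaySplit", "make_splits", "SUBSET_NAMES"]

SUBSET_NAMES = ("active_training", "passive_training", "calibration", "validation")


@dataclass(frozen=True)
class FourWaySplit:
    active_training: np.ndarray
    passive_training: np.ndarray
    calibration: np.ndarray
    validation: np.ndarray

    def subsets(self):
        return {name: getattr(self, name) for name in SUBSET_NAMES}

    @property
    def n(self) -> int:
        return sum(len(v) for v in self.subsets().values())

    def validate(self) -> None:
        idx = np.concatenate([getattr(self, name) for name in SUBSET_NAMES])
        if len(np.unique(idx)) != len(idx):
            raise ValueError("split subsets overlap")


def make_splits(n_compounds: int, k: int, seed: int) -> list[FourWaySplit]:
    """Draw ``k`` independent seeded random four-way splits of ``n_compounds``.

    Subset sizes are as even as ``n`` allows (each within +-2 of n/4).
    """
    if n_compounds < 8:
        raise ValueError("need at least 8 compounds to form a four-way split")
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = np.random.SeedSequence(seed).spawn(k)
    base, rem = divmod(n_compounds, 4)
    sizes = [base + (i < rem) for i in range(4)]
    bounds = np.cumsum([0] + sizes)
    splits = []
    for seq in seqs:
        perm = np.random.default_rng(seq).permutation(n_compounds)
        parts = [np.sort(perm[bounds[i] : bounds[i + 1]]) for i in range(4)]
        splits.append(FourWaySplit(*parts))
    return splits
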