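"""Optimal-descriptor core: correlation-weight table, DCW, and the fitted line.

The optimal descriptor of a compound is

    DCW(T, N) = sum CW(S_k) + sum CW(SS_k) + sum CW(SSS_k)

a sum of real-valued correlation weights over the compound's non-rare
single/pair/triple SMILES attributes (with multiplicity). ``T`` is the
rarity threshold: an attribute seen in fewer than ``T`` distinct
active-training compounds is "rare", its weight is pinned at zero and it
never contributes. ``N`` is the number of Monte Carlo epochs that produced
the weights.

The endpoint model is the semi-correlation line y = C0 + C1 * DCW fitted by
ordinary least squares of the binary label on the descriptor over the
active training set; a compound is classified active when y >= 0.5.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .attributes import DEFAULT_DIALECT, AttributeKey, Dialect, profile_smiles

__all__ = [
    "CWEntry",
    "CorrelationWeightTable",
    "build_vocabulary",
    "compute_dcw",
    "fit_line",
    "DegenerateDescriptorError",
    "SemiCorrelationModel",
]


class DegenerateDescriptorError(ValueError):
    """The descriptor has zero variance on the fitting set."""


@dataclass
class CWEntry:
    cw: float = 0.0
    document_frequency: int = 0
    rare: bool = False


@dataclass
class CorrelationWeightTable:
    """Map from :class:`AttributeKey` to correlation weight + bookkeeping.

    Rare entries always carry ``cw == 0`` and are never updated; lookups of
    keys absent from the table (attributes never seen in active training)
    return 0, so prediction-time novelty is silently neutral.
    """

    entries: dict = field(default_factory=dict)

    def cw(self, key: AttributeKey) -> float:
        e = self.entries.get(key)
        if e is None or e.rare:
            return 0.0
        return e.cw

    def non_rare_keys(self) -> list[AttributeKey]:
        """Deterministically ordered (kind, atoms) list of usable attributes."""
        return sorted(k for k, e in self.entries.items() if not e.rare)

    def set_weights(self, weights: Mapping[AttributeKey, float]) -> None:
        for key, w in weights.items():
            e = self.entries[key]
            if e.rare:
                raise ValueError(f"cannot set weight of rare attribute {key}")
            e.cw = float(w)

    def __len__(self) -> int:
        return len(self.entries)


def build_vocabulary(profiles: Iterable[Counter], T: int) -> CorrelationWeightTable:
    """Build the attribute vocabulary from active-training profiles.

    Rarity is assessed by document frequency: an attribute is non-rare iff
    it occurs in at least ``T`` distinct active-training compounds. Weights
    are left at 0 (unset); the optimizer fills them.
    """
    if T < 1:
        raise ValueError("T must be a positive integer")
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cannot build a vocabulary from an empty profile collection")
    df: Counter = Counter()
    for p in profiles:
        df.update(set(p))
    table = CorrelationWeightTable()
    for key, n in df.items():
        table.entries[key] = CWEntry(cw=0.0, document_frequency=n, rare=n < T)
    return table


def compute_dcw(profile: Counter, table: CorrelationWeightTable) -> float:
    """Sum of multiplicity x weight over the profile's non-rare attributes."""
    return float(sum(mult * table.cw(key) for key, mult in profile.items()))


def fit_line(dcw_values: Sequence[float], labels: Sequence[float]) -> tuple[float, float]:
    """Ordinary least squares of the binary label on the descriptor.

    Returns ``(C0, C1)``. A constant label vector gives the degenerate but
    well-defined line (label, 0); a constant descriptor is an error since
    the slope is then unidentifiable.
    """
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dcw_values and labels must be equal-length 1-d sequences")
    if x.size < 2:
        raise ValueError("need at least 2 points to fit the semi-correlation line")
    if np.ptp(y) == 0:
        return float(y[0]), 0.0
    xc = x - x.mean()
    vx = float(xc @ xc)
    if vx == 0.0:
        raise DegenerateDescriptorError("descriptor has zero variance on the fitting set")
    c1 = float(xc @ (y - y.mean())) / vx
    c0 = float(y.mean() - c1 * x.mean())
    return c0, c1


@dataclass
class SemiCorrelationModel:
    """A frozen, deployable semi-correlation classifier.

    Holds the fitted correlation-weight table, the rarity threshold ``T``,
    the epoch count ``N`` (with the calibration-selected ``best_epoch``),
    the line coefficients ``C0, C1`` and the 0.5 decision threshold.
    """

    table: CorrelationWeightTable
    T: int
    n_epochs: int
    C0: float
    C1: float
    best_epoch: int | None = None
    threshold: float = 0.5
    dialect: Dialect = DEFAULT_DIALECT

    def dcw(self, profile: Counter) -> float:
        return compute_dcw(profile, self.table)

    def predict_profile(self, profile: Counter) -> tuple[float, int]:
        """Return (y, category): y = C0 + C1*DCW, active iff y >= threshold."""
        y = self.C0 + self.C1 * self.dcw(profile)
        return y, int(y >= self.threshold)

    def predict_profiles(self, profiles: Sequence[Counter]) -> tuple[np.ndarray, np.ndarray]:
        ys = np.array([self.C0 + self.C1 * self.dcw(p) for p in profiles], dtype=float)
        return ys, (ys >= self.threshold).astype(int)

    def predict_smiles(self, smiles: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        return self.predict_profiles([profile_smiles(s, self.dialect) for s in smiles])

    def unknown_attribute_count(self, profile: Counter) -> int:
        """Occurrences (with multiplicity) of attributes never seen in training."""
        return int(
            sum(mult for key, mult in profile.items() if key not in self.table.entries)
        )

    # --- plain-text serialization ----------------------------------------
    # Header lines are "key<TAB>value"; each attribute line is
    # kind, cw, document_frequency, rare, then the atoms (tab separated;
    # arity is implied by kind). repr() round-trips floats bit-exactly.

    def to_text(self, fh: TextIO) -> None:
        fh.write("# semicorr model v1\n")
        fh.write(f"T\t{self.T}\n")
        fh.write(f"N\t{self.n_epochs}\n")
        fh.write(f"best_epoch\t{'' if self.best_epoch is None else self.best_epoch}\n")
        fh.write(f"C0\t{self.C0!r}\n")
        fh.write(f"C1\t{self.C1!r}\n")
        fh.write(f"threshold\t{self.threshold!r}\n")
        for key in sorted(self.table.entries):
            e = self.table.entries[key]
            fields = [key.kind, repr(e.cw), str(e.document_frequency), str(int(e.rare))]
            fields.extend(key.atoms)
            fh.write("\t".join(fields) + "\n")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            self.to_text(fh)

    @classmethod
    def from_text(cls, fh: TextIO) -> "SemiCorrelationModel":
        header: dict[str, str] = {}
        table = CorrelationWeightTable()
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in {"S", "SS", "SSS"}:
                kind, cw, df, rare, *atoms = parts
                key = AttributeKey(kind, tuple(atoms))
                table.entries[key] = CWEntry(float(cw), int(df), bool(int(rare)))
            else:
                header[parts[0]] = parts[1] if len(parts) > 1 else ""
        best = header.get("best_epoch", "")
        return cls(
            table=table,
            T=int(header["T"]),
            n_epochs=int(header["N"]),
            C0=float(header["C0"]),
            C1=float(header["C1"]),
            best_epoch=int(best) if best != "" else None,
            threshold=float(header.get("threshold", "0.5")),
        )

    @classmethod
    def load(cls, path) -> "SemiCorrelationModel":
        with open(path) as fh:
            return cls.from_text(fh)
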