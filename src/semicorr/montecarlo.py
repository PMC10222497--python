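"""Monte Carlo optimization of correlation weights.

The optimizer is a greedy, seeded coordinate search. One *epoch* visits
every non-rare attribute once in seeded-random order; each visit proposes
``cw' = cw + u`` with ``u`` uniform in ``[-step, +step]``, refits the
semi-correlation line C0/C1 on the active training set, and keeps the move
iff the target function (TF0 on the two training sets, or TF1 which adds
the calibration-set IIC) does not decrease. Non-finite objectives always
reject, so the running objective is non-decreasing across accepted moves.

Epoch histories record the objective plus per-set correlation coefficients
and Matthews correlation coefficients for all four subsets; validation-set
numbers are reporting-only and never feed back into the search. The model
returned is the snapshot from the epoch with the maximal calibration-set
MCC — the point where overtraining begins — rather than the final epoch.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import objectives
from .descriptor import (
    CorrelationWeightTable,
    SemiCorrelationModel,
    build_vocabulary,
    fit_line,
)
from .splits import FourWaySplit

__all__ = [
    "OptimizerConfig",
    "EpochRecord",
    "optimize",
    "detect_overtraining",
    "evaluate_objective",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs of the Monte Carlo search.

    ``T`` (rarity threshold) and the TF0 penalty / IIC weight come from the
    method definition; epoch count, step size and the uniform initialization
    range are free choices of the search and are exposed here.
    """

    target: Literal["tf0", "tf1"] = "tf1"
    T: int = 1
    n_epochs: int = 40
    step: float = 0.2
    init_low: float = 0.5
    init_high: float = 1.5
    seed: int = 0
    tf0_penalty: float = objectives.TF0_PENALTY
    iic_weight: float = objectives.IIC_WEIGHT

    def __post_init__(self):
        if self.target not in ("tf0", "tf1"):
            raise ValueError("target must be 'tf0' or 'tf1'")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.init_low > self.init_high:
            raise ValueError("init_low must not exceed init_high")
        if self.T < 1:
            raise ValueError("T must be a positive integer")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be non-negative")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    tf: float
    r_at: float
    r_pt: float
    r_c: float
    r_v: float
    mcc_at: float
    mcc_pt: float
    mcc_c: float
    mcc_v: float


def evaluate_objective(
    dcw_at: np.ndarray,
    y_at: np.ndarray,
    dcw_pt: np.ndarray,
    y_pt: np.ndarray,
    dcw_c: np.ndarray | None,
    y_c: np.ndarray | None,
    target: str = "tf1",
    tf0_penalty: float = objectives.TF0_PENALTY,
    iic_weight: float = objectives.IIC_WEIGHT,
) -> float:
    """Reference objective: composed from the public objective functions.

    Returns -inf whenever any required correlation is undefined (constant
    series), so a degenerate proposal is always rejected. The optimizer's
    inlined fast path must agree with this function; tests enforce it.
    """
    try:
        c0, c1 = fit_line(dcw_at, y_at)
        if c1 == 0.0:
            return -math.inf
        calc_at = c0 + c1 * np.asarray(dcw_at, float)
        calc_pt = c0 + c1 * np.asarray(dcw_pt, float)
        r_at = objectives.pearson_r(y_at, calc_at)
        r_pt = objectives.pearson_r(y_pt, calc_pt)
        tf = objectives.tf0(r_at, r_pt, tf0_penalty)
        if target == "tf1":
            calc_c = c0 + c1 * np.asarray(dcw_c, float)
            iic_c = objectives.iic(y_c, calc_c)
            tf = objectives.tf1(tf, iic_c, iic_weight)
    except (objectives.UndefinedCorrelationError, ValueError):
        return -math.inf
    return tf if math.isfinite(tf) else -math.inf


class _SetData:
    """Per-subset dense attribute-count matrix and label statistics."""

    def __init__(self, profiles, labels, index, n_attrs):
        n = len(profiles)
        X = np.zeros((n, n_attrs), order="F")
        for i, prof in enumerate(profiles):
            for key, mult in prof.items():
                j = index.get(key)
                if j is not None:
                    X[i, j] = mult
        self.X = X
        self.y = np.asarray(labels, dtype=float)
        self.n = n
        self.ymean = self.y.mean()
        self.yc = self.y - self.ymean
        self.syy = float(self.yc @ self.yc)
        self.dcw = np.zeros(n)

    def reset(self, cw: np.ndarray) -> None:
        self.dcw = self.X @ cw

    def shift(self, j: int, u: float) -> np.ndarray:
        """Trial descriptor vector after perturbing weight j by u."""
        return self.dcw + u * self.X[:, j]

    def commit(self, j: int, u: float) -> None:
        self.dcw += u * self.X[:, j]


def _fast_objective(at, pt, c, tmp_at, tmp_pt, tmp_c, target, penalty, iic_w):
    """Inlined objective on trial descriptor vectors; mirrors
    :func:`evaluate_objective` exactly."""
    n = at.n
    xm = tmp_at.mean()
    sxx = float(tmp_at @ tmp_at) - n * xm * xm
    if sxx <= 0.0 or at.syy == 0.0:
        return -math.inf
    cov = float(at.yc @ tmp_at)
    if cov == 0.0:
        return -math.inf  # zero slope: constant calculated series
    c1 = cov / sxx
    c0 = at.ymean - c1 * xm
    r_at = abs(cov) / math.sqrt(at.syy * sxx)
    sgn = 1.0 if c1 > 0 else -1.0

    xm_pt = tmp_pt.mean()
    sxx_pt = float(tmp_pt @ tmp_pt) - pt.n * xm_pt * xm_pt
    if sxx_pt <= 0.0 or pt.syy == 0.0:
        return -math.inf
    cov_pt = float(pt.yc @ tmp_pt)
    r_pt = sgn * cov_pt / math.sqrt(pt.syy * sxx_pt)

    r_at = min(1.0, r_at)
    r_pt = min(1.0, max(-1.0, r_pt))
    tf = r_at + r_pt - abs(r_at - r_pt) * penalty
    if target == "tf1":
        xm_c = tmp_c.mean()
        sxx_c = float(tmp_c @ tmp_c) - c.n * xm_c * xm_c
        if sxx_c <= 0.0 or c.syy == 0.0:
            return -math.inf
        cov_c = float(c.yc @ tmp_c)
        r_c = sgn * cov_c / math.sqrt(c.syy * sxx_c)
        r_c = min(1.0, max(-1.0, r_c))
        delta = c.y - (c0 + c1 * tmp_c)
        neg = delta < 0
        n_neg = int(neg.sum())
        mae_neg = float(-delta[neg].sum() / n_neg) if n_neg else 0.0
        n_pos = delta.size - n_neg
        mae_pos = float(np.abs(delta[~neg]).sum() / n_pos) if n_pos else 0.0
        hi = max(mae_neg, mae_pos)
        iic_c = r_c if hi == 0.0 else r_c * min(mae_neg, mae_pos) / hi
        tf += iic_w * iic_c
    return tf if math.isfinite(tf) else -math.inf


def _safe_r(y: np.ndarray, calc: np.ndarray) -> float:
    try:
        return objectives.pearson_r(y, calc)
    except (objectives.UndefinedCorrelationError, ValueError):
        return math.nan


def _mcc(y: np.ndarray, calc: np.ndarray, threshold: float = 0.5) -> float:
    from .metrics import mcc_score

    return mcc_score(y.astype(int), (calc >= threshold).astype(int))


def optimize(
    profiles: Sequence[Counter],
    labels: Sequence[int],
    split: FourWaySplit,
    config: OptimizerConfig = OptimizerConfig(),
) -> tuple[SemiCorrelationModel, list[EpochRecord]]:
    """Fit correlation weights on a four-way split.

    ``profiles`` and ``labels`` are aligned over the whole compound table;
    ``split`` selects the four roles. Returns the overtraining-guarded model
    (snapshot at the calibration-MCC peak) and the full epoch history.
    """
    labels = np.asarray(labels, dtype=float)
    at_profiles = [profiles[i] for i in split.active_training]
    table = build_vocabulary(at_profiles, config.T)
    keys = table.non_rare_keys()
    if not keys:
        raise ValueError("no non-rare attributes: vocabulary is empty at this T")
    index = {k: j for j, k in enumerate(keys)}
    K = len(keys)

    sets = {}
    for name in ("active_training", "passive_training", "calibration", "validation"):
        idx = getattr(split, name)
        sets[name] = _SetData([profiles[i] for i in idx], labels[idx], index, K)
    at, pt, cal, val = (
        sets["active_training"],
        sets["passive_training"],
        sets["calibration"],
        sets["validation"],
    )

    rng = np.random.default_rng(config.seed)
    cw = rng.uniform(config.init_low, config.init_high, size=K)
    for s in sets.values():
        s.reset(cw)

    if config.n_epochs == 0:
        c0, c1 = fit_line(at.dcw, at.y)
        table.set_weights(dict(zip(keys, cw)))
        model = SemiCorrelationModel(
            table=table, T=config.T, n_epochs=0, C0=c0, C1=c1, best_epoch=None
        )
        return model, []

    penalty, iic_w = config.tf0_penalty, config.iic_weight
    tf_cur = _fast_objective(
        at, pt, cal, at.dcw, pt.dcw, cal.dcw, config.target, penalty, iic_w
    )

    history: list[EpochRecord] = []
    best_mcc_c = -math.inf
    best = None  # (epoch, cw copy, C0, C1)

    for epoch in range(config.n_epochs):
        order = rng.permutation(K)
        for j in order:
            u = rng.uniform(-config.step, config.step)
            tmp_at = at.shift(j, u)
            tmp_pt = pt.shift(j, u)
            tmp_c = cal.shift(j, u) if config.target == "tf1" else cal.dcw
            tf_new = _fast_objective(
                at, pt, cal, tmp_at, tmp_pt, tmp_c, config.target, penalty, iic_w
            )
            if math.isfinite(tf_new) and tf_new >= tf_cur:
                tf_cur = tf_new
                cw[j] += u
                at.dcw = tmp_at
                pt.dcw = tmp_pt
                if config.target == "tf1":
                    cal.dcw = tmp_c
                else:
                    cal.commit(j, u)
                val.commit(j, u)

        c0, c1 = fit_line(at.dcw, at.y)
        calcs = {name: c0 + c1 * s.dcw for name, s in sets.items()}
        rec = EpochRecord(
            epoch=epoch,
            tf=tf_cur,
            r_at=_safe_r(at.y, calcs["active_training"]),
            r_pt=_safe_r(pt.y, calcs["passive_training"]),
            r_c=_safe_r(cal.y, calcs["calibration"]),
            r_v=_safe_r(val.y, calcs["validation"]),
            mcc_at=_mcc(at.y, calcs["active_training"]),
            mcc_pt=_mcc(pt.y, calcs["passive_training"]),
            mcc_c=_mcc(cal.y, calcs["calibration"]),
            mcc_v=_mcc(val.y, calcs["validation"]),
        )
        history.append(rec)
        if rec.mcc_c > best_mcc_c:
            best_mcc_c = rec.mcc_c
            best = (epoch, cw.copy(), c0, c1)

    best_epoch, best_cw, best_c0, best_c1 = best
    assert best_epoch == detect_overtraining(history)
    table.set_weights(dict(zip(keys, best_cw)))
    model = SemiCorrelationModel(
        table=table,
        T=config.T,
        n_epochs=config.n_epochs,
        C0=best_c0,
        C1=best_c1,
        best_epoch=best_epoch,
    )
    return model, history


def detect_overtraining(history: Sequence[EpochRecord]) -> int:
    """Epoch index with maximal calibration-set MCC (earliest on ties).

    Optimization past this point improves the training sets while the
    calibration set degrades — the start of overtraining.
    """
    if not history:
        raise ValueError("empty history")
    mccs = np.array([rec.mcc_c for rec in history])
    return int(np.argmax(mccs))
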