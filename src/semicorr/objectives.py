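"""Monte Carlo target functions and their ingredients.

The optimizer maximises one of two scalar objectives built from Pearson
correlations between observed {0,1} endpoints and calculated y values:

    TF0 = r_AT + r_PT - |r_AT - r_PT| * 0.1
    TF1 = TF0 + IIC_C * 0.5

where r_AT / r_PT are computed on the active and passive training sets and
IIC_C, the index of ideality of correlation, on the calibration set:

    IIC_C = r_C * min(MAE-, MAE+) / max(MAE-, MAE+)

with MAE- / MAE+ the mean absolute residuals over the negative and
non-negative residual subsets (residual = observed - calculated; a residual
of exactly 0 belongs to the "+" subset). The min/max runs over the two
non-negative subset MAEs, so the ratio lies in [0, 1] and |IIC| <= |r|:
IIC rewards correlations whose errors are balanced around the line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ResidualSplit",
    "pearson_r",
    "residual_split",
    "iic",
    "tf0",
    "tf1",
    "UndefinedCorrelationError",
]

TF0_PENALTY = 0.1
IIC_WEIGHT = 0.5


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (a constant series)."""


@dataclass(frozen=True)
class ResidualSplit:
    """Sign-split mean absolute residuals.

    ``mae_neg`` averages |residual| over residuals < 0, ``mae_pos`` over
    residuals >= 0; an empty subset contributes MAE 0 with count 0.
    """

    mae_neg: float
    mae_pos: float
    n_neg: int
    n_pos: int


def pearson_r(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Pearson product-moment correlation, raising on constant input."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(calculated, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length series of at least 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("undefined correlation: constant series")
    r = float(xc @ yc) / np.sqrt(sx * sy)
    return float(min(1.0, max(-1.0, r)))


def residual_split(observed: Sequence[float], calculated: Sequence[float]) -> ResidualSplit:
    obs = np.asarray(observed, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if obs.shape != calc.shape or obs.ndim != 1 or obs.size < 1:
        raise ValueError("need two equal-length non-empty series")
    delta = obs - calc
    neg = delta < 0
    n_neg = int(neg.sum())
    n_pos = int(delta.size - n_neg)
    mae_neg = float(np.abs(delta[neg]).mean()) if n_neg else 0.0
    mae_pos = float(np.abs(delta[~neg]).mean()) if n_pos else 0.0
    return ResidualSplit(mae_neg, mae_pos, n_neg, n_pos)


def iic(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Index of ideality of correlation.

    r scaled by min/max of the sign-subset MAEs. A perfect fit (both MAEs
    zero) returns r itself; one-signed residuals (one subset empty) give 0.
    """
    r = pearson_r(observed, calculated)
    rs = residual_split(observed, calculated)
    hi = max(rs.mae_neg, rs.mae_pos)
    if hi == 0.0:
        return r
    return r * min(rs.mae_neg, rs.mae_pos) / hi


def tf0(r_at: float, r_pt: float, penalty: float = TF0_PENALTY) -> float:
    """Sum of the two training-set correlations, penalising their gap."""
    return r_at + r_pt - abs(r_at - r_pt) * penalty


def tf1(tf0_value: float, iic_c: float, weight: float = IIC_WEIGHT) -> float:
    """TF0 plus the weighted calibration-set index of ideality."""
    return tf0_value + weight * iic_c
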