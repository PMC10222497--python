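"""scikit-learn estimator interface to the semi-correlation classifier.

``SemiCorrelationClassifier`` takes raw SMILES strings as ``X`` and binary
labels as ``y``. ``fit`` draws a seeded four-way split (or accepts one),
builds the attribute vocabulary from the active training quarter, runs the
Monte Carlo correlation-weight search, and freezes the snapshot from the
calibration-MCC peak. ``decision_function`` returns the continuous
semi-correlation value y = C0 + C1*DCW; ``predict`` thresholds it at 0.5.

The class follows sklearn conventions (get_params/set_params, trailing
underscore fitted attributes, clone-compatible constructor) so it composes
with sklearn model selection on lists of SMILES strings.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .attributes import profile_smiles
from .metrics import classification_stats, confusion
from .montecarlo import OptimizerConfig, optimize
from .splits import SUBSET_NAMES, FourWaySplit, make_splits

__all__ = ["SemiCorrelationClassifier"]


def _validate_inputs(X, y):
    X = np.asarray(X, dtype=object).ravel()
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have inconsistent lengths")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    return [str(s) for s in X], y.astype(int)


class SemiCorrelationClassifier(ClassifierMixin, BaseEstimator):
    """SMILES-attribute semi-correlation classifier.

    Parameters
    ----------
    T : int, default 1
        Rarity threshold; attributes seen in fewer than ``T`` distinct
        active-training compounds are excluded (weight pinned at 0).
        Typical values are 1-3.
    target : {"tf1", "tf0"}, default "tf1"
        Monte Carlo objective. ``tf0`` balances the active/passive training
        correlations; ``tf1`` additionally rewards calibration-set IIC,
        which favours models that keep predicting well on unseen data.
    n_epochs : int, default 40
        Monte Carlo epochs (one seeded pass over all non-rare attributes
        each). The returned model is rolled back to the calibration-MCC
        peak, so generous values are safe.
    step : float, default 0.2
        Half-width of the uniform weight perturbation.
    init_low, init_high : float, defaults 0.5, 1.5
        Uniform initialization range for the weights.
    random_state : int, default 0
        Seeds the split draw and the Monte Carlo search.

    Attributes
    ----------
    model_ : SemiCorrelationModel
        The frozen correlation-weight model (table, C0, C1, best epoch).
    history_ : pandas.DataFrame
        Per-epoch objective, correlation and MCC curves for all four sets.
    split_ : FourWaySplit
        The four-way split used for fitting.
    classes_ : ndarray of shape (2,)
    """

    def __init__(
        self,
        T: int = 1,
        target: str = "tf1",
        n_epochs: int = 40,
        step: float = 0.2,
        init_low: float = 0.5,
        init_high: float = 1.5,
        random_state: int = 0,
    ):
        self.T = T
        self.target = target
        self.n_epochs = n_epochs
        self.step = step
        self.init_low = init_low
        self.init_high = init_high
        self.random_state = random_state

    def fit(self, X: Sequence[str], y: Sequence[int], split: FourWaySplit | None = None):
        smiles, labels = _validate_inputs(X, y)
        seeds = np.random.SeedSequence(self.random_state).generate_state(2) % (2**31)
        if split is None:
            split = make_splits(len(smiles), k=1, seed=int(seeds[0]))[0]
        split.validate()
        profiles = [profile_smiles(s) for s in smiles]
        config = OptimizerConfig(
            target=self.target,
            T=self.T,
            n_epochs=self.n_epochs,
            step=self.step,
            init_low=self.init_low,
            init_high=self.init_high,
            seed=int(seeds[1]),
        )
        self.model_, history = optimize(profiles, labels, split, config)
        self.history_ = pd.DataFrame([vars(rec) for rec in history])
        self.split_ = split
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        self._check_fitted()
        ys, _ = self.model_.predict_smiles([str(s) for s in np.asarray(X, dtype=object).ravel()])
        return ys

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return (self.decision_function(X) >= self.model_.threshold).astype(int)

    def report(self, X: Sequence[str], y: Sequence[int]) -> pd.DataFrame:
        """Per-subset confusion counts and statistics for fitted data.

        Mirrors the standard report layout: one row per subset plus a
        'total' row, with TP/TN/FP/FN/N and sensitivity, specificity,
        accuracy, MCC.
        """
        self._check_fitted()
        smiles, labels = _validate_inputs(X, y)
        pred = self.predict(smiles)
        rows = []
        for name in SUBSET_NAMES:
            idx = getattr(self.split_, name)
            rows.append((name, labels[idx], pred[idx]))
        rows.append(("total", labels, pred))
        out = []
        for name, obs, prd in rows:
            c = confusion(obs, prd)
            s = classification_stats(c)
            out.append(
                {
                    "set": name,
                    "tp": c.tp,
                    "tn": c.tn,
                    "fp": c.fp,
                    "fn": c.fn,
                    "n": c.n,
                    "sensitivity": s.sensitivity,
                    "specificity": s.specificity,
                    "accuracy": s.accuracy,
                    "mcc": s.mcc,
                }
            )
        return pd.DataFrame(out)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this SemiCorrelationClassifier instance is not fitted yet")
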