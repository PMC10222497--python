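"""Epoch-history plots (optimization evolution curves)."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_history"]

_SET_LABELS = {
    "at": "active training",
    "pt": "passive training",
    "c": "calibration",
    "v": "validation",
}


def plot_history(history: pd.DataFrame, metric: str = "mcc", ax=None):
    """Plot per-set evolution of ``mcc`` or ``r`` across epochs.

    Marks the calibration peak (the overtraining onset) with a vertical
    line. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for suffix, label in _SET_LABELS.items():
        ax.plot(history["epoch"], history[f"{metric}_{suffix}"], label=label)
    best = int(history[f"{metric}_c"].idxmax())
    ax.axvline(history["epoch"].iloc[best], color="grey", ls="--", lw=1,
               label="calibration peak")
    ax.set_xlabel("epoch")
    ax.set_ylabel({"mcc": "MCC", "r": "Pearson r"}.get(metric, metric))
    ax.legend(fontsize=8)
    return ax
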