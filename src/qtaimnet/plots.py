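"""Basic figures: learning curves and parity plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def learning_curve_plot(table, metric: str = "MAE", ax=None):
    """Median metric vs training-set size, one line per arm (log-log)."""
    ax = ax or plt.gca()
    for arm, sub in table.groupby("arm"):
        med = sub.groupby("size")[metric].median()
        ax.plot(med.index, med.values, marker="o", label=arm)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("training set size")
    ax.set_ylabel(f"median test {metric}")
    ax.legend()
    return ax


def parity_plot(y_true, y_pred, ax=None):
    ax = ax or plt.gca()
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    lo = min(y_true.min(), y_pred.min())
    hi = max(y_true.max(), y_pred.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.scatter(y_true, y_pred, s=12, alpha=0.7)
    ax.set_xlabel("true")
    ax.set_ylabel("predicted")
    return ax
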