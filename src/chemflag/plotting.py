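"""Convenience plots: cumulative attribution curves and flagging trade-offs."""

from __future__ import annotations

import numpy as np


def plot_cumulative_importance(summary, ax=None, milestones=(0.5, 0.75, 0.9)):
    """Cumulative mean-|SHAP| contribution vs feature rank, with milestone
    lines at 50/75/90% of total importance."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.arange(1, len(summary.cumulative) + 1), summary.cumulative, lw=1.5)
    for q in milestones:
        ax.axhline(q, color="red", lw=0.8, ls="--")
    ax.set_xlabel("feature rank")
    ax.set_ylabel("cumulative contribution")
    ax.set_ylim(0, 1.02)
    return ax


def plot_flagging_tradeoff(by_rule, ax=None):
    """% flagged among misclassified vs correctly classified, per rule,
    across confidence thresholds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for rule, sub in by_rule.groupby("rule"):
        ax.plot(sub["confidence"], sub["pct_flagged_misclassified"], marker="o",
                label=f"{rule} (misclassified)")
        ax.plot(sub["confidence"], sub["pct_flagged_correct"], marker="x", ls="--",
                label=f"{rule} (correct)")
    ax.set_xlabel("class-probability threshold")
    ax.set_ylabel("% flagged")
    ax.legend(fontsize=7)
    return ax
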