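"""Diagnostic figures: per-cycle log-log fluctuation plots and group box plots."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dfa import DFAResult


def plot_loglog(results: dict[str, DFAResult], path: str, title: str = "") -> str:
    """One log-log fluctuation plot; each labelled curve shows its alpha."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, res in results.items():
        c = res.curve
        ok = c.fluctuations > 0
        ax.loglog(c.sizes[ok], c.fluctuations[ok], "o-", ms=3,
                  label=f"{label}: $\\alpha$={res.alpha:.3f}")
    ax.set_xlabel("window size n")
    ax.set_ylabel("F(n)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def plot_group_box(table: pd.DataFrame, channel: str, path: str) -> str:
    """Box plot of per-cycle alpha by group for one channel."""
    sub = table[table["channel"] == channel]
    groups = sorted(sub["group"].unique())
    data = [sub.loc[sub["group"] == g, "alpha"].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel(r"DFA $\alpha$")
    ax.set_title(channel)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
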