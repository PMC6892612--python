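"""Optional matplotlib figure hooks for the main result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_heritability_scatter(summary: pd.DataFrame, ax=None):
    """H² vs h² per condition, with the H² = h² diagonal."""
    ax = _axes(ax)
    ax.scatter(summary["h2"], summary["H2"], s=18)
    lim = (0, 1.02)
    ax.plot(lim, lim, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("narrow-sense heritability $h^2$")
    ax.set_ylabel("broad-sense heritability $H^2$")
    ax.set_xlim(*lim)
    ax.set_ylim(*lim)
    return ax


def plot_inheritance_fractions(summary: pd.DataFrame, ax=None):
    """Stacked per-condition inheritance-mode fractions.

    Expects one row per condition with one column per mode fraction
    (as written by the pipeline's inheritance summary).
    """
    from .inheritance import MODE_ORDER

    ax = _axes(ax)
    bottom = np.zeros(len(summary))
    for mode in MODE_ORDER:
        if mode not in summary.columns:
            continue
        vals = summary[mode].to_numpy(dtype=float)
        ax.bar(summary["condition"], vals, bottom=bottom, label=mode)
        bottom += vals
    ax.set_ylabel("fraction of separable crosses")
    ax.legend(fontsize=7)
    ax.tick_params(axis="x", rotation=90)
    return ax


def plot_maf_scatter(scatter: pd.DataFrame, low_threshold: float = 0.05, ax=None):
    """Panel MAF vs source-population MAF; significant sites highlighted."""
    ax = _axes(ax)
    sig = scatter["significant"].astype(bool)
    ax.scatter(scatter.loc[~sig, "maf_source"], scatter.loc[~sig, "maf_panel"],
               s=8, facecolors="none", edgecolors="tab:blue", label="all sites")
    ax.scatter(scatter.loc[sig, "maf_source"], scatter.loc[sig, "maf_panel"],
               s=10, color="tab:orange", label="significant")
    ax.axvline(low_threshold, color="tab:orange", lw=0.8)
    ax.set_xlabel("source-population MAF")
    ax.set_ylabel("diallel-panel MAF")
    ax.legend(fontsize=8)
    return ax
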