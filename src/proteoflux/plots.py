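"""Matplotlib views of the report tables: scatter, grouped bars, heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless backend; callers can save figures

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["proteostasis_scatter", "ontology_bars", "overlap_heatmap"]

_CLASS_COLORS = {
    "SynUp": "#1b9e77",
    "SynDown": "#66a61e",
    "DegUp": "#d95f02",
    "DegDown": "#e7298a",
    "Indeterminate": "#999999",
}


def proteostasis_scatter(scatter: pd.DataFrame, ax=None, significant_only=False):
    """Δabundance (x) vs Δturnover (y) with quadrant-coded colors."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    data = scatter[scatter["significant"]] if significant_only else scatter
    for cls, grp in data.groupby("regulation_class"):
        ax.scatter(
            grp["mean_abundance_fc"], grp["mean_turnover_fc"],
            s=18 + 4 * np.sqrt(grp["n_abundance"]),
            c=_CLASS_COLORS.get(cls, "#999999"), label=cls, alpha=0.8,
            edgecolors="none",
        )
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("mean scaled Δabundance")
    ax.set_ylabel("mean scaled Δturnover")
    ax.legend(frameon=False, fontsize=8)
    return ax


def ontology_bars(bars: pd.DataFrame, term_id: str, ax=None):
    """Per-member abundance and turnover scaled FCs for one term."""
    data = bars[bars["term_id"] == term_id]
    if data.empty:
        raise ValueError(f"no bar rows for term {term_id!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.3 * data["protein_id"].nunique()), 4))
    pivot = data.pivot_table(index="protein_id", columns="series",
                             values="fc_scaled", aggfunc="mean")
    pivot.plot.bar(ax=ax, color={"abundance": "#7570b3", "turnover": "#d95f02"})
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("scaled FC")
    ax.set_title(term_id)
    return ax


def overlap_heatmap(overlap: pd.DataFrame, ax=None):
    """Percent of proteins shared across terms (row-normalized)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(overlap.to_numpy(), vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(len(overlap.columns)))
    ax.set_xticklabels(overlap.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(overlap.index)))
    ax.set_yticklabels(overlap.index, fontsize=7)
    plt.colorbar(im, ax=ax, label="% shared proteins")
    return ax
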