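"""Diagnostic plots (optional; nothing downstream depends on them)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def den_histogram(gene_counts: pd.DataFrame, path: str | Path) -> None:
    """Histograms of per-gene up/down DEN on a log count axis."""
    plt = _axes()
    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    for ax, direction in zip(axes, ("down", "up")):
        counts = gene_counts[f"{direction}_count"]
        ax.hist(counts, bins=min(50, counts.max() + 1), color="steelblue")
        ax.set_yscale("log")
        ax.set_xlabel(f"{direction}-regulation DEN")
    axes[0].set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def den_feature_scatter(gene_counts: pd.DataFrame, feature: pd.Series,
                        direction: str, path: str | Path,
                        feature_name: str = "feature") -> None:
    """Scatter of a per-gene feature against directional DEN."""
    plt = _axes()
    merged = pd.concat(
        [gene_counts[f"{direction}_count"].rename("den"),
         feature.rename("feature")], axis=1, join="inner").dropna()
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(merged["den"], merged["feature"], s=4, alpha=0.4,
               color="darkred")
    ax.set_xscale("symlog")
    ax.set_xlabel(f"{direction}-regulation DEN")
    ax.set_ylabel(feature_name)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
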