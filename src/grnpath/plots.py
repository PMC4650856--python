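"""Optional figures: cutoff-scan fitness curves and biomarker heatmaps."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["plot_cutoff_scan", "plot_biomarker_heatmap"]


def plot_cutoff_scan(scan: pd.DataFrame, path: str | Path) -> None:
    """Two-row panel: power-law R^2 and edge counts versus cutoff,
    one row per regulator sub-network (in-degree fits)."""
    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True)
    for row, name in enumerate(("miRNA_regulator", "TF_regulator")):
        sub = scan[(scan["subnetwork"] == name) & (scan["direction"] == "in_degree")]
        axes[row, 0].plot(sub["cutoff"], sub["r_squared"], marker="o")
        axes[row, 0].set_ylabel(f"{name}\nR$^2$")
        axes[row, 1].plot(sub["cutoff"], sub["n_edges"], marker="o", color="tab:orange")
        axes[row, 1].set_ylabel("edges")
    for ax in axes[1]:
        ax.set_xlabel("|alpha| cutoff")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_biomarker_heatmap(
    matrix: ExpressionMatrix,
    gene_set: Sequence[str],
    labels: Mapping[str, str],
    path: str | Path,
) -> None:
    """Expression heatmap of a biomarker set, samples grouped by class."""
    samples = sorted((s for s in matrix.sample_ids if s in labels),
                     key=lambda s: (labels[s], s))
    data = matrix.values.loc[list(gene_set), samples]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(samples)),
                                    max(2, 0.3 * len(gene_set))))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(np.arange(len(gene_set)), labels=list(gene_set), fontsize=7)
    ax.set_xticks(np.arange(len(samples)),
                  labels=[f"{labels[s]}:{s}" for s in samples], rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
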