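"""Static figure output for the pipeline run directory."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def enrichment_barplot(summary: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Proportional-overlap bars per (class, mark, cell); faint = not significant."""
    if summary.empty:
        return
    labels = [
        f"{r.pcre_class}/{r.mark}/{r.cell}" for r in summary.itertuples()
    ]
    values = summary["mean_proportional_overlap"].to_numpy()
    sig = summary["mean_fdr"].to_numpy() < alpha
    colors = ["#c23b22" if s else "#e8b4b0" for s in sig]
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(labels)), 4))
    ax.bar(np.arange(len(labels)), values, color=colors)
    ax.set_xticks(np.arange(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("proportional overlap")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def correlation_heatmap(corr: pd.DataFrame, order: list[str], path) -> None:
    ordered = corr.loc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(ordered.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)))
    ax.set_yticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=7)
    ax.set_yticklabels(order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def density_plot(densities: dict, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for cls, (grid, dens) in densities.items():
        ax.plot(grid / 1e6, dens * 1e6, label=cls)
    ax.set_xlabel("|distance from viewpoint| (Mb)")
    ax.set_ylabel("density (per Mb)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
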