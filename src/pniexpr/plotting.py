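"""Optional figures: volcano plot, clustered heatmap, ROC curve.

Plotting is a convenience layer over the tested core; nothing downstream
depends on it.  All functions take an explicit path and write a PNG/PDF
via the non-interactive Agg backend.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .cluster import Dendrogram  # noqa: E402


def volcano(deg_table, path, p_cut: float = 0.01, fc_cut: float = 2.0) -> None:
    """log2FC vs -log10 adjusted p, significant genes highlighted."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x = deg_table["log2fc"]
    y = -np.log10(deg_table["p_adj"].clip(lower=1e-300))
    sig = (deg_table["p_adj"] < p_cut) & (np.abs(x) > np.log2(fc_cut))
    ax.scatter(x[~sig], y[~sig], s=6, c="grey", alpha=0.5, linewidths=0)
    ax.scatter(x[sig], y[sig], s=8, c="crimson", linewidths=0)
    ax.axhline(-np.log10(p_cut), ls="--", c="k", lw=0.7)
    for v in (np.log2(fc_cut), -np.log2(fc_cut)):
        ax.axvline(v, ls="--", c="k", lw=0.7)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap(scaled_values, sample_dendrogram: Dendrogram, path) -> None:
    """Green-low / red-high heatmap with samples in dendrogram leaf order."""
    order = sample_dendrogram.leaf_order()
    data = scaled_values.loc[:, order]
    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(data.values, aspect="auto", cmap="RdYlGn_r",
                   vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=5)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="scaled expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def roc_plot(roc_result, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    fpr = 1.0 - roc_result.specificity
    order = np.argsort(fpr)
    ax.plot(fpr[order], roc_result.sensitivity[order], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls=":", c="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc_result.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
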