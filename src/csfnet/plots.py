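"""Minimal plotting helpers (volcano, module-trait heatmap, downsampled TOM)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["volcano", "trait_heatmap", "tom_heatmap"]


def volcano(table: pd.DataFrame, alpha: float = 0.05, ax=None):
    """log2 fold change vs -log10 t-test p, significant proteins highlighted."""
    ax = ax or plt.subplots(figsize=(5, 4))[1]
    sig = table["significant"]
    ax.scatter(table.loc[~sig, "log2_fold_change"],
               -np.log10(table.loc[~sig, "t_p"]), s=6, c="grey", alpha=0.5)
    ax.scatter(table.loc[sig, "log2_fold_change"],
               -np.log10(table.loc[sig, "t_p"]), s=8, c="crimson")
    ax.set_xlabel("log2 fold change (AD - CU)")
    ax.set_ylabel("-log10 p")
    return ax


def trait_heatmap(table: pd.DataFrame, approach: int = 1, ax=None):
    """Standardized-beta heatmap with unadjusted p-values printed in cells."""
    sub = table[table["approach"] == approach]
    beta = sub.pivot(index="module", columns="outcome", values="std_beta")
    pvals = sub.pivot(index="module", columns="outcome", values="p")
    ax = ax or plt.subplots(figsize=(1 + beta.shape[1], 1 + 0.4 * beta.shape[0]))[1]
    im = ax.imshow(beta.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(beta.shape[1]), beta.columns, rotation=45, ha="right")
    ax.set_yticks(range(beta.shape[0]), beta.index)
    for i in range(beta.shape[0]):
        for j in range(beta.shape[1]):
            ax.text(j, i, f"{pvals.iloc[i, j]:.2g}", ha="center", va="center",
                    fontsize=6)
    plt.colorbar(im, ax=ax, label="standardized beta")
    return ax


def tom_heatmap(tom_matrix: np.ndarray, labels=None, max_nodes: int = 400, ax=None):
    """Topological overlap heatmap, downsampled for large networks."""
    t = np.asarray(tom_matrix)
    n = t.shape[0]
    if n > max_nodes:
        idx = np.linspace(0, n - 1, max_nodes).astype(int)
        t = t[np.ix_(idx, idx)]
    ax = ax or plt.subplots(figsize=(5, 5))[1]
    ax.imshow(1 - t, cmap="YlOrRd_r")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
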