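"""Minimal figure helpers: significance-masked correlogram and clustered
correlation heatmap (blue = positive, red = negative)."""

from __future__ import annotations

import numpy as np

from .correlation import ClusterTree, CorrelationMatrix


def correlogram(mat: CorrelationMatrix, ax=None):
    """Circle-style correlogram; only significant correlations are drawn."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    k = len(mat.genes)
    rho = mat.rho.to_numpy()
    mask = mat.mask.to_numpy() | np.eye(k, dtype=bool)
    for i in range(k):
        for j in range(k):
            if not mask[i, j]:
                continue
            r = rho[i, j]
            color = plt.cm.RdBu((r + 1) / 2)  # blue positive, red negative
            ax.scatter(j, k - 1 - i, s=1500 * abs(r) / k, c=[color])
    ax.set_xticks(range(k), mat.genes, rotation=90)
    ax.set_yticks(range(k), mat.genes[::-1])
    ax.set_xlim(-0.5, k - 0.5)
    ax.set_ylim(-0.5, k - 0.5)
    ax.set_title(f"{mat.treatment}: Spearman rho (p < {mat.alpha})")
    return ax


def clustered_heatmap(mat: CorrelationMatrix, tree: ClusterTree, ax=None):
    """Heatmap of rho with rows/columns in dendrogram leaf order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    order = tree.leaf_order
    rho = mat.rho.loc[order, order].to_numpy()
    im = ax.imshow(rho, cmap="RdBu", vmin=-1, vmax=1)
    ax.set_xticks(range(len(order)), order, rotation=90)
    ax.set_yticks(range(len(order)), order)
    ax.figure.colorbar(im, ax=ax, label="Spearman rho")
    ax.set_title(f"{mat.treatment}: clustered co-expression")
    return ax
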