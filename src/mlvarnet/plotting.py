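"""Minimal matplotlib views of networks and centrality distributions."""

from __future__ import annotations

import numpy as np

from .bootstrap import GROUP_LABELS, CentralityResult
from .graph import NetworkGraph


def plot_adjacency(graph: NetworkGraph, ax=None, annotate: bool = True):
    """Heatmap of the signed adjacency matrix (rows: target at t,
    columns: source at t-1); non-significant cells are hatched out."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 4.5))
    w = graph.weights
    lim = max(1e-12, np.max(np.abs(w)))
    im = ax.imshow(w, cmap="RdYlGn", vmin=-lim, vmax=lim)
    J = graph.n_nodes
    ax.set_xticks(range(J), graph.labels, rotation=45, ha="right")
    ax.set_yticks(range(J), graph.labels)
    ax.set_xlabel("source (t-1)")
    ax.set_ylabel("target (t)")
    if annotate:
        for j in range(J):
            for k in range(J):
                txt = f"{w[j, k]:.2f}"
                if graph.mask is not None and not graph.mask[j, k]:
                    txt = f"({txt})"
                ax.text(k, j, txt, ha="center", va="center", fontsize=7)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"{graph.kind} network")
    return ax


def plot_centrality(result: CentralityResult, ax=None):
    """Betweenness per node and neuroticism group with 50%/95% intervals."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 3.5))
    J = len(result.labels)
    G = len(result.group_ids)
    width = 0.8 / G
    for gi, g in enumerate(result.group_ids):
        x = np.arange(J) + (gi - (G - 1) / 2) * width
        for lev, (lo, hi) in sorted(result.intervals.items(), reverse=True):
            ax.vlines(x, lo[gi], hi[gi],
                      lw=4 if lev == 50 else 1.5,
                      color=f"C{gi}", alpha=0.7 if lev == 50 else 0.4)
        ax.plot(x, result.estimate[gi], "o", ms=4, color=f"C{gi}",
                label=GROUP_LABELS[g])
    ax.set_xticks(range(J), result.labels, rotation=30, ha="right")
    ax.set_ylabel("betweenness")
    ax.legend(title="neuroticism", fontsize=8)
    return ax
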