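"""Directed signed weighted networks and their analysis.

A fitted transition matrix is read as an adjacency matrix: entry (j, k)
is the edge k -> j, the lag-1 effect of variable k on variable j. Edge
*strength* is the absolute weight; shortest-path distance between adjacent
nodes is 1/|weight|, so strong links are short. Betweenness centrality then
counts, for each ordered node pair, the fraction of shortest paths a node
lies on (Brandes accounting, equal fractional credit among ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NetworkGraph",
    "ComparisonResult",
    "IRFResult",
    "betweenness",
    "compare_networks",
    "irf",
    "export_graph",
    "read_graph_edgelist",
]

EXPORT_FORMATS = ("edgelist-tsv", "graphml", "dot")

#: weights at or below this magnitude are treated as absent edges, so that
#: numerically-zero coefficients (e.g. 1e-16 from a least-squares solve)
#: cannot create spurious shortest paths
ZERO_WEIGHT_TOL = 1e-12


@dataclass
class NetworkGraph:
    """Weighted directed network over the J observed variables.

    weights[j, k] is the signed weight of the edge k -> j. ``mask`` marks
    edges that pass a significance or magnitude threshold (display only;
    weights are always kept in full). ``pvalues`` is carried when the graph
    came from a significance-tested fit.
    """

    labels: list[str]
    weights: np.ndarray
    mask: np.ndarray | None = None
    kind: str = "fixed"  #: fixed | sd | individual | group
    pvalues: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        J = len(self.labels)
        if len(set(self.labels)) != J:
            raise ValueError("node labels must be unique")
        if self.weights.shape != (J, J):
            raise ValueError(f"weights must be {J}x{J}, got {self.weights.shape}")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.weights.shape:
                raise ValueError("mask shape must match weights")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def edge(self, source: str, target: str) -> float:
        """Weight of the edge source -> target."""
        j = self.labels.index(target)
        k = self.labels.index(source)
        return float(self.weights[j, k])

    def to_networkx(self, use_mask: bool = False, include_self_loops: bool = True) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        J = self.n_nodes
        for j in range(J):
            for k in range(J):
                if not include_self_loops and j == k:
                    continue
                w = self.weights[j, k]
                if abs(w) <= ZERO_WEIGHT_TOL:
                    continue
                if use_mask and self.mask is not None and not self.mask[j, k]:
                    continue
                attrs = {"weight": float(w), "sign": int(np.sign(w)), "distance": 1.0 / abs(w)}
                if self.mask is not None:
                    attrs["significant"] = bool(self.mask[j, k])
                if self.pvalues is not None:
                    attrs["p_value"] = float(self.pvalues[j, k])
                g.add_edge(self.labels[k], self.labels[j], **attrs)
        return g


def betweenness(graph: NetworkGraph, use_mask: bool = False) -> pd.Series:
    """Weighted directed betweenness centrality per node.

    Self-loops are removed and zero-weight edges are absent; the distance of
    an edge is the reciprocal of its absolute weight. Scores are raw pair
    counts (unnormalized), so a node on the single shortest path between one
    ordered pair scores 1. Defaults to the full weight matrix; set
    ``use_mask`` to restrict to masked (significant) edges.
    """
    g = graph.to_networkx(use_mask=use_mask, include_self_loops=False)
    scores = nx.betweenness_centrality(g, weight="distance", normalized=False)
    return pd.Series([scores[v] for v in graph.labels], index=graph.labels, name="betweenness")


@dataclass
class ComparisonResult:
    """Link-weight agreement between two networks on shared nodes."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_links: int
    labels: list[str]
    scatter: pd.DataFrame = field(repr=False)  #: source, target, weight_a, weight_b


def compare_networks(ga: NetworkGraph, gb: NetworkGraph) -> ComparisonResult:
    """Correlate corresponding link weights (including self-loops).

    Nodes are matched by label; networks are first restricted to the common
    label set. Both Pearson and Spearman coefficients are returned, with the
    aligned weight pairs for scatter plotting.
    """
    common = [l for l in ga.labels if l in gb.labels]
    if len(common) < 2 or len(common) ** 2 < 3:
        raise ValueError(
            f"need at least 3 comparable links, networks share only {len(common)} node(s)"
        )
    ia = [ga.labels.index(l) for l in common]
    ib = [gb.labels.index(l) for l in common]
    wa = ga.weights[np.ix_(ia, ia)].ravel()
    wb = gb.weights[np.ix_(ib, ib)].ravel()
    pr = stats.pearsonr(wa, wb)
    sr = stats.spearmanr(wa, wb)
    scatter = pd.DataFrame(
        {
            "source": np.tile(common, len(common)),
            "target": np.repeat(common, len(common)),
            "weight_a": wa,
            "weight_b": wb,
        }
    )
    return ComparisonResult(
        float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue),
        len(wa), common, scatter,
    )


@dataclass
class IRFResult:
    """Impulse responses: responses[h, j, k] = effect on j at horizon h of a
    unit impulse in k at horizon 0."""

    responses: np.ndarray  #: (H+1, J, J)
    spectral_radius: float
    warning: str | None = None


def irf(phi: np.ndarray, horizon: int) -> IRFResult:
    """Propagate a unit impulse through the lag-1 transition matrix.

    The horizon-h response matrix is phi**h; with spectral radius below one
    responses decay geometrically to zero. A spectral radius at or above one
    attaches a nonstationarity warning instead of raising.
    """
    phi = np.asarray(phi, dtype=float)
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rho = float(np.max(np.abs(np.linalg.eigvals(phi))))
    out = np.empty((horizon + 1, *phi.shape))
    out[0] = np.eye(phi.shape[0])
    for h in range(1, horizon + 1):
        out[h] = phi @ out[h - 1]
    msg = None
    if rho >= 1.0:
        msg = f"spectral radius {rho:.3f} >= 1: process nonstationary, responses do not decay"
        warnings.warn(msg)
    return IRFResult(out, rho, msg)


# ---------------------------------------------------------------------------
# Export


def _metadata_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in sorted(meta.items()))


def export_graph(
    graph: NetworkGraph,
    path: str | Path,
    format: str = "edgelist-tsv",
    metadata: dict | None = None,
) -> Path:
    """Write a network to disk.

    ``edgelist-tsv`` lists every ordered pair including self-loops with
    columns source, target, weight, p_value, significant (orientation:
    weight of row (source, target) is the effect of source at t-1 on target
    at t). ``graphml`` writes typed attributes; ``dot`` a quick-look
    Graphviz file. Output is byte-stable for fixed input.
    """
    path = Path(path)
    if format not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {format!r}; choose one of {EXPORT_FORMATS}")
    J = graph.n_nodes
    if format == "edgelist-tsv":
        rows = []
        for j in range(J):
            for k in range(J):
                rows.append(
                    {
                        "source": graph.labels[k],
                        "target": graph.labels[j],
                        "weight": repr(float(graph.weights[j, k])),
                        "p_value": "" if graph.pvalues is None else repr(float(graph.pvalues[j, k])),
                        "significant": "" if graph.mask is None else str(bool(graph.mask[j, k])),
                    }
                )
        body = pd.DataFrame(rows).to_csv(sep="\t", index=False)
        path.write_text(_metadata_lines(metadata) + body)
    elif format == "graphml":
        g = graph.to_networkx()
        g.graph["kind"] = graph.kind
        for k, v in (metadata or {}).items():
            g.graph[str(k)] = str(v)
        nx.write_graphml(g, path)
    else:  # dot
        lines = [_metadata_lines(metadata).rstrip("\n")] if metadata else []
        lines.append("digraph network {")
        for lab in graph.labels:
            lines.append(f'  "{lab}";')
        for j in range(J):
            for k in range(J):
                w = graph.weights[j, k]
                if w == 0.0:
                    continue
                style = "solid" if w > 0 else "dashed"
                lines.append(
                    f'  "{graph.labels[k]}" -> "{graph.labels[j]}" '
                    f'[weight={w:.6g}, label="{w:.3g}", style={style}];'
                )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    return path


def read_graph_edgelist(path: str | Path, kind: str = "fixed") -> NetworkGraph:
    """Round-trip reader for the edgelist-tsv format written by export_graph."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"source": str, "target": str},
                     float_precision="round_trip")
    labels = list(pd.unique(df["target"]))
    J = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    weights = np.zeros((J, J))
    pvals = np.full((J, J), np.nan)
    mask = np.zeros((J, J), dtype=bool)
    has_p = df["p_value"].notna().any() if "p_value" in df else False
    has_m = df["significant"].notna().any() if "significant" in df else False
    for _, r in df.iterrows():
        j, k = idx[r["target"]], idx[r["source"]]
        weights[j, k] = r["weight"]
        if has_p:
            pvals[j, k] = r["p_value"]
        if has_m:
            mask[j, k] = str(r["significant"]) == "True"
    return NetworkGraph(
        labels, weights, mask if has_m else None, kind, pvals if has_p else None
    )
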