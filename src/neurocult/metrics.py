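"""Network statistics for neuronal-culture graphs.

Implements the literal (unnormalized) forms of the three centralities,
the node-to-node degree mixing matrix, the degree-assortativity
coefficient, the three clustering summaries (transitivity, average local
clustering over nodes of degree >= 2, and average square clustering), the
edge-length exceedance curve, and per-snapshot series summaries.

Conventions
-----------
* Centralities default to the unnormalized textbook definitions:
  ``degree(v) = deg(v)``, ``closeness(v) = 1 / sum_u d(u, v)`` and
  ``betweenness(v) = sum_{s != v != t} sigma_st(v) / sigma_st`` over
  unordered pairs.  ``normalized=True`` switches to the usual
  ``1/(n-1)``-scaled variants.
* On disconnected graphs closeness sums over *reachable* nodes only;
  unreachable pairs contribute nothing (and nothing to betweenness
  either, since ``sigma_st = 0`` pairs are skipped).
* A node with no reachable peers has closeness 0 by the empty-sum
  convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import SpatialNetwork

__all__ = [
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "node_to_node_matrix",
    "DegreeMixingMatrix",
    "assortativity",
    "clustering_summary",
    "ClusteringSummary",
    "square_clustering",
    "edge_length_exceedance",
    "ExceedanceCurve",
    "snapshot_series_summary",
    "SnapshotSummary",
]


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, SpatialNetwork) else net


# ----------------------------------------------------------------------
# Centralities
# ----------------------------------------------------------------------
def degree_centrality(net, normalized: bool = False) -> dict[int, float]:
    """Degree of every node; divided by ``n - 1`` when normalized."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    scale = 1.0 / (n - 1) if normalized and n > 1 else 1.0
    return {v: d * scale for v, d in g.degree()}


def closeness_centrality(net, normalized: bool = False) -> dict[int, float]:
    """Reciprocal of the summed shortest-path distances from each node.

    Sums run over the nodes reachable from ``v``; an isolated node gets
    0.  The normalized variant multiplies by ``n - 1``.
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    scale = float(n - 1) if normalized and n > 1 else 1.0
    out: dict[int, float] = {}
    for v in g:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(dist.values())  # d(v, v) = 0 contributes nothing
        out[v] = scale / total if total > 0 else 0.0
    return out


def betweenness_centrality(net, normalized: bool = False) -> dict[int, float]:
    """Shortest-path betweenness over unordered pairs.

    Pairs with no connecting path are skipped (they have no shortest
    paths to count).
    """
    g = _as_graph(net)
    return dict(nx.betweenness_centrality(g, normalized=normalized))


# ----------------------------------------------------------------------
# Degree mixing
# ----------------------------------------------------------------------
@dataclass
class DegreeMixingMatrix:
    """Count matrix of edge-end degree pairs.

    ``matrix[k1, k2]`` counts edge orientations whose source has degree
    ``k1`` and whose target has degree ``k2``; every undirected edge is
    counted in both orientations, so the matrix is symmetric and its
    total mass is ``2 |E|``.  ``peaks`` lists the argmax coordinates in
    ascending lexicographic order.
    """

    matrix: np.ndarray
    peaks: list[tuple[int, int]] = field(default_factory=list)

    def to_csv(self, path) -> None:
        k = self.matrix.shape[0]
        pd.DataFrame(
            self.matrix, index=range(k), columns=range(k)
        ).to_csv(path, index_label="degree")


def node_to_node_matrix(net) -> DegreeMixingMatrix:
    g = _as_graph(net)
    deg = dict(g.degree())
    kmax = max(deg.values()) if deg else 0
    m = np.zeros((kmax + 1, kmax + 1), dtype=np.int64)
    for u, v in g.edges():
        m[deg[u], deg[v]] += 1
        m[deg[v], deg[u]] += 1
    peaks: list[tuple[int, int]] = []
    if m.any():
        best = m.max()
        ks = np.argwhere(m == best)
        peaks = sorted((int(a), int(b)) for a, b in ks)
    return DegreeMixingMatrix(matrix=m, peaks=peaks)


def assortativity(net) -> float:
    """Pearson correlation of end-point degrees over all edge orientations.

    Returns ``nan`` (undefined) on degree-regular graphs where the
    end-degree variance vanishes; raises on edgeless graphs.
    """
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        raise ValueError("assortativity is undefined on an edgeless graph")
    deg = dict(g.degree())
    x, y = [], []
    for u, v in g.edges():
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


# ----------------------------------------------------------------------
# Clustering
# ----------------------------------------------------------------------
@dataclass
class ClusteringSummary:
    """Transitivity, average local clustering, average square clustering.

    ``clustering`` and ``square_clustering`` average only over nodes of
    degree >= 2 and are ``nan`` when no such node exists; transitivity is
    0 when the graph has no connected triplet.
    """

    transitivity: float
    clustering: float
    square_clustering: float

    def as_dict(self) -> dict[str, float]:
        return {
            "transitivity": self.transitivity,
            "clustering": self.clustering,
            "square_clustering": self.square_clustering,
        }


def square_clustering(net) -> dict[int, float]:
    """Square (4-cycle) clustering per node of degree >= 2.

    For each unordered neighbor pair ``(m, n)`` of ``i`` let ``q`` be
    the number of common neighbors of ``m`` and ``n`` other than ``i``
    (the observed squares through ``i, m, n``), ``theta = 1`` if ``m``
    and ``n`` are adjacent, and ``alpha = 1 + q + theta``.  The pair's
    contribution is ``q / ((k_m - alpha)(k_n - alpha) + q)``; a 0/0
    pair (no square present, none possible) contributes 0.  The node
    value is the mean over its neighbor pairs.
    """
    g = _as_graph(net)
    adj = {v: set(g[v]) for v in g}
    out: dict[int, float] = {}
    for i in g:
        nbrs = sorted(adj[i])
        if len(nbrs) < 2:
            continue
        vals = []
        for m, n in itertools.combinations(nbrs, 2):
            q = len((adj[m] & adj[n]) - {i})
            theta = 1 if n in adj[m] else 0
            alpha = 1 + q + theta
            denom = (len(adj[m]) - alpha) * (len(adj[n]) - alpha) + q
            vals.append(q / denom if denom != 0 else 0.0)
        out[i] = float(np.mean(vals))
    return out


def clustering_summary(net) -> ClusteringSummary:
    g = _as_graph(net)
    t = nx.transitivity(g)
    local = nx.clustering(g)
    vprime = [v for v, d in g.degree() if d >= 2]
    c = float(np.mean([local[v] for v in vprime])) if vprime else float("nan")
    sq = square_clustering(g)
    c4 = float(np.mean(list(sq.values()))) if sq else float("nan")
    return ClusteringSummary(float(t), c, c4)


# ----------------------------------------------------------------------
# Spatial edge-length statistics
# ----------------------------------------------------------------------
@dataclass
class ExceedanceCurve:
    """Empirical exceedance probability P(L > threshold) of edge lengths.

    Right-continuous complementary ECDF with *strict* inequality:
    evaluated below the minimum length it is 1, at/above the maximum 0.
    """

    thresholds: np.ndarray  # sorted distinct lengths
    probabilities: np.ndarray  # P(L > thresholds[i])
    lengths: np.ndarray  # raw sample

    def evaluate(self, threshold: float) -> float:
        return float(np.mean(self.lengths > threshold))

    def mean_length(self) -> float:
        return float(self.lengths.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold_px": self.thresholds, "p_exceed": self.probabilities}
        )


def edge_length_exceedance(net: SpatialNetwork) -> ExceedanceCurve:
    lengths = net.edge_lengths()
    if lengths.size == 0:
        raise ValueError("exceedance curve is undefined on an edgeless graph")
    if np.any(lengths <= 0):
        raise ValueError("every edge must have a positive length")
    thresholds = np.unique(lengths)
    probs = np.array([np.mean(lengths > t) for t in thresholds])
    return ExceedanceCurve(thresholds, probs, np.sort(lengths))


# ----------------------------------------------------------------------
# Snapshot series
# ----------------------------------------------------------------------
@dataclass
class SnapshotSummary:
    """Per-node centrality tables and per-snapshot means for a series."""

    per_node: pd.DataFrame  # snapshot, time_h, node, degree, closeness, betweenness
    means: pd.DataFrame  # snapshot, time_h, metric, mean

    def cdf(self, metric: str, snapshot: int) -> pd.DataFrame:
        """Empirical CDF grid (value, cdf) of one metric at one snapshot."""
        sub = self.per_node[self.per_node["snapshot"] == snapshot]
        vals = np.sort(sub[metric].to_numpy())
        return pd.DataFrame(
            {"value": vals, "cdf": np.arange(1, vals.size + 1) / vals.size}
        )


def snapshot_series_summary(
    nets: list[SpatialNetwork], normalized: bool = False
) -> SnapshotSummary:
    """Centrality tables and means for a time-ordered snapshot series."""
    rows = []
    for snap, net in enumerate(nets):
        deg = degree_centrality(net, normalized)
        clo = closeness_centrality(net, normalized)
        bet = betweenness_centrality(net, normalized)
        for v in net.graph:
            rows.append(
                {
                    "snapshot": snap,
                    "time_h": net.time_h,
                    "node": v,
                    "degree": deg[v],
                    "closeness": clo[v],
                    "betweenness": bet[v],
                }
            )
    per_node = pd.DataFrame(
        rows,
        columns=["snapshot", "time_h", "node", "degree", "closeness", "betweenness"],
    )
    mean_rows = []
    for snap, grp in per_node.groupby("snapshot"):
        for metric in ("degree", "closeness", "betweenness"):
            mean_rows.append(
                {
                    "snapshot": snap,
                    "time_h": grp["time_h"].iloc[0],
                    "metric": metric,
                    "mean": float(grp[metric].mean()),
                }
            )
    means = pd.DataFrame(mean_rows, columns=["snapshot", "time_h", "metric", "mean"])
    return SnapshotSummary(per_node=per_node, means=means)
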