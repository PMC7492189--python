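"""Multifractal analysis of networks via finite box covering.

A box of size ``r`` is a set of nodes of pairwise shortest-path distance
at most ``r`` (``r`` is a box *diameter*; boxes are grown as balls of
radius ``floor(r/2)``).  Covering the graph at several ``r`` yields
normalized box masses ``mu_i = M_i(r) / N`` whose moments

    Z(q, r) = sum_i mu_i^q  ~  (r/d)^tau(q)

define the mass exponents ``tau(q)`` and generalized dimensions
``D(q) = tau(q) / (q - 1)`` (``D(1)`` via the limit form).  The
Legendre transform

    alpha(q) = d/dq [(q - 1) D(q)],    f(alpha) = q alpha - (q - 1) D(q)

gives the multifractal spectrum; its height ``f_max``, width
``alpha_max - alpha_min`` and height range summarize the network's
structural heterogeneity.

Covering is random-sequential (uniformly chosen uncovered seeds, balls
restricted to uncovered nodes) with the best of several restarts kept.
A compaction pass then rebalances box masses: nodes migrate from large
boxes into adjacent undersized ones whenever the pairwise-diameter
constraint allows, which suppresses the spurious near-empty boxes that
otherwise dominate the negative-q moments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.stats import linregress

from .network import SpatialNetwork

__all__ = [
    "BoxCover",
    "MassExponents",
    "Spectrum",
    "box_cover",
    "mass_exponents",
    "legendre_spectrum",
]


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, SpatialNetwork) else net


def _distance_matrix(g: nx.Graph) -> tuple[np.ndarray, list]:
    nodes = list(g.nodes())
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr")
    dist = shortest_path(adj, method="BF" if len(nodes) < 3 else "D", unweighted=True)
    return dist, nodes


@dataclass
class BoxCover:
    """A partition of the node set into boxes of diameter <= r."""

    r: int
    boxes: list[list]  # node lists
    masses: np.ndarray  # node count per box

    @property
    def n_boxes(self) -> int:
        return len(self.boxes)


def _random_cover(dist: np.ndarray, r: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random-sequential ball covering on a distance matrix."""
    n = dist.shape[0]
    radius = r // 2
    uncovered = np.ones(n, dtype=bool)
    boxes: list[np.ndarray] = []
    order = rng.permutation(n)
    for seed_node in order:
        if not uncovered[seed_node]:
            continue
        members = np.flatnonzero(uncovered & (dist[seed_node] <= radius))
        uncovered[members] = False
        boxes.append(members)
    return boxes


def _compact(
    boxes: list[np.ndarray], dist: np.ndarray, r: int
) -> list[np.ndarray]:
    """Rebalance box masses without breaking the diameter constraint.

    Repeatedly move a node from a larger box into the currently smallest
    box when the enlarged box still has pairwise distance <= r.  Each
    move strictly decreases the sum of squared box sizes, so the loop
    terminates; the result has the same box count with far fewer
    near-empty boxes.
    """
    boxes = [list(b) for b in boxes if len(b)]
    nb = len(boxes)
    if nb < 2:
        return [np.asarray(b) for b in boxes]
    sizes = np.array([len(b) for b in boxes])
    frozen = np.zeros(nb, dtype=bool)
    # per-target cache of max distance from every node to the box; updated
    # incrementally as the box grows (max with the newcomer's row)
    dmax_cache: dict[int, np.ndarray] = {}
    for _guard in range(50 * nb + dist.shape[0]):
        if frozen.all():
            break
        active = np.flatnonzero(~frozen)
        bi = int(active[np.argmin(sizes[active])])
        if bi not in dmax_cache:
            dmax_cache[bi] = dist[:, np.asarray(boxes[bi])].max(axis=1)
        dmax = dmax_cache[bi]
        moved = False
        for dj in np.argsort(-sizes):
            if sizes[dj] <= sizes[bi] + 1:
                break
            for node in boxes[dj]:
                if dmax[node] <= r:
                    boxes[dj].remove(node)
                    boxes[bi].append(node)
                    sizes[dj] -= 1
                    sizes[bi] += 1
                    dmax_cache[bi] = np.maximum(dmax, dist[:, node])
                    dmax_cache.pop(int(dj), None)  # stale as a target
                    moved = True
                    break
            if moved:
                break
        if not moved:
            frozen[bi] = True
    return [np.asarray(b) for b in boxes if len(b)]


def box_cover(
    net,
    r: int,
    seed: int = 0,
    n_covers: int = 1,
    compact: bool = True,
    _dist: np.ndarray | None = None,
) -> BoxCover:
    """Best-of-``n_covers`` random-sequential covering at box diameter r.

    Boxes are balls of radius ``floor(r/2)`` grown around uniformly
    chosen uncovered seeds; among the restarts the cover with fewest
    boxes is kept (and compacted unless disabled).  ``r = 0`` puts every
    node in its own box.  Disconnected inputs are reduced to the largest
    component.
    """
    if r < 0:
        raise ValueError("box diameter r must be >= 0")
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot cover an empty graph")
    if not nx.is_connected(g):
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    if _dist is None:
        _dist, nodes = _distance_matrix(g)
    else:
        nodes = list(g.nodes())
    rng = np.random.default_rng(seed)
    best: list[np.ndarray] | None = None
    for _ in range(max(1, n_covers)):
        boxes = _random_cover(_dist, r, rng)
        if best is None or len(boxes) < len(best):
            best = boxes
    if compact:
        best = _compact(best, _dist, r)
    node_arr = np.asarray(nodes, dtype=object)
    out_boxes = [list(node_arr[b]) for b in best]
    return BoxCover(
        r=r,
        boxes=out_boxes,
        masses=np.array([len(b) for b in best], dtype=float),
    )


@dataclass
class MassExponents:
    """tau(q) fits and generalized dimensions D(q) on a q-grid."""

    q: np.ndarray
    tau: np.ndarray
    D: np.ndarray
    r_grid: np.ndarray
    r_squared: np.ndarray  # fit diagnostic per q
    degenerate: bool = False  # True when no scaling range exists

    def flagged(self, r2_threshold: float = 0.8) -> np.ndarray:
        """Boolean mask of q values whose fits are degenerate."""
        if self.degenerate:
            return np.ones_like(self.q, dtype=bool)
        return self.r_squared < r2_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"q": self.q, "tau": self.tau, "D": self.D, "r2": self.r_squared}
        )


def _default_q_grid() -> np.ndarray:
    return np.arange(-10.0, 10.0 + 1e-9, 0.5)


def mass_exponents(
    net,
    q_grid: np.ndarray | None = None,
    r_grid: np.ndarray | None = None,
    n_covers: int = 20,
    seed: int = 0,
) -> MassExponents:
    """Estimate tau(q) and D(q) from box-mass moments over an r range.

    For each r, ``n_covers`` independent covers are drawn and their
    partition sums averaged; ``tau(q)`` is the slope of
    ``ln Z(q, r)`` against ``ln(r/d)`` (d = diameter), with the ``q = 1``
    limit handled through the entropy sum ``sum mu ln mu``.  Graphs with
    no usable scaling range (diameter < 4) are flagged degenerate rather
    than rejected.
    """
    g = _as_graph(net)
    if not nx.is_connected(g):
        warnings.warn("disconnected input: analyzing largest component")
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    dist, _nodes = _distance_matrix(g)
    n = dist.shape[0]
    diam = int(dist.max())
    q = _default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)

    if r_grid is None:
        r_hi = max(2, math.ceil(diam / 2))
        r_grid = np.unique(
            np.round(np.geomspace(2, r_hi, num=8)).astype(int)
        )
    else:
        r_grid = np.unique(np.asarray(r_grid, dtype=int))
    if diam < 4 or len(r_grid) < 4:
        return MassExponents(
            q=q,
            tau=np.full_like(q, np.nan),
            D=np.full_like(q, np.nan),
            r_grid=np.asarray(r_grid, dtype=int),
            r_squared=np.zeros_like(q),
            degenerate=True,
        )

    ss = np.random.SeedSequence(seed)
    log_z = np.zeros((len(r_grid), len(q)))  # ln of cover-averaged Z(q, r)
    ent = np.zeros(len(r_grid))  # cover-averaged sum mu ln mu
    for ri, r in enumerate(r_grid):
        seeds = np.random.SeedSequence((seed, int(r))).generate_state(n_covers)
        z_acc = np.zeros(len(q))
        e_acc = 0.0
        for s in seeds:
            cover = box_cover(g, int(r), seed=int(s % (2**31 - 1)), _dist=dist)
            mu = cover.masses / n
            z_acc += np.power.outer(mu, q).sum(axis=0)
            e_acc += float((mu * np.log(mu)).sum())
        log_z[ri] = np.log(z_acc / n_covers)
        ent[ri] = e_acc / n_covers

    x = np.log(r_grid / diam)
    tau = np.empty(len(q))
    dim = np.empty(len(q))
    r2 = np.empty(len(q))
    for qi, qq in enumerate(q):
        if abs(qq - 1.0) < 1e-9:
            fit = linregress(x, ent)
            tau[qi] = 0.0
            dim[qi] = fit.slope
        else:
            fit = linregress(x, log_z[:, qi])
            tau[qi] = fit.slope
            dim[qi] = fit.slope / (qq - 1.0)
        r2[qi] = fit.rvalue**2
    return MassExponents(
        q=q,
        tau=tau,
        D=dim,
        r_grid=np.asarray(r_grid, dtype=int),
        r_squared=r2,
    )


@dataclass
class Spectrum:
    """Multifractal spectrum (alpha, f(alpha)) and its summary parameters."""

    q: np.ndarray
    alpha: np.ndarray
    f: np.ndarray
    f_max: float
    width: float  # alpha_max - alpha_min
    f_range: float  # f_max - f_min
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q": self.q, "alpha": self.alpha, "f": self.f})

    def summary(self) -> dict[str, float]:
        return {
            "f_alpha_max": self.f_max,
            "alpha_width": self.width,
            "f_alpha_range": self.f_range,
        }


def legendre_spectrum(me: MassExponents) -> Spectrum:
    """Legendre transform of the mass exponents to the (alpha, f) curve.

    ``alpha(q)`` is the derivative of ``(q - 1) D(q)`` by central finite
    differences (one-sided at the grid ends);
    ``f(alpha) = q alpha - (q - 1) D(q)`` holds exactly on the grid by
    construction.  Non-monotone ``alpha(q)`` (a noisy estimate) attaches
    a warning instead of failing.
    """
    keep = np.isfinite(me.D)
    if keep.sum() < 3:
        raise ValueError("need at least 3 finite D(q) values for the transform")
    q = me.q[keep]
    t = (q - 1.0) * me.D[keep]
    alpha = np.gradient(t, q)
    f = q * alpha - t
    warns = []
    if np.any(np.diff(alpha) > 0.05):
        warns.append("alpha(q) is not monotone non-increasing: noisy estimate")
    return Spectrum(
        q=q,
        alpha=alpha,
        f=f,
        f_max=float(f.max()),
        width=float(alpha.max() - alpha.min()),
        f_range=float(f.max() - f.min()),
        warnings=warns,
    )
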