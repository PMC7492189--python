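"""Independent brute-force oracles for small graphs.

These deliberately avoid the library routines they are used to check:
distances come from breadth-first search written out longhand, and
betweenness counts enumerate every simple path.  Only feasible for a
handful of nodes, which is the point.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx


def bfs_distances(g: nx.Graph, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in g[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def closeness_oracle(g: nx.Graph) -> dict:
    """Literal reciprocal-of-distance-sum closeness over reachable nodes."""
    out = {}
    for v in g:
        total = sum(d for u, d in bfs_distances(g, v).items() if u != v)
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def _all_shortest_paths(g: nx.Graph, s, t) -> list[tuple]:
    """Every shortest s-t path, found by exhaustive simple-path search."""
    best: list[tuple] = []
    best_len = [None]

    def walk(path: tuple):
        u = path[-1]
        if u == t:
            if best_len[0] is None or len(path) < best_len[0]:
                best_len[0] = len(path)
                best.clear()
            if len(path) == best_len[0]:
                best.append(path)
            return
        if best_len[0] is not None and len(path) >= best_len[0]:
            return
        for w in g[u]:
            if w not in path:
                walk(path + (w,))

    walk((s,))
    return best


def betweenness_oracle(g: nx.Graph) -> dict:
    """Sum over unordered pairs of the fraction of shortest paths via v."""
    out = {v: 0.0 for v in g}
    for s, t in itertools.combinations(list(g), 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for v in g:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out
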