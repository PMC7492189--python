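"""Spatial network container and on-disk formats.

The central currency between all pipeline stages is an undirected simple
graph whose nodes carry planar pixel coordinates.  The coordinate
convention, used everywhere in this package, is ``(row, col)`` with
0-based indices and row increasing downward; distances are Euclidean and
measured in pixels.  GraphML files store ``x = col`` and ``y = row`` so
that external viewers lay the graph out the way the image looks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["SpatialNetwork", "read_graphml", "write_graphml", "read_edge_csv"]


@dataclass
class SpatialNetwork:
    """An undirected simple graph with per-node planar coordinates.

    Nodes are integers carrying ``row``/``col`` attributes (pixels) and
    optionally ``area_px``; edges carry ``length_px``, the Euclidean
    centroid-to-centroid distance.  ``time_h`` is the acquisition time of
    the snapshot the network was derived from.
    """

    graph: nx.Graph
    time_h: float = 0.0

    # ------------------------------------------------------------------
    @classmethod
    def from_coordinates(
        cls,
        coords: Mapping[int, tuple[float, float]],
        edges: Iterable[tuple[int, int]],
        time_h: float = 0.0,
        areas: Mapping[int, float] | None = None,
    ) -> "SpatialNetwork":
        """Build a network from ``{node: (row, col)}`` and an edge list."""
        g = nx.Graph()
        for node, (r, c) in coords.items():
            g.add_node(int(node), row=float(r), col=float(c))
            if areas is not None and node in areas:
                g.nodes[int(node)]["area_px"] = float(areas[node])
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                continue
            ru, cu = coords[u]
            rv, cv = coords[v]
            g.add_edge(u, v, length_px=math.hypot(ru - rv, cu - cv))
        return cls(graph=g, time_h=float(time_h))

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positions(self) -> dict[int, tuple[float, float]]:
        """``{node: (row, col)}`` for every node."""
        return {
            n: (d["row"], d["col"]) for n, d in self.graph.nodes(data=True)
        }

    def edge_lengths(self) -> np.ndarray:
        """Euclidean lengths (px) of all edges, recomputed if absent."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            if "length_px" in d:
                out.append(d["length_px"])
            else:
                ru, cu = self.graph.nodes[u]["row"], self.graph.nodes[u]["col"]
                rv, cv = self.graph.nodes[v]["row"], self.graph.nodes[v]["col"]
                out.append(math.hypot(ru - rv, cu - cv))
        return np.asarray(out, dtype=float)

    def largest_component(self) -> "SpatialNetwork":
        if self.n_nodes == 0 or nx.is_connected(self.graph):
            return self
        nodes = max(nx.connected_components(self.graph), key=len)
        return SpatialNetwork(self.graph.subgraph(nodes).copy(), self.time_h)

    # ------------------------------------------------------------------
    def to_edge_csv(self, path: str | Path) -> None:
        rows = [
            {"u": u, "v": v, "length_px": d.get("length_px", float("nan"))}
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["u", "v", "length_px"]).to_csv(
            path, index=False
        )

    def to_node_csv(self, path: str | Path) -> None:
        rows = [
            {
                "node": n,
                "row": d.get("row", float("nan")),
                "col": d.get("col", float("nan")),
                "area_px": d.get("area_px", float("nan")),
            }
            for n, d in self.graph.nodes(data=True)
        ]
        pd.DataFrame(rows, columns=["node", "row", "col", "area_px"]).to_csv(
            path, index=False
        )


def write_graphml(net: SpatialNetwork, path: str | Path) -> None:
    """Write GraphML with ``x``/``y`` node attributes and ``time_h``."""
    g = nx.Graph()
    g.graph["time_h"] = float(net.time_h)
    for n, d in net.graph.nodes(data=True):
        attrs = {"x": float(d.get("col", 0.0)), "y": float(d.get("row", 0.0))}
        if "area_px" in d:
            attrs["area_px"] = float(d["area_px"])
        g.add_node(int(n), **attrs)
    for u, v, d in net.graph.edges(data=True):
        attrs = {}
        if "length_px" in d:
            attrs["length_px"] = float(d["length_px"])
        if "birth_snapshot" in d:
            attrs["birth_snapshot"] = int(d["birth_snapshot"])
        g.add_edge(int(u), int(v), **attrs)
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> SpatialNetwork:
    """Read a GraphML written by :func:`write_graphml` (or compatible)."""
    g = nx.read_graphml(str(path))
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(
            int(n),
            row=float(d.get("y", 0.0)),
            col=float(d.get("x", 0.0)),
            **({"area_px": float(d["area_px"])} if "area_px" in d else {}),
        )
    for u, v, d in g.edges(data=True):
        attrs = {}
        if "length_px" in d:
            attrs["length_px"] = float(d["length_px"])
        if "birth_snapshot" in d:
            attrs["birth_snapshot"] = int(d["birth_snapshot"])
        out.add_edge(int(u), int(v), **attrs)
    time_h = float(g.graph.get("time_h", 0.0))
    return SpatialNetwork(out, time_h)


def read_edge_csv(
    edge_path: str | Path, node_path: str | Path, time_h: float = 0.0
) -> SpatialNetwork:
    """Read an edge-list CSV (u, v[, length_px]) plus a node-coordinate CSV."""
    nodes = pd.read_csv(node_path)
    edges = pd.read_csv(edge_path)
    coords = {
        int(r.node): (float(r.row), float(r.col)) for r in nodes.itertuples()
    }
    areas = (
        {int(r.node): float(r.area_px) for r in nodes.itertuples()}
        if "area_px" in nodes.columns
        else None
    )
    return SpatialNetwork.from_coordinates(
        coords, [(int(r.u), int(r.v)) for r in edges.itertuples()], time_h, areas
    )
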