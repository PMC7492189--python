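"""Synthetic neuronal cultures: ground-truth networks and rendered images.

The study's raw quantitative-phase image series is not publicly
deposited, so this module generates the inputs every downstream stage is
tested against: bright round somas, curvilinear neurites drawn as
bounded-curvature arcs, sub-threshold debris, optional neurite gaps,
additive Gaussian noise, and a monotone connection-growth schedule over
up to 15 snapshots.

Connectivity follows a pure exponential distance-decay kernel: the
unordered soma pair ``(i, j)`` carries an edge with probability
``exp(-d_ij / connect_scale_px)``, the simplest kernel under which
physically close neurons acquire more interconnections than distant
ones.  Edges are assigned birth snapshots in ascending order of length
(short neurites complete first), so connections are only ever added over
the series.

Coordinates are ``(row, col)``, 0-based, row increasing downward;
distances are Euclidean in pixels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .network import SpatialNetwork

__all__ = [
    "CultureSpec",
    "GroundTruthNetwork",
    "PhaseImage",
    "PlacementError",
    "sample_ground_truth",
    "render_snapshot",
    "render_series",
    "generate_network_fixture",
    "write_image",
    "read_image",
]


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot honor a separation constraint."""


@dataclass
class PhaseImage:
    """One grayscale snapshot with its pixel size and acquisition time."""

    data: np.ndarray  # 2-D float array, intensities in [0, 1]
    pixel_size_um: float = 0.65
    time_h: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("phase image must be a 2-D grid")
        if not np.isfinite(self.data).all():
            raise ValueError("phase image must contain finite values")


@dataclass
class CultureSpec:
    """Parameters of one synthetic culture.

    Defaults describe a sparse low-density culture on a ~1 mm^2 field:
    30 somas of 15-22 px radius (area 700-1500 px, above the 600 px
    segmentation threshold), an exponential connection kernel with a
    100 px decay scale, and 15 snapshots spanning 14 h.  Debris areas sit
    strictly below the segmentation threshold in use.
    """

    field_height_px: int = 1024
    field_width_px: int = 1024
    n_somas: int = 30
    soma_radius_px: tuple[int, int] = (15, 22)
    min_soma_separation_px: float = 60.0
    connect_scale_px: float = 100.0
    neurite_width_px: int = 3
    n_snapshots: int = 15
    edges_per_snapshot_fraction: float = 1.0 / 15.0
    debris_count: int = 25
    debris_area_px: tuple[int, int] = (80, 300)
    gap_rate: float = 0.15
    gap_length_px: tuple[int, int] = (3, 8)
    noise_sigma: float = 0.01
    background_level: float = 0.10
    soma_level: float = 0.90
    neurite_level: float = 0.45
    total_duration_h: float = 14.0
    pixel_size_um: float = 0.65

    def __post_init__(self) -> None:
        if min(self.field_height_px, self.field_width_px) <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_somas <= 0:
            raise ValueError("n_somas must be positive")
        lo, hi = self.soma_radius_px
        if not (0 < lo <= hi):
            raise ValueError("soma_radius_px range must be nonempty and positive")
        if self.min_soma_separation_px < 0:
            raise ValueError("min_soma_separation_px must be nonnegative")
        if self.connect_scale_px <= 0:
            raise ValueError("connect_scale_px must be positive")
        if self.neurite_width_px < 1:
            raise ValueError("neurite_width_px must be a positive integer")
        if not (1 <= self.n_snapshots <= 15):
            raise ValueError("n_snapshots must be in 1..15")
        if not (0 < self.edges_per_snapshot_fraction <= 1):
            raise ValueError("edges_per_snapshot_fraction must be in (0, 1]")
        if self.debris_count < 0:
            raise ValueError("debris_count must be nonnegative")
        dlo, dhi = self.debris_area_px
        if not (0 < dlo <= dhi):
            raise ValueError("debris_area_px range must be nonempty")
        if not (0 <= self.gap_rate <= 1):
            raise ValueError("gap_rate must be a fraction in [0, 1]")
        glo, ghi = self.gap_length_px
        if not (0 < glo <= ghi):
            raise ValueError("gap_length_px range must be nonempty")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not (self.background_level < self.neurite_level < self.soma_level):
            raise ValueError(
                "intensity ordering background < neurite < soma must hold"
            )
        max_area = math.pi * hi * hi * self.n_somas
        if max_area > 0.25 * self.field_height_px * self.field_width_px:
            raise ValueError(
                "soma count x max soma area exceeds 25% of the field area"
            )


@dataclass
class GroundTruthNetwork:
    """The generated culture: somas, neurite arcs, growth schedule, clutter."""

    spec: CultureSpec
    centroids: np.ndarray  # (n, 2) float, (row, col)
    radii: np.ndarray  # (n,) int
    edges: list[tuple[int, int]]
    polylines: list[np.ndarray]  # one (k, 2) float polyline per edge
    birth_snapshots: np.ndarray  # (|E|,) int
    debris: list[tuple[tuple[float, float], int]]  # (centroid, area_px)
    gaps: list[tuple[int, float, int]]  # (edge index, arc offset px, length px)

    def network_at(self, snapshot: int) -> SpatialNetwork:
        """Ground-truth graph restricted to edges born at or before a snapshot."""
        coords = {i: tuple(c) for i, c in enumerate(self.centroids)}
        areas = {i: math.pi * r * r for i, r in enumerate(self.radii)}
        edges = [
            e
            for e, b in zip(self.edges, self.birth_snapshots)
            if b <= snapshot
        ]
        net = SpatialNetwork.from_coordinates(
            coords, edges, time_h=self._time_of(snapshot), areas=areas
        )
        return net

    def final_network(self) -> SpatialNetwork:
        return self.network_at(self.spec.n_snapshots - 1)

    def _time_of(self, snapshot: int) -> float:
        n = self.spec.n_snapshots
        return 0.0 if n <= 1 else self.spec.total_duration_h * snapshot / (n - 1)

    # ------------------------------------------------------------------
    def to_graphml(self, path: str | Path) -> None:
        from .network import write_graphml

        net = self.final_network()
        for (u, v), b in zip(self.edges, self.birth_snapshots):
            if net.graph.has_edge(u, v):
                net.graph[u][v]["birth_snapshot"] = int(b)
        write_graphml(net, path)

    def clutter_to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "kind": "debris",
                "row": c[0],
                "col": c[1],
                "area_px": a,
                "edge": -1,
                "offset_px": float("nan"),
                "length_px": float("nan"),
            }
            for c, a in self.debris
        ] + [
            {
                "kind": "gap",
                "row": float("nan"),
                "col": float("nan"),
                "area_px": float("nan"),
                "edge": e,
                "offset_px": off,
                "length_px": ln,
            }
            for e, off, ln in self.gaps
        ]
        pd.DataFrame(
            rows,
            columns=["kind", "row", "col", "area_px", "edge", "offset_px", "length_px"],
        ).to_csv(path, index=False)


# ----------------------------------------------------------------------
# Ground-truth sampling
# ----------------------------------------------------------------------
def _quadratic_arc(
    p0: np.ndarray, p1: np.ndarray, curvature: float, n_points: int
) -> np.ndarray:
    """Quadratic Bezier arc from p0 to p1 with a perpendicular control offset."""
    mid = 0.5 * (p0 + p1)
    d = p1 - p0
    norm = np.hypot(*d)
    perp = np.array([-d[1], d[0]]) / max(norm, 1e-12)
    ctrl = mid + curvature * norm * perp
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1


def sample_ground_truth(spec: CultureSpec, seed: int) -> GroundTruthNetwork:
    """Sample a culture: soma layout, distance-decay edges, growth schedule.

    Somas are placed by rejection sampling honoring the minimum
    center-to-center separation (and disk disjointness); each unordered
    pair independently carries an edge with probability
    ``exp(-d / connect_scale_px)``; every edge gets a bounded-curvature
    quadratic arc; births are scheduled so that ``ceil(fraction * |E|)``
    new edges appear per snapshot, shortest first.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.field_height_px, spec.field_width_px
    rlo, rhi = spec.soma_radius_px

    centroids: list[np.ndarray] = []
    radii: list[int] = []
    max_attempts = 2000 * spec.n_somas
    attempts = 0
    while len(centroids) < spec.n_somas:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {spec.n_somas} somas with "
                f"min_soma_separation_px={spec.min_soma_separation_px} in a "
                f"{h}x{w} field after {max_attempts} attempts"
            )
        attempts += 1
        r = int(rng.integers(rlo, rhi + 1))
        margin = r + 2
        c = np.array(
            [
                rng.uniform(margin, h - margin),
                rng.uniform(margin, w - margin),
            ]
        )
        ok = True
        for cj, rj in zip(centroids, radii):
            sep = max(spec.min_soma_separation_px, r + rj + 4)
            if np.hypot(*(c - cj)) < sep:
                ok = False
                break
        if ok:
            centroids.append(c)
            radii.append(r)
    cent = np.array(centroids)
    rad = np.array(radii, dtype=int)

    # Distance-decay edges.  The arc for each edge must clear every
    # *other* soma disk, so that the rendered neurite touches exactly the
    # two somas it joins; curvatures are re-sampled until that holds.
    edges: list[tuple[int, int]] = []
    polylines: list[np.ndarray] = []
    clearance = spec.neurite_width_px + 10
    for i in range(spec.n_somas):
        for j in range(i + 1, spec.n_somas):
            d = float(np.hypot(*(cent[i] - cent[j])))
            if rng.random() < math.exp(-d / spec.connect_scale_px):
                edges.append((i, j))
                n_pts = max(8, int(2 * d))
                others = [k for k in range(spec.n_somas) if k not in (i, j)]
                best_poly, best_clear = None, -np.inf
                for _try in range(25):
                    curv = rng.uniform(-0.15, 0.15)
                    poly = _quadratic_arc(cent[i], cent[j], curv, n_pts)
                    clear = min(
                        (
                            float(np.min(np.hypot(*(poly - cent[k]).T))) - rad[k]
                            for k in others
                        ),
                        default=np.inf,
                    )
                    if clear > best_clear:
                        best_poly, best_clear = poly, clear
                    if clear >= clearance:
                        break
                polylines.append(best_poly)

    # Birth schedule: shortest edges first, fixed batch per snapshot.
    n_e = len(edges)
    births = np.zeros(n_e, dtype=int)
    if n_e:
        lengths = np.array(
            [np.hypot(*(cent[u] - cent[v])) for u, v in edges]
        )
        order = np.argsort(lengths, kind="stable")
        batch = math.ceil(spec.edges_per_snapshot_fraction * n_e)
        for rank, idx in enumerate(order):
            births[idx] = min(rank // batch, spec.n_snapshots - 1)

    # Gaps: one per selected neurite, in the middle half of the arc.
    gaps: list[tuple[int, float, int]] = []
    for e_idx, poly in enumerate(polylines):
        if rng.random() < spec.gap_rate:
            seg = np.hypot(*np.diff(poly, axis=0).T)
            arclen = float(seg.sum())
            glen = int(rng.integers(spec.gap_length_px[0], spec.gap_length_px[1] + 1))
            lo = 0.30 * arclen
            hi = max(lo + 1.0, 0.70 * arclen - glen)
            gaps.append((e_idx, float(rng.uniform(lo, hi)), glen))

    # Debris: sub-threshold bright disks away from somas and neurites.
    debris: list[tuple[tuple[float, float], int]] = []
    poly_pts = (
        np.vstack(polylines) if polylines else np.empty((0, 2))
    )
    for _ in range(spec.debris_count):
        for _attempt in range(200):
            area = int(
                rng.integers(spec.debris_area_px[0], spec.debris_area_px[1] + 1)
            )
            dr = max(1.0, math.sqrt(area / math.pi))
            margin = dr + 2
            c = np.array(
                [
                    rng.uniform(margin, h - margin),
                    rng.uniform(margin, w - margin),
                ]
            )
            if cent.size and np.min(np.hypot(*(cent - c).T)) < dr + rhi + 6:
                continue
            if poly_pts.size and np.min(
                np.hypot(*(poly_pts - c).T)
            ) < dr + spec.neurite_width_px + 4:
                continue
            # debris must not merge with each other either, or the union
            # could exceed the segmentation area threshold
            if any(
                math.hypot(c[0] - pc[0], c[1] - pc[1])
                < dr + math.sqrt(pa / math.pi) + 3
                for pc, pa in debris
            ):
                continue
            debris.append(((float(c[0]), float(c[1])), area))
            break

    return GroundTruthNetwork(
        spec=spec,
        centroids=cent,
        radii=rad,
        edges=edges,
        polylines=polylines,
        birth_snapshots=births,
        debris=debris,
        gaps=gaps,
    )


# ----------------------------------------------------------------------
# Rendering
# ----------------------------------------------------------------------
def _polyline_mask(
    shape: tuple[int, int],
    poly: np.ndarray,
    keep: np.ndarray | None = None,
) -> np.ndarray:
    """Rasterize a polyline (1 px wide) onto a boolean grid.

    ``keep`` marks which polyline vertices to draw; segments whose
    either endpoint is dropped are not drawn (this is how gaps are cut
    *before* rasterization rather than erased afterwards).
    """
    mask = np.zeros(shape, dtype=bool)
    pts = np.round(poly).astype(int)
    for k in range(len(pts) - 1):
        if keep is not None and not (keep[k] and keep[k + 1]):
            continue
        rr, cc = draw_line(pts[k, 0], pts[k, 1], pts[k + 1, 0], pts[k + 1, 1])
        inside = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[inside], cc[inside]] = True
    return mask


def _thicken(mask: np.ndarray, width_px: int) -> np.ndarray:
    if width_px <= 1:
        return mask
    from scipy.ndimage import binary_dilation

    radius = (width_px - 1) // 2 + (width_px - 1) % 2
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    struct = yy * yy + xx * xx <= radius * radius
    return binary_dilation(mask, structure=struct)


def render_snapshot(
    truth: GroundTruthNetwork, spec: CultureSpec, snapshot: int, seed: int
) -> PhaseImage:
    """Render one snapshot: neurites born so far, somas, debris, noise.

    Gap placements remove the corresponding arc-length interval from a
    neurite before rasterization, so a gapped neurite is drawn as two
    disjoint strokes.  Somas are painted last and therefore sit at
    exactly ``soma_level`` in the noiseless image.
    """
    if not (0 <= snapshot < spec.n_snapshots):
        raise ValueError("snapshot out of range")
    h, w = spec.field_height_px, spec.field_width_px
    img = np.full((h, w), spec.background_level, dtype=float)

    gap_by_edge = {e: (off, ln) for e, off, ln in truth.gaps}
    neurite_mask = np.zeros((h, w), dtype=bool)
    for e_idx, ((u, v), poly) in enumerate(zip(truth.edges, truth.polylines)):
        if truth.birth_snapshots[e_idx] > snapshot:
            continue
        keep = None
        if e_idx in gap_by_edge:
            off, ln = gap_by_edge[e_idx]
            seg = np.hypot(*np.diff(poly, axis=0).T)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            keep = ~((arc >= off) & (arc <= off + ln))
        neurite_mask |= _polyline_mask((h, w), poly, keep)
    neurite_mask = _thicken(neurite_mask, spec.neurite_width_px)
    img[neurite_mask] = spec.neurite_level

    for (cr, cc), area in truth.debris:
        dr = max(1.0, math.sqrt(area / math.pi))
        rr, xx = draw_disk((cr, cc), dr, shape=(h, w))
        img[rr, xx] = spec.soma_level

    for (cr, cc), r in zip(truth.centroids, truth.radii):
        rr, xx = draw_disk((cr, cc), r, shape=(h, w))
        img[rr, xx] = spec.soma_level

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, snapshot)))
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    return PhaseImage(
        data=img,
        pixel_size_um=spec.pixel_size_um,
        time_h=truth._time_of(snapshot),
    )


def render_series(
    truth: GroundTruthNetwork, spec: CultureSpec, seed: int
) -> list[PhaseImage]:
    return [
        render_snapshot(truth, spec, s, seed) for s in range(spec.n_snapshots)
    ]


# ----------------------------------------------------------------------
# Image I/O (16-bit TIFF or 8-bit PNG, JSON sidecar)
# ----------------------------------------------------------------------
def write_image(image: PhaseImage, path: str | Path, fmt: str = "tiff") -> Path:
    """Write a snapshot as 16-bit TIFF (default) or 8-bit PNG + JSON sidecar."""
    path = Path(path)
    if fmt == "tiff":
        tifffile.imwrite(
            str(path), np.round(image.data * 65535).astype(np.uint16)
        )
    elif fmt == "png":
        Image.fromarray(
            np.round(image.data * 255).astype(np.uint8), mode="L"
        ).save(str(path))
    else:
        raise ValueError(f"unknown image format {fmt!r}; use 'tiff' or 'png'")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"pixel_size_um": image.pixel_size_um, "time_h": image.time_h}
        )
    )
    return path


def read_image(path: str | Path) -> PhaseImage:
    """Read a TIFF/PNG snapshot and its JSON sidecar (if present)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(str(path)).astype(float)
        data = raw / 65535.0 if raw.max() > 255 else raw / max(raw.max(), 1.0)
    else:
        raw = np.asarray(Image.open(str(path)).convert("L"), dtype=float)
        data = raw / 255.0
    meta = {"pixel_size_um": 0.65, "time_h": 0.0}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return PhaseImage(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        time_h=float(meta["time_h"]),
    )


# ----------------------------------------------------------------------
# Direct graph fixtures
# ----------------------------------------------------------------------
_FIXTURE_KINDS = ("ring", "uv_flower", "geometric", "complete", "star", "path")


def _circular_coords(g: nx.Graph, radius: float = 100.0) -> dict:
    nodes = list(g.nodes())
    n = len(nodes)
    return {
        v: (
            radius * (1 - math.cos(2 * math.pi * k / n)),
            radius * (1 + math.sin(2 * math.pi * k / n)),
        )
        for k, v in enumerate(nodes)
    }


def _uv_flower(u: int, v: int, generations: int) -> nx.Graph:
    """(u, v)-flower: iteratively replace each edge by parallel u- and v-paths."""
    if not (1 <= u <= v) or generations < 1:
        raise ValueError("uv_flower needs 1 <= u <= v and generations >= 1")
    g = nx.Graph()
    g.add_edge(0, 1)
    nxt = 2
    for _ in range(generations):
        new = nx.Graph()
        new.add_nodes_from(g.nodes())
        for a, b in g.edges():
            for plen in (u, v):
                prev = a
                for step in range(plen - 1):
                    new.add_edge(prev, nxt)
                    prev = nxt
                    nxt += 1
                new.add_edge(prev, b)
        g = new
    return g


def generate_network_fixture(
    kind: str, params: dict | None = None, seed: int = 0
) -> SpatialNetwork:
    """Deterministic or seeded validation fixtures with coordinates.

    Supported kinds: ring(n), uv_flower(u, v, generations),
    geometric(n, radius), complete(n), star(n), path(n).  Spatial kinds
    get a unit-disk/lattice layout scaled to pixels; the rest get a
    circular embedding (topology is what matters for them).
    """
    params = dict(params or {})
    if kind == "ring":
        g = nx.cycle_graph(int(params.get("n", 16)))
    elif kind == "uv_flower":
        g = _uv_flower(
            int(params.get("u", 2)),
            int(params.get("v", 2)),
            int(params.get("generations", 3)),
        )
    elif kind == "geometric":
        n = int(params.get("n", 100))
        radius = float(params.get("radius", 0.15))
        g = nx.random_geometric_graph(n, radius, seed=int(seed))
        coords = {
            v: (1000.0 * p[1], 1000.0 * p[0])
            for v, p in nx.get_node_attributes(g, "pos").items()
        }
        return SpatialNetwork.from_coordinates(coords, g.edges())
    elif kind == "complete":
        g = nx.complete_graph(int(params.get("n", 5)))
    elif kind == "star":
        g = nx.star_graph(int(params.get("n", 5)) - 1)
    elif kind == "path":
        g = nx.path_graph(int(params.get("n", 5)))
    else:
        raise ValueError(
            f"unknown fixture kind {kind!r}; supported: {', '.join(_FIXTURE_KINDS)}"
        )
    return SpatialNetwork.from_coordinates(_circular_coords(g), g.edges())
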