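"""Image-to-network reconstruction for neuronal cultures.

One snapshot becomes a spatial graph in four steps:

1. *Clarity screening* — a deterministic normalized local-variance focus
   score; callers compare it to a threshold to accept or reject tiles.
2. *Soma/debris segmentation* — bright round bodies are isolated by a
   grayscale opening (which erases thin neurites), thresholded (Otsu),
   and labeled; components below the minimum area (600 px in neuron
   mode, 800 px in cluster mode) are debris and discarded.
3. *Terminal detection and gap filling* — the thinned neurite skeleton
   is scanned for end pixels (exactly one 8-neighbor); a terminal within
   reach of skeleton in another component is bridged by a straight
   segment, at most once, to its nearest candidate.
4. *Neurite tracing* — from every soma boundary, skeleton pixels are
   walked outward depth-first; at branch points only continuations
   roughly collinear with the incoming direction (or with the local
   steerable-filter ridge tangent) are followed, so two neurites that
   merely cross do not short-circuit.  A walk that reaches another
   soma's halo records that unordered pair as an edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line
from skimage.filters import gaussian as gaussian_blur
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk as disk_selem
from skimage.morphology import opening as gray_opening
from skimage.morphology import skeletonize

from .network import SpatialNetwork
from .steerable import steerable_ridge
from .synthetic import PhaseImage

__all__ = [
    "ReconstructionParams",
    "Soma",
    "SomaSet",
    "SkeletonMask",
    "clarity_score",
    "segment_somas",
    "binarize",
    "make_skeleton",
    "detect_terminals",
    "fill_gaps",
    "trace_network",
    "reconstruct_image",
]

_NEIGHBORS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


@dataclass
class ReconstructionParams:
    """Tunable parameters of the image-to-network procedure.

    ``min_area_px`` defaults by mode: 600 (neuron) / 800 (cluster).
    ``gap_radius_px`` is the terminal search radius of the gap filler
    (0 disables bridging).  ``filter_scale_px`` is the Gaussian scale of
    the steerable ridge filter, matched to the neurite half-width;
    ``angle_tol_deg`` bounds the turn a walk may take at a skeleton
    branch point.
    """

    mode: str = "neuron"
    min_area_px: int | None = None
    gap_radius_px: float = 12.0
    filter_scale_px: float = 1.5
    angle_tol_deg: float = 60.0
    use_ridge: bool = True
    opening_radius_px: int = 6
    clarity_threshold: float = 0.0

    def resolved_min_area(self) -> int:
        if self.min_area_px is not None:
            return int(self.min_area_px)
        if self.mode == "neuron":
            return 600
        if self.mode == "cluster":
            return 800
        raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Soma:
    id: int
    centroid: tuple[float, float]  # (row, col)
    area_px: int


@dataclass
class SomaSet:
    """Segmented somas: a label image (0 = background) and a table.

    ``bright_mask`` covers *every* bright round body found before the
    area filter — somas and debris alike — and is what downstream
    neurite binarization masks out, so that debris neither skews the
    threshold histogram nor enters the skeleton.
    """

    labels: np.ndarray  # int label grid, 0 = background
    somas: list[Soma]
    bright_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.somas)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def bright_or_soma_mask(self) -> np.ndarray:
        return self.mask if self.bright_mask is None else self.bright_mask


@dataclass
class SkeletonMask:
    """A thinned (1-px-wide) binary neurite skeleton; 8-connectivity."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)


# ----------------------------------------------------------------------
# Step 1: clarity screening
# ----------------------------------------------------------------------
def clarity_score(image: PhaseImage | np.ndarray, window: int = 7) -> float:
    """Deterministic focus score in [0, 1) from normalized local variance.

    The mean local intensity variance is mapped through
    ``v / (v + tau^2)`` with ``tau`` a fixed 5%-of-scale anchor, so a
    constant image scores exactly 0 and blurring strictly lowers the
    score.  Compare against a configured threshold to accept tiles.
    """
    img = np.asarray(image.data if isinstance(image, PhaseImage) else image, float)
    if img.size == 0:
        raise ValueError("empty image")
    local_mean = ndimage.uniform_filter(img, window)
    local_sq = ndimage.uniform_filter(img * img, window)
    v = float(np.mean(np.clip(local_sq - local_mean**2, 0.0, None)))
    tau = 0.05 * max(float(img.max()), 1e-12)
    return v / (v + tau * tau) if v > 0 else 0.0


# ----------------------------------------------------------------------
# Step 2: soma segmentation
# ----------------------------------------------------------------------
def segment_somas(
    image: PhaseImage | np.ndarray,
    min_area_px: int = 600,
    mode: str | None = None,
    opening_radius_px: int = 6,
) -> SomaSet:
    """Threshold bright round bodies and keep those >= the area threshold.

    A grayscale opening with a disk erases structures thinner than the
    disk (neurites), leaving somas and round debris; Otsu then separates
    them from background.  Components below ``min_area_px`` are debris
    and dropped.  ``mode`` overrides the threshold: 600 (neuron) / 800
    (cluster).
    """
    if mode is not None:
        min_area_px = 600 if mode == "neuron" else 800
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    img = np.asarray(image.data if isinstance(image, PhaseImage) else image, float)
    opened = gray_opening(img, disk_selem(opening_radius_px))
    if opened.max() <= opened.min():
        return SomaSet(
            labels=np.zeros(img.shape, dtype=np.int32),
            somas=[],
            bright_mask=np.zeros(img.shape, dtype=bool),
        )
    th = threshold_otsu(opened)
    bright = opened > th
    # The opening erases debris smaller than its disk, so `bright` alone
    # is incomplete as an exclusion mask for neurite thresholding: tiny
    # soma-intensity debris would poison that histogram.  Complete it
    # with an intensity split of the robust foreground, accepted only
    # when the foreground is genuinely bimodal (neurites and bodies).
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    fg0 = img > (med + 6.0 * 1.4826 * mad if mad > 0 else med)
    vals = img[fg0]
    if vals.size >= 2 and np.unique(vals).size >= 2:
        tb = threshold_otsu(vals)
        lo, hi = vals[vals <= tb], vals[vals > tb]
        if (
            lo.size
            and hi.size
            and hi.mean() - lo.mean() > 3.0 * (lo.std() + hi.std()) + 1e-9
        ):
            bright = bright | (img > tb)
    raw = cc_label(bright, connectivity=2)
    labels = np.zeros(img.shape, dtype=np.int32)
    somas: list[Soma] = []
    next_id = 0
    for lab in range(1, raw.max() + 1):
        mask = raw == lab
        area = int(mask.sum())
        if area < min_area_px:
            continue  # debris by definition
        rr, cc = np.nonzero(mask)
        labels[mask] = next_id + 1
        somas.append(
            Soma(
                id=next_id,
                centroid=(float(rr.mean()), float(cc.mean())),
                area_px=area,
            )
        )
        next_id += 1
    return SomaSet(labels=labels, somas=somas, bright_mask=bright)


# ----------------------------------------------------------------------
# Binarization and skeletonization
# ----------------------------------------------------------------------
def binarize(
    image: PhaseImage | np.ndarray,
    subtract_background: bool = False,
    background_sigma: float = 50.0,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Foreground mask by Otsu thresholding.

    ``exclude`` masks pixels (typically somas and debris, far brighter
    than neurites) out of the threshold *estimation* so that Otsu
    separates background from neurites rather than neurites from somas;
    excluded pixels are still classified against the resulting
    threshold.  Optional large-scale background subtraction is available
    for unevenly illuminated images; it is off by default because the
    smoothed field is inflated next to bright somas, which depresses the
    apparent contrast of exactly the short neurites that join nearby
    cells.
    """
    img = np.asarray(image.data if isinstance(image, PhaseImage) else image, float)
    if subtract_background:
        img = np.clip(img - gaussian_blur(img, background_sigma), 0.0, None)
    sample = img if exclude is None else img[~exclude]
    if sample.size == 0 or sample.max() <= sample.min():
        return np.zeros(img.shape, dtype=bool)
    th = threshold_otsu(sample)
    # When foreground occupies a vanishing fraction of the field (a young
    # culture with one or two neurites), Otsu splits the background noise
    # instead; never threshold below the robust noise floor.
    med = float(np.median(sample))
    mad = float(np.median(np.abs(sample - med)))
    th = max(th, med + 6.0 * 1.4826 * mad)
    return img > th


def make_skeleton(
    image: PhaseImage | np.ndarray,
    somas: SomaSet | None = None,
    foreground: np.ndarray | None = None,
) -> SkeletonMask:
    """Thin the neurite foreground to a 1-px skeleton.

    Soma interiors (dilated by 1 px) are removed first so the skeleton
    describes neurites only; their end pixels near a soma boundary act
    as anchors during tracing.
    """
    bright = None
    if somas is not None:
        bright = somas.bright_or_soma_mask()
        if not bright.any():
            bright = None
    if foreground is None:
        exclude = (
            ndimage.binary_dilation(bright, iterations=2)
            if bright is not None
            else None
        )
        fg = binarize(image, exclude=exclude)
    else:
        fg = foreground.astype(bool)
    if bright is not None:
        fg = fg & ~ndimage.binary_dilation(bright, iterations=1)
    return SkeletonMask(skeletonize(fg))


# ----------------------------------------------------------------------
# Step 3: terminal detection and gap filling
# ----------------------------------------------------------------------
def _neighbor_counts(grid: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(grid.astype(int), kernel, mode="constant")


def detect_terminals(
    skeleton: SkeletonMask,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Skeleton pixels with exactly one 8-neighbor, and isolated pixels.

    Returns ``(terminals, isolated)``; isolated single pixels (zero
    neighbors) are reported separately, not as terminals.
    """
    grid = skeleton.grid
    counts = _neighbor_counts(grid)
    term = np.argwhere(grid & (counts == 1))
    isol = np.argwhere(grid & (counts == 0))
    return (
        [tuple(map(int, p)) for p in term],
        [tuple(map(int, p)) for p in isol],
    )


def fill_gaps(
    skeleton: SkeletonMask,
    terminals: Sequence[tuple[int, int]],
    radius_px: float,
    soma_mask: np.ndarray | None = None,
) -> SkeletonMask:
    """Bridge each terminal to its nearest out-of-component neighbor.

    Candidates are skeleton pixels of a *different* connected component
    (a terminal's own branch is never a gap partner) or, if provided,
    soma pixels.  Each terminal bridges at most once, by a straight
    pixel segment; the result is re-thinned.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    grid = skeleton.grid.copy()
    if radius_px == 0 or not terminals:
        return SkeletonMask(grid)
    comps = cc_label(grid, connectivity=2)
    skel_pts = np.argwhere(grid)
    tree = cKDTree(skel_pts)
    soma_pts = np.argwhere(soma_mask) if soma_mask is not None else None
    soma_tree = cKDTree(soma_pts) if soma_pts is not None and len(soma_pts) else None

    bridges = np.zeros_like(grid)
    for tr, tc in terminals:
        own = comps[tr, tc]
        best: tuple[float, tuple[int, int]] | None = None
        for idx in tree.query_ball_point((tr, tc), radius_px):
            pr, pc = skel_pts[idx]
            if comps[pr, pc] == own:
                continue
            d = math.hypot(pr - tr, pc - tc)
            if best is None or d < best[0]:
                best = (d, (int(pr), int(pc)))
        if soma_tree is not None:
            d, idx = soma_tree.query((tr, tc))
            if d <= radius_px and (best is None or d < best[0]):
                pr, pc = soma_pts[idx]
                best = (float(d), (int(pr), int(pc)))
        if best is not None:
            rr, cc = draw_line(tr, tc, *best[1])
            bridges[rr, cc] = True
    return SkeletonMask(skeletonize(grid | bridges))


# ----------------------------------------------------------------------
# Step 4: neurite tracing
# ----------------------------------------------------------------------
def _angle_between(v: np.ndarray, w: np.ndarray) -> float:
    c = float(np.clip(np.dot(v, w), -1.0, 1.0))
    return math.degrees(math.acos(c))


_TRAIL = 15  # chord window (px) for the walk direction estimate
_LOOKAHEAD = 15  # how far a candidate branch is probed at a junction


def _lookahead_chord(
    grid: np.ndarray,
    start: tuple[int, int],
    first: tuple[int, int],
    direction: np.ndarray,
    n_steps: int = _LOOKAHEAD,
) -> np.ndarray:
    """Probe a branch for up to ``n_steps`` px and return its chord vector.

    From ``start`` through ``first``, greedily follow the locally
    straightest continuation; the chord from ``start`` to wherever the
    probe ends summarizes the branch direction on the scale of a
    crossing's merged segment, which single-pixel steps cannot resolve.
    """
    h, w = grid.shape
    seen = {start, first}
    r, c = first
    d = direction
    for _ in range(n_steps):
        best = None
        for dr, dc in _NEIGHBORS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and grid[nr, nc] and (nr, nc) not in seen:
                step = np.array([dr, dc], float)
                step /= np.hypot(dr, dc)
                ang = _angle_between(d, step)
                if ang <= 75.0 and (best is None or ang < best[0]):
                    best = (ang, nr, nc, step)
        if best is None:
            break
        _, r, c, step = best
        seen.add((r, c))
        d = 0.7 * d + 0.3 * step
        d /= max(np.hypot(*d), 1e-12)
    chord = np.array([r - start[0], c - start[1]], float)
    n = np.hypot(*chord)
    return chord / n if n > 0 else direction


def trace_network(
    image: PhaseImage,
    somas: SomaSet,
    skeleton: SkeletonMask,
    params: ReconstructionParams | None = None,
) -> SpatialNetwork:
    """Walk neurite skeleton pixels from every soma and record contacts.

    Each soma is a node at its centroid.  Walks start at skeleton pixels
    inside the soma's halo, heading outward, and proceed depth-first,
    visiting each skeleton pixel at most once per source soma.  At
    branch points only continuations within ``angle_tol_deg`` of the
    incoming direction are taken — with the steerable ridge tangent as a
    fallback vote — so crossing neurites are traversed straight through.
    Reaching another soma's halo records the unordered pair as one edge;
    duplicates collapse (the analysis graphs are simple and undirected).
    Walks that die without reaching a soma contribute nothing.
    """
    params = params or ReconstructionParams()
    grid = skeleton.grid
    h, w = grid.shape
    halo_px = 4
    halo = ndimage.maximum_filter(somas.labels, size=2 * halo_px + 1)

    tangent = None
    if params.use_ridge:
        _, tangent = steerable_ridge(
            np.asarray(image.data, float), sigma=params.filter_scale_px
        )

    tol = params.angle_tol_deg
    edges: set[tuple[int, int]] = set()
    dead_walks = 0

    for soma in somas.somas:
        s = soma.id
        anchors = np.argwhere(grid & (halo == s + 1))
        if anchors.size == 0:
            continue
        centroid = np.asarray(soma.centroid)
        visited = np.zeros_like(grid)
        # frame: (row, col, trail of recent positions, fallback direction)
        stack: list[tuple[int, int, tuple, np.ndarray]] = []
        for ar, ac in anchors:
            d0 = np.array([ar - centroid[0], ac - centroid[1]], dtype=float)
            n0 = np.hypot(*d0)
            d0 = d0 / n0 if n0 > 0 else np.array([1.0, 0.0])
            stack.append((int(ar), int(ac), (), d0))
        while stack:
            r, c, trail, dir0 = stack.pop()
            if visited[r, c]:
                continue
            visited[r, c] = True
            lab = halo[r, c]
            if lab > 0 and lab != s + 1:
                edges.add(tuple(sorted((s, lab - 1))))
                continue  # arrived at a soma; stop this branch
            if len(trail) >= 3:
                direction = np.array(
                    [r - trail[0][0], c - trail[0][1]], dtype=float
                )
                direction /= max(np.hypot(*direction), 1e-12)
            else:
                direction = dir0
            new_trail = (trail + ((r, c),))[-_TRAIL:]
            cands = []
            for dr, dc in _NEIGHBORS:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and grid[nr, nc] and not visited[nr, nc]:
                    step = np.array([dr, dc], dtype=float)
                    step /= np.hypot(dr, dc)
                    cands.append((nr, nc, step))
            if not cands:
                dead_walks += 1
                continue
            if len(cands) == 1:
                nr, nc, _step = cands[0]
                stack.append((nr, nc, new_trail, direction))
                continue
            # Branch point: probe each branch ahead and continue along the
            # one whose chord is best aligned with the incoming chord, so
            # a crossing neurite is traversed straight through instead of
            # short-circuiting onto the other arm.
            accepted = []
            for nr, nc, step in cands:
                chord = _lookahead_chord(grid, (r, c), (nr, nc), step)
                ang = _angle_between(direction, chord)
                ok = ang <= tol
                if not ok and tangent is not None:
                    t = tangent[r, c]
                    tvec = np.array([math.sin(t), math.cos(t)])
                    ang_t = min(
                        _angle_between(chord, tvec), _angle_between(chord, -tvec)
                    )
                    ok = ang_t <= tol / 2 and ang <= 90.0
                if ok:
                    accepted.append((nr, nc, ang))
            if accepted:
                nr, nc, _ang = min(accepted, key=lambda x: x[2])
                stack.append((nr, nc, new_trail, direction))
            else:
                dead_walks += 1

    coords = {sm.id: sm.centroid for sm in somas.somas}
    areas = {sm.id: sm.area_px for sm in somas.somas}
    net = SpatialNetwork.from_coordinates(
        coords, sorted(edges), time_h=image.time_h, areas=areas
    )
    net.graph.graph["walks_without_target"] = dead_walks
    return net


# ----------------------------------------------------------------------
# End-to-end convenience
# ----------------------------------------------------------------------
def reconstruct_image(
    image: PhaseImage, params: ReconstructionParams | None = None
) -> SpatialNetwork:
    """Full snapshot reconstruction: segment, skeletonize, bridge, trace."""
    params = params or ReconstructionParams()
    somas = segment_somas(
        image,
        min_area_px=params.resolved_min_area(),
        opening_radius_px=params.opening_radius_px,
    )
    skeleton = make_skeleton(image, somas)
    if params.gap_radius_px > 0:
        terminals, _ = detect_terminals(skeleton)
        skeleton = fill_gaps(skeleton, terminals, params.gap_radius_px)
    return trace_network(image, somas, skeleton, params)
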