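import dataclasses

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.filters import gaussian

from neurocult.reconstruction import (
    ReconstructionParams,
    SkeletonMask,
    clarity_score,
    detect_terminals,
    fill_gaps,
    make_skeleton,
    reconstruct_image,
    segment_somas,
    trace_network,
)
from neurocult.synthetic import (
    CultureSpec,
    PhaseImage,
    render_snapshot,
    sample_ground_truth,
)


def edge_sets(truth, net):
    """Ground-truth and reconstructed edge sets on matched node ids."""
    from scipy.spatial import cKDTree

    pos = np.array(
        [[net.graph.nodes[n]["row"], net.graph.nodes[n]["col"]] for n in net.graph]
    )
    ids = list(net.graph)
    mapping = {
        n: int(i) for n, i in zip(ids, cKDTree(truth.centroids).query(pos)[1])
    }
    t = set(map(tuple, map(sorted, truth.edges)))
    f = set(tuple(sorted((mapping[u], mapping[v]))) for u, v in net.graph.edges())
    return t, f


def f1_score(truth, net) -> float:
    t, f = edge_sets(truth, net)
    tp = len(t & f)
    prec = tp / len(f) if f else 0.0
    rec = tp / len(t) if t else 1.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


# ----------------------------------------------------------------------
# Clarity screening
# ----------------------------------------------------------------------
def test_clarity_score_zero_on_constant_images():
    assert clarity_score(np.zeros((64, 64))) == 0.0
    assert clarity_score(np.full((64, 64), 0.7)) == 0.0


def test_clarity_score_drops_under_blur():
    rng = np.random.default_rng(0)
    sharp = rng.random((128, 128))
    blurred = gaussian(sharp, 3.0)
    assert clarity_score(sharp) > clarity_score(blurred)


def test_clarity_checkerboard_beats_uniform_gray():
    board = np.indices((64, 64)).sum(axis=0) % 2
    gray = np.full((64, 64), board.mean())
    assert clarity_score(board.astype(float)) > clarity_score(gray)


# ----------------------------------------------------------------------
# Soma segmentation
# ----------------------------------------------------------------------
def _disk_image(areas, level=0.9, bg=0.1, shape=(256, 256)):
    img = np.full(shape, bg)
    col = 60
    for area in areas:
        r = max(1.0, np.sqrt(area / np.pi))
        rr, cc = draw_disk((128, col), r, shape=shape)
        img[rr, cc] = level
        col += 120
    return img


def test_segmentation_area_thresholds():
    img = _disk_image([900, 400])
    assert len(segment_somas(img, min_area_px=600)) == 1
    assert len(segment_somas(img, min_area_px=300)) == 2


def test_segmentation_mode_defaults():
    # an 700 px body is a neuron-mode soma but cluster-mode debris
    img = _disk_image([700])
    assert len(segment_somas(img, mode="neuron")) == 1
    assert len(segment_somas(img, mode="cluster")) == 0


def test_segmentation_empty_image():
    assert len(segment_somas(np.zeros((64, 64)))) == 0


def test_segmentation_on_culture_rejects_all_debris():
    spec = CultureSpec(n_somas=20, debris_count=30, noise_sigma=0.0, gap_rate=0.0)
    truth = sample_ground_truth(spec, seed=1)
    img = render_snapshot(truth, spec, spec.n_snapshots - 1, seed=1)
    somas = segment_somas(img, min_area_px=600)
    assert len(somas) == 20


# ----------------------------------------------------------------------
# Terminal detection
# ----------------------------------------------------------------------
def _mask(shape, pts):
    grid = np.zeros(shape, dtype=bool)
    for r, c in pts:
        grid[r, c] = True
    return SkeletonMask(grid)


def test_terminals_on_straight_line():
    sk = _mask((20, 20), [(5, c) for c in range(4, 14)])
    terms, isolated = detect_terminals(sk)
    assert sorted(terms) == [(5, 4), (5, 13)]
    assert isolated == []


def test_terminals_on_closed_cycle():
    sk = _mask((10, 10), [(2, 2), (2, 3), (3, 3), (3, 2)])
    terms, _ = detect_terminals(sk)
    assert terms == []


def test_terminals_on_y_shape():
    pts = (
        [(10 - k, 10) for k in range(10)]  # stem going up
        + [(11 + k, 10 - k) for k in range(9)]  # left arm
        + [(11 + k, 10 + k) for k in range(9)]  # right arm
    )
    sk = _mask((32, 32), pts)
    terms, _ = detect_terminals(sk)
    assert len(terms) == 3


def test_isolated_pixels_reported_separately():
    sk = _mask((10, 10), [(1, 1), (5, 5), (5, 6)])
    terms, isolated = detect_terminals(sk)
    assert isolated == [(1, 1)]
    assert sorted(terms) == [(5, 5), (5, 6)]


# ----------------------------------------------------------------------
# Gap filling
# ----------------------------------------------------------------------
def _two_collinear_segments(gap=3):
    pts = [(10, c) for c in range(2, 12)] + [(10, c) for c in range(12 + gap, 24)]
    return _mask((24, 32), pts)


def test_fill_gap_within_radius_connects():
    from skimage.measure import label

    sk = _two_collinear_segments(gap=3)
    terms, _ = detect_terminals(sk)
    out = fill_gaps(sk, terms, radius_px=5)
    assert label(out.grid, connectivity=2).max() == 1


def test_fill_gap_beyond_radius_does_not_connect():
    from skimage.measure import label

    sk = _two_collinear_segments(gap=3)
    terms, _ = detect_terminals(sk)
    out = fill_gaps(sk, terms, radius_px=2)
    assert label(out.grid, connectivity=2).max() == 2


def test_fill_gaps_rejects_negative_radius():
    sk = _two_collinear_segments()
    with pytest.raises(ValueError):
        fill_gaps(sk, [], radius_px=-1)


def test_gap_filling_reconnects_every_gapped_edge():
    """With every neurite cut and cuts shorter than the search radius,
    the filled skeleton recovers every ground-truth edge."""
    spec = CultureSpec(
        n_somas=20, gap_rate=1.0, gap_length_px=(3, 8), debris_count=0,
        noise_sigma=0.0,
    )
    truth = sample_ground_truth(spec, seed=2)
    img = render_snapshot(truth, spec, spec.n_snapshots - 1, seed=2)
    net = reconstruct_image(img, ReconstructionParams(gap_radius_px=12))
    t, f = edge_sets(truth, net)
    assert len(t & f) / len(t) >= 0.9


# ----------------------------------------------------------------------
# Tracing
# ----------------------------------------------------------------------
def test_trace_single_neurite_two_somas():
    spec = CultureSpec(
        field_height_px=256, field_width_px=256, n_somas=2,
        min_soma_separation_px=90, connect_scale_px=1e12, n_snapshots=1,
        edges_per_snapshot_fraction=1.0, debris_count=0, gap_rate=0.0,
        noise_sigma=0.0,
    )
    truth = sample_ground_truth(spec, seed=3)
    img = render_snapshot(truth, spec, 0, seed=3)
    net = reconstruct_image(img, ReconstructionParams())
    assert net.n_nodes == 2
    assert sorted(net.graph.edges()) == [(0, 1)]
    assert net.graph[0][1]["length_px"] > 0


def test_trace_disjoint_somas_yield_no_edges():
    img = _disk_image([900, 900])
    phase = PhaseImage(data=img)
    somas = segment_somas(phase)
    skeleton = make_skeleton(phase, somas)
    net = trace_network(phase, somas, skeleton)
    assert net.n_nodes == 2 and net.n_edges == 0


def test_reconstruction_translation_invariance():
    spec = CultureSpec(
        field_height_px=480, field_width_px=480, n_somas=8,
        debris_count=0, gap_rate=0.0, noise_sigma=0.0,
    )
    truth = sample_ground_truth(spec, seed=4)
    img = render_snapshot(truth, spec, spec.n_snapshots - 1, seed=4)
    dr, dc = 4, 6
    shifted = np.full_like(img.data, spec.background_level)
    shifted[dr:, dc:] = img.data[:-dr, :-dc]
    net_a = reconstruct_image(img, ReconstructionParams())
    net_b = reconstruct_image(PhaseImage(data=shifted), ReconstructionParams())
    assert set(net_a.graph.edges()) == set(net_b.graph.edges())
    for v in net_a.graph:
        assert net_b.graph.nodes[v]["row"] == pytest.approx(
            net_a.graph.nodes[v]["row"] + dr, abs=1.0
        )


def test_fill_gaps_never_removes_edges():
    spec = CultureSpec(gap_rate=0.5, noise_sigma=0.01)
    for seed in (0, 1):
        truth = sample_ground_truth(spec, seed)
        img = render_snapshot(truth, spec, spec.n_snapshots - 1, seed)
        without = reconstruct_image(img, ReconstructionParams(gap_radius_px=0))
        with_fill = reconstruct_image(img, ReconstructionParams(gap_radius_px=12))
        assert set(without.graph.edges()) <= set(with_fill.graph.edges())


def test_debris_below_threshold_never_changes_network():
    spec = CultureSpec(debris_count=25, noise_sigma=0.0)
    truth = sample_ground_truth(spec, seed=5)
    img_with = render_snapshot(truth, spec, spec.n_snapshots - 1, seed=5)
    img_without = render_snapshot(
        dataclasses.replace(truth, debris=[]), spec, spec.n_snapshots - 1, seed=5
    )
    net_with = reconstruct_image(img_with, ReconstructionParams())
    net_without = reconstruct_image(img_without, ReconstructionParams())
    assert net_with.n_nodes == net_without.n_nodes == spec.n_somas
    assert set(net_with.graph.edges()) == set(net_without.graph.edges())


def test_clean_culture_f1(clean_culture_spec):
    truth = sample_ground_truth(clean_culture_spec, seed=0)
    img = render_snapshot(
        truth, clean_culture_spec, clean_culture_spec.n_snapshots - 1, seed=0
    )
    net = reconstruct_image(img, ReconstructionParams())
    assert f1_score(truth, net) >= 0.9
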