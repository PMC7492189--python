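import dataclasses
import math

import numpy as np
import pytest

from neurocult.synthetic import (
    CultureSpec,
    PlacementError,
    generate_network_fixture,
    render_snapshot,
    sample_ground_truth,
)


def tiny_spec(**kw) -> CultureSpec:
    base = dict(
        field_height_px=256,
        field_width_px=256,
        n_somas=2,
        min_soma_separation_px=80,
        n_snapshots=2,
        debris_count=0,
        gap_rate=0.0,
        noise_sigma=0.0,
    )
    base.update(kw)
    return CultureSpec(**base)


# ----------------------------------------------------------------------
# Spec validation
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "bad",
    [
        {"n_somas": 0},
        {"connect_scale_px": 0},
        {"edges_per_snapshot_fraction": 0.0},
        {"n_snapshots": 16},
        {"gap_rate": 1.5},
        {"soma_radius_px": (10, 5)},
        {"background_level": 0.5, "neurite_level": 0.4},  # ordering violated
        {"n_somas": 200},  # > 25% of a 256x256 field
    ],
)
def test_spec_validation_rejects(bad):
    with pytest.raises(ValueError):
        tiny_spec(**bad)


def test_placement_failure_names_constraint():
    with pytest.raises(PlacementError, match="min_soma_separation_px"):
        sample_ground_truth(
            tiny_spec(n_somas=8, min_soma_separation_px=500), seed=0
        )


# ----------------------------------------------------------------------
# Ground-truth sampling
# ----------------------------------------------------------------------
def test_connection_kernel_limit_cases():
    # lambda -> infinity: the single possible edge is essentially certain
    truth = sample_ground_truth(tiny_spec(connect_scale_px=1e12), seed=1)
    assert len(truth.centroids) == 2
    assert truth.edges == [(0, 1)]
    # lambda -> 0: no edges at all
    truth = sample_ground_truth(tiny_spec(connect_scale_px=1e-9), seed=1)
    assert truth.edges == []


def test_edge_frequency_decays_with_distance():
    """Monte-Carlo check of the exponential distance-decay kernel."""
    spec = CultureSpec(
        n_somas=20, connect_scale_px=80.0, debris_count=0, noise_sigma=0.0
    )
    by_bin: dict[int, list[int]] = {i: [] for i in range(6)}
    for seed in range(60):
        truth = sample_ground_truth(spec, seed)
        edge_set = set(truth.edges)
        cent = truth.centroids
        for i in range(spec.n_somas):
            for j in range(i + 1, spec.n_somas):
                d = float(np.hypot(*(cent[i] - cent[j])))
                b = min(int(d // 120), 5)
                by_bin[b].append((i, j) in edge_set)
    freqs = [np.mean(by_bin[b]) for b in range(6) if by_bin[b]]
    assert all(f1 >= f2 for f1, f2 in zip(freqs, freqs[1:]))


def test_ground_truth_reproducible_and_final_degrees():
    spec = CultureSpec(debris_count=5, gap_rate=0.2)
    t1 = sample_ground_truth(spec, seed=9)
    t2 = sample_ground_truth(spec, seed=9)
    assert np.array_equal(t1.centroids, t2.centroids)
    assert t1.edges == t2.edges
    assert t1.gaps == t2.gaps
    final = t1.final_network()
    deg = dict(final.graph.degree())
    expect = {i: 0 for i in range(spec.n_somas)}
    for u, v in t1.edges:
        expect[u] += 1
        expect[v] += 1
    assert deg == expect


def test_birth_snapshots_shortest_first_and_bounded():
    spec = CultureSpec(n_somas=25, connect_scale_px=150.0, debris_count=0)
    truth = sample_ground_truth(spec, seed=4)
    lengths = np.array(
        [np.hypot(*(truth.centroids[u] - truth.centroids[v])) for u, v in truth.edges]
    )
    births = truth.birth_snapshots
    assert births.min() == 0
    assert births.max() <= spec.n_snapshots - 1
    # births are nondecreasing when edges are sorted by length
    order = np.argsort(lengths)
    assert (np.diff(births[order]) >= 0).all()


# ----------------------------------------------------------------------
# Rendering
# ----------------------------------------------------------------------
def test_noiseless_render_soma_centroids_exact():
    spec = tiny_spec()
    truth = sample_ground_truth(spec, seed=2)
    img = render_snapshot(truth, spec, 0, seed=2)
    for (r, c) in truth.centroids:
        assert img.data[int(round(r)), int(round(c))] == spec.soma_level


def test_growth_only_adds_ink():
    spec = CultureSpec(
        n_somas=20, n_snapshots=4, debris_count=0, gap_rate=0.0, noise_sigma=0.0
    )
    truth = sample_ground_truth(spec, seed=3)
    prev = render_snapshot(truth, spec, 0, seed=3)
    for snap in range(1, spec.n_snapshots):
        cur = render_snapshot(truth, spec, snap, seed=3)
        assert (cur.data >= prev.data - 1e-12).all()
        prev = cur


def test_gap_erases_a_run_of_neurite_pixels():
    spec = tiny_spec(gap_rate=1.0, gap_length_px=(5, 5))
    truth = sample_ground_truth(
        dataclasses.replace(spec, connect_scale_px=1e12), seed=5
    )
    assert truth.edges and truth.gaps
    img = render_snapshot(truth, spec, spec.n_snapshots - 1, seed=5)
    poly = truth.polylines[0]
    vals = [
        img.data[int(round(r)), int(round(c))]
        for r, c in poly
    ]
    # background run strictly inside the stroke, at least gap length long
    interior = np.array(vals[5:-5])
    is_bg = interior <= spec.background_level + 1e-9
    runs = np.diff(np.flatnonzero(np.diff(np.concatenate([[0], is_bg, [0]]))))
    assert is_bg.any()
    assert max(runs[::2].max(), 0) >= 5 if runs.size else False


def test_render_deterministic_with_noise():
    spec = tiny_spec(noise_sigma=0.05)
    truth = sample_ground_truth(spec, seed=6)
    a = render_snapshot(truth, spec, 1, seed=6)
    b = render_snapshot(truth, spec, 1, seed=6)
    assert np.array_equal(a.data, b.data)


# ----------------------------------------------------------------------
# Direct graph fixtures
# ----------------------------------------------------------------------
def test_star_fixture():
    net = generate_network_fixture("star", {"n": 5})
    assert net.n_nodes == 5 and net.n_edges == 4
    assert sorted(d for _, d in net.graph.degree())[-1] == 4


def test_ring_fixture_degrees_and_diameter():
    import networkx as nx

    net = generate_network_fixture("ring", {"n": 200})
    assert all(d == 2 for _, d in net.graph.degree())
    assert nx.diameter(net.graph) == 100


def test_uv_flower_counts_match_recursion():
    u, v, g = 2, 2, 3
    # independent recursion: E_g = (u+v) E_{g-1}; N_g = N_{g-1} + E_{g-1}(u+v-2)
    e_exp, n_exp = 1, 2
    for _ in range(g):
        n_exp = n_exp + e_exp * (u + v - 2)
        e_exp = e_exp * (u + v)
    net = generate_network_fixture("uv_flower", {"u": u, "v": v, "generations": g})
    assert (net.n_nodes, net.n_edges) == (n_exp, e_exp)


def test_unknown_fixture_kind_lists_supported():
    with pytest.raises(ValueError, match="ring"):
        generate_network_fixture("torus", {})


def test_geometric_fixture_has_coordinates():
    net = generate_network_fixture("geometric", {"n": 50, "radius": 0.2}, seed=1)
    assert net.n_nodes == 50
    for _, d in net.graph.nodes(data=True):
        assert "row" in d and "col" in d
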