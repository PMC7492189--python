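import math

import networkx as nx
import numpy as np
import pytest

from conftest import as_spatial, random_graph
from oracles import betweenness_oracle, closeness_oracle

from neurocult.metrics import (
    assortativity,
    betweenness_centrality,
    closeness_centrality,
    clustering_summary,
    degree_centrality,
    edge_length_exceedance,
    node_to_node_matrix,
    snapshot_series_summary,
    square_clustering,
)
from neurocult.network import SpatialNetwork
from neurocult.synthetic import generate_network_fixture


def paw_graph() -> nx.Graph:
    g = nx.cycle_graph(3)
    g.add_edge(2, 3)
    return g


# ----------------------------------------------------------------------
# Centralities: closed-form examples
# ----------------------------------------------------------------------
def test_degree_centrality_examples():
    star = nx.star_graph(4)
    assert degree_centrality(star)[0] == 4
    tri = nx.cycle_graph(3)
    assert all(v == 2 for v in degree_centrality(tri).values())
    g = nx.Graph()
    g.add_node(0)
    assert degree_centrality(g)[0] == 0


def test_closeness_path_and_complete():
    path = nx.path_graph(3)
    clo = closeness_centrality(path)
    assert clo[1] == pytest.approx(1 / 2)
    assert clo[0] == pytest.approx(1 / 3)
    k4 = nx.complete_graph(4)
    assert closeness_centrality(k4)[0] == pytest.approx(1 / 3)


def test_closeness_singleton_is_zero():
    g = nx.Graph()
    g.add_node(0)
    assert closeness_centrality(g)[0] == 0.0


def test_betweenness_star_and_cycle():
    star = nx.star_graph(3)  # center + 3 leaves
    bet = betweenness_centrality(star)
    assert bet[0] == pytest.approx(3.0)
    assert all(bet[v] == 0 for v in (1, 2, 3))
    c4 = nx.cycle_graph(4)
    bet = betweenness_centrality(c4)
    assert all(b == pytest.approx(0.5) for b in bet.values())


def test_normalized_variants_scale():
    g = nx.path_graph(5)
    n = g.number_of_nodes()
    deg_raw = degree_centrality(g)
    deg_norm = degree_centrality(g, normalized=True)
    clo_raw = closeness_centrality(g)
    clo_norm = closeness_centrality(g, normalized=True)
    for v in g:
        assert deg_norm[v] == pytest.approx(deg_raw[v] / (n - 1))
        assert clo_norm[v] == pytest.approx(clo_raw[v] * (n - 1))


def test_centralities_match_bruteforce_oracles():
    """Exhaustive BFS / path-enumeration oracles on small random graphs."""
    rng = np.random.default_rng(42)
    for _ in range(60):
        g = random_graph(rng)
        deg = degree_centrality(g)
        assert deg == {v: d for v, d in g.degree()}
        clo = closeness_centrality(g)
        clo_ref = closeness_oracle(g)
        bet = betweenness_centrality(g)
        bet_ref = betweenness_oracle(g)
        for v in g:
            assert clo[v] == pytest.approx(clo_ref[v], abs=1e-12)
            assert bet[v] == pytest.approx(bet_ref[v], abs=1e-9)


# ----------------------------------------------------------------------
# Degree mixing and assortativity
# ----------------------------------------------------------------------
def test_mixing_matrix_increment_rule():
    # a degree-5 node joined to a degree-4 node inside a host graph
    g = nx.Graph()
    g.add_edges_from((0, i) for i in range(1, 6))  # deg(0) = 5
    g.add_edges_from((1, i) for i in range(6, 9))  # deg(1) = 1 + 3
    m = node_to_node_matrix(g).matrix
    assert m[5, 4] == 1 and m[4, 5] == 1


def test_mixing_matrix_triangle_and_conservation():
    tri = nx.cycle_graph(3)
    mix = node_to_node_matrix(tri)
    assert mix.matrix[2, 2] == 6
    assert mix.matrix.sum() == 6
    assert mix.peaks == [(2, 2)]

    rng = np.random.default_rng(3)
    for _ in range(50):
        g = random_graph(rng)
        m = node_to_node_matrix(g).matrix
        assert np.array_equal(m, m.T)
        assert m.sum() == 2 * g.number_of_edges()


def test_mixing_matrix_empty_graph():
    g = nx.empty_graph(4)
    mix = node_to_node_matrix(g)
    assert mix.matrix.sum() == 0
    assert mix.peaks == []


def test_assortativity_closed_forms():
    assert assortativity(nx.star_graph(3)) == pytest.approx(-1.0)
    assert assortativity(nx.path_graph(4)) == pytest.approx(-0.5)
    assert math.isnan(assortativity(nx.cycle_graph(5)))  # 2-regular
    with pytest.raises(ValueError):
        assortativity(nx.empty_graph(3))


def test_assortativity_matches_networkx_pearson():
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 40:
        g = random_graph(rng)
        if g.number_of_edges() == 0:
            continue
        r = assortativity(g)
        if math.isnan(r):
            checked += 1
            continue
        ref = nx.degree_assortativity_coefficient(g)
        assert r == pytest.approx(ref, abs=1e-12)
        checked += 1


# ----------------------------------------------------------------------
# Clustering
# ----------------------------------------------------------------------
def test_clustering_triangle():
    s = clustering_summary(nx.cycle_graph(3))
    assert s.transitivity == pytest.approx(1.0)
    assert s.clustering == pytest.approx(1.0)
    assert s.square_clustering == pytest.approx(0.0)


def test_clustering_paw():
    s = clustering_summary(paw_graph())
    assert s.transitivity == pytest.approx(3 / 5)
    assert s.clustering == pytest.approx(7 / 9)


def test_square_clustering_four_cycle_and_k23():
    for v, c in square_clustering(nx.cycle_graph(4)).items():
        assert c == pytest.approx(1.0)
    for v, c in square_clustering(nx.complete_bipartite_graph(2, 3)).items():
        assert c == pytest.approx(1.0)


def test_clustering_undefined_without_degree_two_nodes():
    g = nx.Graph()
    g.add_edge(0, 1)
    s = clustering_summary(g)
    assert s.transitivity == 0.0
    assert math.isnan(s.clustering)
    assert math.isnan(s.square_clustering)


def test_clustering_ranges_on_random_graphs():
    rng = np.random.default_rng(11)
    for _ in range(40):
        g = random_graph(rng)
        s = clustering_summary(g)
        for val in (s.transitivity, s.clustering, s.square_clustering):
            if not math.isnan(val):
                assert 0.0 <= val <= 1.0


# ----------------------------------------------------------------------
# Exceedance curve
# ----------------------------------------------------------------------
def _net_with_lengths(lengths):
    g = nx.Graph()
    coords = {}
    for i, ell in enumerate(lengths):
        a, b = 2 * i, 2 * i + 1
        coords[a] = (0.0, float(10 * i))
        coords[b] = (float(ell), float(10 * i))
        g.add_edge(a, b)
    return SpatialNetwork.from_coordinates(coords, g.edges())


def test_exceedance_small_example():
    curve = edge_length_exceedance(_net_with_lengths([1.0, 2.0, 3.0]))
    assert curve.evaluate(0) == pytest.approx(1.0)
    assert curve.evaluate(1) == pytest.approx(2 / 3)
    assert curve.evaluate(2.5) == pytest.approx(1 / 3)
    assert curve.evaluate(3) == pytest.approx(0.0)
    assert np.all(np.diff(curve.probabilities) <= 0)


def test_exceedance_degenerate_lengths():
    curve = edge_length_exceedance(_net_with_lengths([5.0, 5.0, 5.0]))
    assert curve.evaluate(4.999) == 1.0
    assert curve.evaluate(5.0) == 0.0


def test_exceedance_requires_edges():
    with pytest.raises(ValueError):
        edge_length_exceedance(as_spatial(nx.empty_graph(3)))


# ----------------------------------------------------------------------
# Snapshot series
# ----------------------------------------------------------------------
def test_snapshot_summary_matches_per_snapshot_recomputation():
    rng = np.random.default_rng(5)
    nets = [as_spatial(random_graph(rng, 10), rng) for _ in range(3)]
    for i, net in enumerate(nets):
        net.time_h = float(i)
    summary = snapshot_series_summary(nets)
    for snap, net in enumerate(nets):
        sub = summary.means[summary.means["snapshot"] == snap]
        bet = betweenness_centrality(net)
        expect = float(np.mean(list(bet.values())))
        got = float(sub[sub["metric"] == "betweenness"]["mean"].iloc[0])
        assert got == pytest.approx(expect)
    cdf = summary.cdf("degree", 0)
    assert cdf["cdf"].iloc[-1] == pytest.approx(1.0)
    assert (cdf["value"].diff().dropna() >= 0).all()
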