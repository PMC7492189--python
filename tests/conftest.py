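import itertools

import networkx as nx
import numpy as np
import pytest

from neurocult.network import SpatialNetwork
from neurocult.synthetic import CultureSpec


def random_graph(rng: np.random.Generator, n_max: int = 7) -> nx.Graph:
    """A small random graph (possibly disconnected) for oracle tests."""
    n = int(rng.integers(2, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < rng.uniform(0.2, 0.8):
            g.add_edge(u, v)
    return g


def as_spatial(g: nx.Graph, rng: np.random.Generator | None = None) -> SpatialNetwork:
    rng = rng or np.random.default_rng(0)
    coords = {v: (float(rng.uniform(0, 100)), float(rng.uniform(0, 100))) for v in g}
    return SpatialNetwork.from_coordinates(coords, g.edges())


@pytest.fixture
def clean_culture_spec() -> CultureSpec:
    """Defaults with every corruption channel switched off."""
    return CultureSpec(debris_count=0, gap_rate=0.0, noise_sigma=0.0)


@pytest.fixture
def small_culture_spec() -> CultureSpec:
    """A small fast culture for pipeline-level tests."""
    return CultureSpec(
        field_height_px=640,
        field_width_px=640,
        n_somas=15,
        n_snapshots=3,
        debris_count=8,
        gap_rate=0.1,
        noise_sigma=0.01,
    )
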