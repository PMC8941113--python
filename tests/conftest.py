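"""Shared fixtures: small oracle implementations and reusable instances."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from hypercore import netbuild as nb
from hypercore import synthetic_data as sd


def naive_coreness(g: nx.Graph) -> dict:
    """Brute-force coreness by repeated minimum-degree deletion.

    For k = 1, 2, ... repeatedly delete any node of degree < k; nodes removed
    during round k have coreness k - 1. Independent of the bucket algorithm
    used by the library.
    """
    coreness = {v: 0 for v in g.nodes()}
    h = g.copy()
    k = 1
    while h.number_of_nodes() > 0:
        while True:
            low = [v for v in h.nodes() if h.degree(v) < k]
            if not low:
                break
            for v in low:
                coreness[v] = k - 1
                h.remove_node(v)
        for v in h.nodes():
            coreness[v] = k
        k += 1
    return coreness


def scale_free_correlation_matrix(n: int = 800, seed: int = 5,
                                  edge_rho: float = 0.5,
                                  background_rho: float = 0.2):
    """Correlation matrix whose 0.4-thresholded graph is scale-free.

    A Havel-Hakimi realization of an exact power-law (exponent 2.5) degree
    sequence, made connected by bridging components, defines the edge set;
    edges get correlation ``edge_rho``, non-edges ``background_rho``.
    Returns (CorrelationMatrix, graph).
    """
    rng = np.random.default_rng(seed)
    k = np.floor(2.0 * (1 - rng.random(n)) ** (-1 / 1.5)).astype(int)
    k = np.clip(k, 2, n // 4)
    if k.sum() % 2:
        k[0] += 1
    g = nx.havel_hakimi_graph(sorted(k.tolist()))
    comps = [sorted(c) for c in nx.connected_components(g)]
    for a, b in zip(comps, comps[1:]):
        g.add_edge(a[0], b[0])
    adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes()))
    c = np.where(adj > 0, edge_rho, background_rho)
    np.fill_diagonal(c, 1.0)
    return nb.CorrelationMatrix(c, np.arange(n)), g


@pytest.fixture(scope="session")
def s1_instance():
    """One S1 sample (n=500, gamma=2.5, beta=2.5, <k>=10) with its truth."""
    g, truth = sd.sample_s1_network(500, 2.5, 10.0, 2.5, seed=1)
    lcc, _ = nb.largest_component(g)
    return lcc, truth


@pytest.fixture(scope="session")
def s1_embedding(s1_instance):
    """The S1 instance embedded once (shared across embedding tests)."""
    from hypercore import hypembed as he

    lcc, truth = s1_instance
    return he.embed(lcc, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """One subject of each dominance pattern at default effect sizes."""
    spec = sd.CohortSpec(
        n_subjects=3,
        pattern_mix={"DMN-dominant": 1, "VN-dominant": 1, "distributed": 1},
        seed=7,
    )
    return sd.make_cohort(spec)


@pytest.fixture()
def k4_pendant():
    """K4 plus one pendant vertex hanging off node 0."""
    g = nx.complete_graph(4)
    g.add_edge(0, 4)
    return g
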