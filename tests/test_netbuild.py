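"""Correlation, thresholding, largest component and threshold selection."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypercore import netbuild as nb
from hypercore.io_formats import BoldMatrix

from conftest import scale_free_correlation_matrix


def _bold(values, tr=1.0):
    n = values.shape[0]
    ids = np.arange(n)
    grid = np.column_stack([ids, np.zeros(n, int), np.zeros(n, int)])
    return BoldMatrix(values, ids, grid, grid.astype(float), tr)


@pytest.mark.parametrize(
    "series, expected",
    [((1, 1, 1), 0.0), ((1, 2, 3), 1.0), ((0, 2), 2.0)],
)
def test_sample_variance_closed_forms(series, expected):
    assert nb.sample_variance(series) == pytest.approx(expected, abs=1e-12)


def test_sample_variance_needs_two_points():
    with pytest.raises(ValueError):
        nb.sample_variance([1.0])


class TestSamplePearson:
    def test_closed_forms(self):
        x = np.array([1.0, 2.0, 3.0])
        assert nb.sample_pearson(x, x) == pytest.approx(1.0)
        assert nb.sample_pearson(x, -x) == pytest.approx(-1.0)
        assert nb.sample_pearson(x, [1, 2, 4]) == pytest.approx(
            0.9819805060619659, abs=1e-12
        )

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 50))
        r = nb.sample_pearson(x, y)
        assert nb.sample_pearson(y, x) == pytest.approx(r, abs=1e-12)
        assert nb.sample_pearson(3.0 * x + 1.0, y) == pytest.approx(
            r, abs=1e-12
        )

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            nb.sample_pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationMatrix:
    def test_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(1)
        b = _bold(rng.standard_normal((30, 40)))
        c = nb.correlation_matrix(b)
        for i in range(30):
            for j in range(i + 1, 30):
                assert c.values[i, j] == pytest.approx(
                    nb.sample_pearson(b.values[i], b.values[j]), abs=1e-12
                )

    def test_identical_rows_give_unit_correlation(self):
        row = np.random.default_rng(2).standard_normal(20)
        b = _bold(np.vstack([row, row]))
        c = nb.correlation_matrix(b)
        assert c.values[0, 1] == pytest.approx(1.0)

    def test_constant_row_reported_with_id(self):
        b = _bold(np.vstack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ValueError, match=r"\[0\]"):
            nb.correlation_matrix(b)


class TestThresholdGraph:
    def _matrix(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.5
        c[0, 2] = c[2, 0] = 0.3
        c[1, 2] = c[2, 1] = -0.8
        return nb.CorrelationMatrix(c, np.arange(3))

    def test_strict_positive_rule(self):
        g = nb.threshold_graph(self._matrix(), 0.4)
        assert set(g.edges()) == {(0, 1)}

    def test_negative_correlations_never_edges(self):
        for t in (0.01, 0.2, 0.7):
            g = nb.threshold_graph(self._matrix(), t)
            assert not g.has_edge(1, 2)

    def test_high_threshold_empty(self):
        g = nb.threshold_graph(self._matrix(), 0.999)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            nb.threshold_graph(self._matrix(), 1.2)

    def test_degree_equals_count_above_threshold(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-1, 1, (20, 20))
        c = (a + a.T) / 2
        np.fill_diagonal(c, 1.0)
        cm = nb.CorrelationMatrix(c, np.arange(20))
        g = nb.threshold_graph(cm, 0.3)
        for i in range(20):
            expected = np.sum(c[i] > 0.3) - 1  # minus the diagonal
            assert g.degree(i) == expected


class TestLargestComponent:
    def test_connected_graph(self):
        g = nx.path_graph(5)
        sub, frac = nb.largest_component(g)
        assert frac == 1.0

    def test_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(3))
        sub, frac = nb.largest_component(g)
        assert frac == pytest.approx(5 / 8)
        assert sub.number_of_nodes() == 5

    def test_all_isolated(self):
        g = nx.empty_graph(4)
        sub, frac = nb.largest_component(g)
        assert sub.number_of_nodes() == 1
        assert frac == pytest.approx(1 / 4)
        assert min(sub.nodes()) == 0  # tie toward smallest node id

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            nb.largest_component(nx.Graph())


class TestScaleFreeness:
    def test_power_law_sample_passes(self):
        rng = np.random.default_rng(3)
        k = np.floor(2.0 * (1 - rng.random(2000)) ** (-1 / 1.5)).astype(int)
        rep = nb.check_scale_freeness(k)
        assert rep.passes_scalefree
        assert rep.r_squared >= 0.95
        assert rep.slope == pytest.approx(-2.5, abs=0.3)

    def test_er_poisson_fails(self):
        g = nx.gnp_random_graph(2000, 20 / 1999, seed=4)
        rep = nb.check_scale_freeness([d for _, d in g.degree()])
        assert not rep.passes_scalefree

    def test_regular_degrees_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|distinct"):
            nb.check_scale_freeness(np.full(100, 7))


class TestSelectThreshold:
    def test_constructed_matrix_selects_smallest_passing(self):
        cm, _ = scale_free_correlation_matrix()
        rho, reports = nb.select_threshold(cm, [0.4, 0.6])
        assert rho == 0.4
        assert reports[0].passes_scalefree and reports[0].passes_lcc
        assert not (reports[1].passes_scalefree and reports[1].passes_lcc)

    def test_single_passing_candidate(self):
        cm, _ = scale_free_correlation_matrix()
        rho, reports = nb.select_threshold(cm, [0.4])
        assert rho == 0.4
        assert len(reports) == 1

    def test_all_failing_raises_with_near_misses(self):
        cm, _ = scale_free_correlation_matrix()
        with pytest.raises(nb.NoAdmissibleThreshold, match="near-misses"):
            nb.select_threshold(cm, [0.6, 0.7])


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_threshold_monotonicity(seed):
    """Raising the threshold can only remove edges and shrink the LCC."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1, 1, (25, 25))
    c = (a + a.T) / 2
    np.fill_diagonal(c, 1.0)
    cm = nb.CorrelationMatrix(c, np.arange(25))
    prev_edges = None
    prev_lcc = None
    for t in (0.2, 0.4, 0.6, 0.8):
        g = nb.threshold_graph(cm, t)
        edges = {tuple(sorted(e)) for e in g.edges()}
        lcc = (
            max(len(cc) for cc in nx.connected_components(g))
            if g.number_of_nodes()
            else 0
        )
        if prev_edges is not None:
            assert edges <= prev_edges
            assert lcc <= prev_lcc
        prev_edges, prev_lcc = edges, lcc
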