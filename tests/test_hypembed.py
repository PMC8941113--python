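"""Hyperbolic geometry, S1/H2 parameter inference and embedding recovery."""

import networkx as nx
import numpy as np
import pytest

from hypercore import hypembed as he
from hypercore import netbuild as nb
from hypercore import synthetic_data as sd


class TestExactDistance:
    def test_coincident_points(self):
        assert he.hyperbolic_distance_exact(3.0, 3.0, 0.0) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_antipodal_additivity(self):
        # law of cosines at dtheta=pi collapses to d = r1 + r2
        assert he.hyperbolic_distance_exact(4.0, 7.0, np.pi) == pytest.approx(
            11.0, abs=1e-9
        )

    def test_origin_point(self):
        for dth in (0.3, 1.5, np.pi):
            assert he.hyperbolic_distance_exact(0.0, 5.0, dth) == pytest.approx(
                5.0, abs=1e-9
            )

    def test_symmetry(self):
        d1 = he.hyperbolic_distance_exact(2.0, 6.0, 1.2)
        d2 = he.hyperbolic_distance_exact(6.0, 2.0, 1.2)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_triangle_inequality_random_triples(self):
        rng = np.random.default_rng(0)
        n = 10_000
        r = rng.uniform(0, 12, (n, 3))
        th = rng.uniform(0, 2 * np.pi, (n, 3))
        def d(i, j):
            return he.hyperbolic_distance_exact(
                r[:, i], r[:, j], th[:, i] - th[:, j]
            )
        assert np.all(d(0, 2) <= d(0, 1) + d(1, 2) + 1e-9)


class TestApproxDistance:
    def test_closed_form(self):
        assert he.hyperbolic_distance_approx(10.0, 10.0, np.pi) == pytest.approx(
            20.0 + 2 * np.log(np.pi / 2), abs=1e-12
        )

    def test_small_angle_accuracy(self):
        """For separations up to ~1 rad at r >= 5 the asymptotic form tracks
        the law of cosines to better than 1%."""
        rs = np.linspace(5, 15, 11)
        dth = np.linspace(0.1, 1.0, 10)
        for r1 in rs:
            for r2 in rs:
                ex = he.hyperbolic_distance_exact(r1, r2, dth)
                ap = he.hyperbolic_distance_approx(r1, r2, dth)
                assert np.max(np.abs(ap - ex) / ex) < 0.01

    def test_large_angle_bias_is_log_sine_gap(self):
        """At dtheta=pi the approximation overshoots the exact distance by
        exactly 2 ln(pi/2): the asymptote's Delta-theta/2 stands in for
        sin(Delta-theta/2)."""
        ex = he.hyperbolic_distance_exact(10.0, 10.0, np.pi)
        ap = he.hyperbolic_distance_approx(10.0, 10.0, np.pi)
        assert ap - ex == pytest.approx(2 * np.log(np.pi / 2), abs=1e-9)

    def test_validity_bound_enforced(self):
        with pytest.raises(ValueError):
            he.hyperbolic_distance_approx(0.1, 0.1, 1e-6)


class TestConnectionProbability:
    def test_fermi_midpoint(self):
        assert he.connection_probability(5.0, 2.5, 5.0) == pytest.approx(0.5)

    def test_closed_form(self):
        assert he.connection_probability(7.0, 2.0, 5.0) == pytest.approx(
            1 / (1 + np.e**2), abs=1e-12
        )

    def test_limits_and_monotonicity(self):
        d = np.linspace(0, 50, 200)
        p = he.connection_probability(d, 3.0, 10.0)
        assert np.all(np.diff(p) < 0)
        assert he.connection_probability(1e6, 3.0, 10.0) < 1e-10

    def test_beta_bound(self):
        with pytest.raises(ValueError):
            he.connection_probability(1.0, 0.5, 5.0)


class TestInferHiddenDegrees:
    def test_regular_graph_uniform_kappa(self):
        g = nx.circulant_graph(30, [1, 2])  # 4-regular
        kappa = he.infer_hidden_degrees(g, beta=2.5)
        assert np.allclose(kappa, kappa[0])

    def test_recovers_true_hidden_degrees(self, s1_instance):
        lcc, truth = s1_instance
        nodes = sorted(lcc.nodes())
        kappa = he.infer_hidden_degrees(lcc, beta=2.5)
        r = np.corrcoef(kappa, truth.kappa_true[nodes])[0, 1]
        assert r >= 0.9

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            he.infer_hidden_degrees(nx.Graph(), beta=2.5)


class TestEstimateBeta:
    def test_recovers_beta_on_s1_sample(self, s1_instance):
        lcc, _ = s1_instance
        assert 2.0 <= he.estimate_beta(lcc, seed=0) <= 3.0

    def test_tree_rejected(self):
        with pytest.raises(ValueError, match="triangle"):
            he.estimate_beta(nx.random_labeled_tree(30, seed=1))

    def test_monotone_in_observed_clustering(self):
        # denser triangles -> larger beta estimate
        g_lo, _ = sd.sample_s1_network(300, 2.7, 8.0, 1.8, seed=2)
        g_hi, _ = sd.sample_s1_network(300, 2.7, 8.0, 6.0, seed=2)
        g_lo, _ = nb.largest_component(g_lo)
        g_hi, _ = nb.largest_component(g_hi)
        assert he.estimate_beta(g_lo, seed=0) < he.estimate_beta(g_hi, seed=0)


class TestInitializeAngles:
    def test_ring_lattice_recovers_ring_order(self):
        n = 100
        g = nx.circulant_graph(n, [1, 2])
        theta = he.initialize_angles_le(g)
        # circular rank order must advance monotonically around the ring
        diffs = np.mod(np.diff(theta), 2 * np.pi)
        direction = np.sign(np.median(diffs) - np.pi)  # cw or ccw
        steps = diffs if direction < 0 else np.mod(-np.diff(theta), 2 * np.pi)
        assert np.sum(steps < np.pi) >= n - 5

    def test_path_graph_monotone(self):
        g = nx.path_graph(30)
        theta = he.initialize_angles_le(g, equal_spacing=False)
        unwrapped = np.unwrap(theta)
        d = np.diff(unwrapped)
        assert np.all(d > 0) or np.all(d < 0)

    def test_complete_graph_accepts_degeneracy(self):
        theta = he.initialize_angles_le(nx.complete_graph(12))
        assert theta.shape == (12,)
        assert np.all((0 <= theta) & (theta < 2 * np.pi))

    def test_disconnected_rejected(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        with pytest.raises(ValueError):
            he.initialize_angles_le(g)


class TestRefineAndEmbed:
    def test_likelihood_trace_monotone(self, s1_embedding):
        trace = s1_embedding.loglik_trace
        assert len(trace) >= 2
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
        assert s1_embedding.loglik == trace[-1]

    def test_ground_truth_recovery(self, s1_instance, s1_embedding):
        lcc, truth = s1_instance
        nodes = sorted(lcc.nodes())
        _, _, sim = he.align_angles(
            truth.theta_true[nodes], s1_embedding.theta
        )
        assert sim >= 0.8

    def test_r_hat_is_outermost_radius(self, s1_embedding):
        assert s1_embedding.R_hat == pytest.approx(
            s1_embedding.r.max(), abs=1e-9
        )

    def test_hub_is_innermost(self, s1_embedding):
        hub = np.argmax(s1_embedding.degree)
        assert s1_embedding.r[hub] == s1_embedding.r.min()

    def test_determinism(self, s1_instance):
        lcc, _ = s1_instance
        kappa = he.infer_hidden_degrees(lcc, 2.5)
        theta0 = he.initialize_angles_le(lcc)
        e1 = he.refine_angles_ml(lcc, theta0, kappa, 2.5, seed=9,
                                 max_sweeps=3)
        e2 = he.refine_angles_ml(lcc, theta0, kappa, 2.5, seed=9,
                                 max_sweeps=3)
        assert np.array_equal(e1.theta, e2.theta)

    def test_toy_graph_smoke(self):
        g = nx.circulant_graph(10, [1, 2])
        e = he.embed(g, seed=0)
        assert e.n_nodes == 10
        assert np.isfinite(e.loglik)


class TestAlignEmbeddings:
    def _dummy(self, theta):
        n = len(theta)
        r = np.full(n, 5.0)
        return he.HyperbolicEmbedding(
            voxel_ids=np.arange(n), r=r, theta=theta,
            degree=np.ones(n, int), kappa=np.ones(n), beta=2.0,
            R_hat=5.0,
        )

    def test_pure_rotation_recovered(self):
        rng = np.random.default_rng(0)
        t1 = rng.uniform(0, 2 * np.pi, 200)
        e1 = self._dummy(t1)
        e2 = self._dummy(np.mod(t1 + 1.0, 2 * np.pi))
        rot, refl, sim = he.align_embeddings(e1, e2)
        assert not refl
        assert rot == pytest.approx(1.0, abs=1e-6)
        assert sim == pytest.approx(1.0, abs=1e-9)

    def test_reflection_recovered(self):
        rng = np.random.default_rng(1)
        t1 = rng.uniform(0, 2 * np.pi, 200)
        rot, refl, sim = he.align_embeddings(
            self._dummy(t1), self._dummy(np.mod(-t1, 2 * np.pi))
        )
        assert refl
        assert sim == pytest.approx(1.0, abs=1e-9)

    def test_independent_angles_low_similarity(self):
        rng = np.random.default_rng(2)
        e1 = self._dummy(rng.uniform(0, 2 * np.pi, 500))
        e2 = self._dummy(rng.uniform(0, 2 * np.pi, 500))
        _, _, sim = he.align_embeddings(e1, e2)
        assert sim < 0.2

    def test_node_set_mismatch(self):
        e1 = self._dummy(np.zeros(5))
        e2 = self._dummy(np.zeros(6))
        with pytest.raises(ValueError):
            he.align_embeddings(e1, e2)


def test_embedding_reproducible_across_seeds(s1_instance, s1_embedding):
    """Two independent refinements of one graph agree up to disc symmetry."""
    lcc, _ = s1_instance
    e2 = he.embed(lcc, seed=202)
    _, _, sim = he.align_embeddings(s1_embedding, e2)
    assert sim >= 0.9
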