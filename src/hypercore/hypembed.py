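"""Hyperbolic disc (S1/H2) embedding of binary graphs by likelihood maximization.

The model places node i at polar coordinates (r_i, theta_i) on a hyperbolic
disc of curvature -zeta^2 (zeta fixed to 1 here) and connects pairs with the
Fermi probability

    p_ij = 1 / (1 + exp((beta/2) * (d_ij - R_hat))),

where d_ij is the hyperbolic distance and R_hat the outermost radial
coordinate. beta > 1 controls clustering: the colder the Fermi rule, the more
link probability concentrates below R_hat and the more triangles the model
produces. Radial coordinates encode popularity via hidden degrees kappa
(expected degree of a node under the model); angular coordinates encode
similarity.

Fitting pipeline (`embed`): estimate beta by matching mean local clustering,
infer hidden degrees by fixed point on expected degrees, seed angles with a
Laplacian-eigenmap projection, then refine them by coordinate-wise
likelihood ascent. Embeddings are identified only up to rotation and
reflection of the disc; `align_embeddings` resolves that gauge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.linalg import eigsh

__all__ = [
    "HyperbolicEmbedding",
    "hyperbolic_distance_exact",
    "hyperbolic_distance_approx",
    "connection_probability",
    "infer_hidden_degrees",
    "estimate_beta",
    "initialize_angles_le",
    "refine_angles_ml",
    "embed",
    "align_embeddings",
    "align_angles",
]

# clamp on the Fermi exponent; equivalent to clamping p to ~[1e-12, 1-1e-12]
_X_CLAMP = 27.6


@dataclass
class HyperbolicEmbedding:
    """Per-node polar coordinates plus the fitted S1/H2 model parameters."""

    voxel_ids: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    degree: np.ndarray
    kappa: np.ndarray
    beta: float
    R_hat: float
    curvature: float = 1.0
    loglik: float = float("nan")
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        self.theta = np.mod(np.asarray(self.theta, dtype=float), 2 * np.pi)
        self.degree = np.asarray(self.degree, dtype=int)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if np.any(self.r < 0):
            raise ValueError("radial coordinates must be >= 0")
        if abs(self.R_hat - self.r.max()) > 1e-9:
            raise ValueError("R_hat must equal the outermost radial coordinate")
        if self.beta <= 1:
            raise ValueError("beta must exceed 1")

    @property
    def n_nodes(self) -> int:
        return len(self.voxel_ids)


def hyperbolic_distance_exact(r1, r2, dtheta, curvature: float = 1.0):
    """Hyperbolic distance from the hyperbolic law of cosines.

    cosh(z*d) = cosh(z*r1) cosh(z*r2) (1 - tanh(z*r1) tanh(z*r2) cos dtheta)

    with z the curvature parameter. Angular separations are wrapped to
    [0, pi]; inputs may be scalars or broadcastable arrays.
    """
    if curvature <= 0:
        raise ValueError("curvature must be positive")
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("radial coordinates must be >= 0")
    dtheta = np.asarray(dtheta, dtype=float)
    if not np.all(np.isfinite(dtheta)):
        raise ValueError("non-finite angular separation")
    dtheta = np.mod(np.abs(dtheta), 2 * np.pi)
    dtheta = np.minimum(dtheta, 2 * np.pi - dtheta)
    z = curvature
    # cosh cosh (1 - tanh tanh cos) == cosh(r1-r2) + 2 sinh sinh sin^2(dth/2):
    # same law, but free of catastrophic cancellation at small separations
    arg = np.cosh(z * (r1 - r2)) + 2.0 * np.sinh(z * r1) * np.sinh(
        z * r2
    ) * np.sin(dtheta / 2.0) ** 2
    d = np.arccosh(np.maximum(arg, 1.0)) / z
    return d if d.ndim else float(d)


def hyperbolic_distance_approx(r1, r2, dtheta):
    """Large-distance approximation d ~ r1 + r2 + 2 ln(dtheta / 2).

    Valid only for dtheta > sqrt(e^(-2 r1) + e^(-2 r2)); below that bound the
    caller must fall back to the exact law of cosines.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    dtheta = np.asarray(dtheta, dtype=float)
    bound = np.sqrt(np.exp(-2 * r1) + np.exp(-2 * r2))
    if np.any(dtheta <= bound):
        raise ValueError(
            "angular separation below the approximation's validity bound"
        )
    d = r1 + r2 + 2.0 * np.log(dtheta / 2.0)
    return d if d.ndim else float(d)


def connection_probability(d, beta: float, R_hat: float):
    """Fermi connection probability p = 1 / (1 + exp((beta/2)(d - R_hat)))."""
    if beta <= 1:
        raise ValueError("beta must exceed 1")
    x = np.clip((beta / 2.0) * (np.asarray(d, dtype=float) - R_hat), -700, 700)
    p = 1.0 / (1.0 + np.exp(x))
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# parameter inference


def _mu(beta: float, mean_degree: float) -> float:
    # density constant of the S1 model making E[degree_i] = kappa_i
    # (exact in the thermodynamic limit)
    return beta * np.sin(np.pi / beta) / (2.0 * np.pi * mean_degree)


def expected_mean_degree(kappa: np.ndarray, beta: float, mu: float) -> float:
    """Expected mean degree of a finite S1 sample with the given parameters.

    Averages the pair connection probability over the uniform angular
    separation on [0, pi]:  p_bar = (theta*/pi) F(pi/theta*),
    theta* = mu kappa_i kappa_j / R,  F(x) = int_0^x du / (1 + u^beta).
    """
    n = len(kappa)
    R = n / (2.0 * np.pi)
    u = np.concatenate([[0.0], np.logspace(-4, 6, 1500)])
    f = np.concatenate(
        [[0.0], np.cumsum(np.diff(u) * 0.5 * ((1 / (1 + u[:-1] ** beta))
                                              + 1 / (1 + u[1:] ** beta)))]
    )
    iu, ju = np.triu_indices(n, k=1)
    theta_star = mu * kappa[iu] * kappa[ju] / R
    x = np.clip(np.pi / theta_star, u[0], u[-1])
    pbar = (theta_star / np.pi) * np.interp(x, u, f)
    return float(2.0 * pbar.sum() / n)


def corrected_mu(kappa: np.ndarray, beta: float,
                 mean_degree_target: float) -> float:
    """Density constant adjusted so the finite sample hits its target mean
    degree.

    The closed-form mu underestimates density in finite samples (angular
    separations are capped at pi and probabilities at 1); a scalar root find
    on a multiplicative correction removes that bias.
    """
    from scipy.optimize import brentq

    mu0 = _mu(beta, mean_degree_target)

    def gap(log_c):
        return expected_mean_degree(kappa, beta,
                                    mu0 * np.exp(log_c)) - mean_degree_target

    lo, hi = -3.0, 3.0
    while gap(hi) < 0 and hi < 30:  # beta near 1 needs huge corrections
        hi += 5.0
    while gap(lo) > 0 and lo > -30:
        lo -= 5.0
    if gap(hi) < 0:
        return mu0 * np.exp(hi)  # target unreachable (denser than complete)
    return mu0 * np.exp(brentq(gap, lo, hi, xtol=1e-6))


def infer_hidden_degrees(g: nx.Graph, beta: float, tol: float = 0.1,
                         max_iter: int = 1000) -> np.ndarray:
    """Hidden degrees kappa by fixed point on model-expected degrees.

    Under the S1 model with uniform angles, the expected degree of node i is
    approximately kappa_i * sum_j kappa_j / sum(kappa) (capping per-pair
    probabilities at 1). Each kappa_i is nudged multiplicatively until the
    expected degree matches the observed degree within ``tol`` (sup-norm).
    Nodes are returned in sorted-node order.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if beta <= 1:
        raise ValueError("beta must exceed 1")
    if not nx.is_connected(g):
        raise ValueError("graph must be connected")
    nodes = sorted(g.nodes())
    k_obs = np.array([g.degree(n) for n in nodes], dtype=float)
    kappa = k_obs.copy()
    for _ in range(max_iter):
        total = kappa.sum()
        pbar = np.minimum(np.outer(kappa, kappa) / total, 1.0)
        np.fill_diagonal(pbar, 0.0)
        expected = pbar.sum(axis=1)
        resid = np.max(np.abs(expected - k_obs))
        if resid < tol:
            return kappa
        kappa *= np.sqrt(k_obs / np.maximum(expected, 1e-12))
        kappa = np.maximum(kappa, 1e-6)
    raise RuntimeError(
        f"hidden-degree fixed point did not converge; residual {resid:.3g}"
    )


def _sample_s1_adjacency(kappa: np.ndarray, beta: float, rng,
                         mu: float | None = None) -> nx.Graph:
    """One S1-model graph with the given hidden degrees (uniform angles)."""
    n = len(kappa)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    if mu is None:
        mu = corrected_mu(kappa, beta, float(kappa.mean()))
    R = n / (2 * np.pi)
    iu, ju = np.triu_indices(n, k=1)
    dtheta = np.abs(theta[iu] - theta[ju])
    dtheta = np.minimum(dtheta, 2 * np.pi - dtheta)
    chi = (R * dtheta) / (mu * kappa[iu] * kappa[ju])
    p = 1.0 / (1.0 + chi**beta)
    keep = rng.random(len(p)) < p
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[keep], ju[keep]))
    return g


def _mean_local_clustering(g: nx.Graph) -> float:
    """Mean local clustering over nodes of degree >= 2.

    Degree-0/1 nodes have no defined triangle fraction; including them as
    zeros would make the statistic depend on how many low-degree nodes a
    particular sample happens to contain rather than on beta.
    """
    nodes = [v for v in g if g.degree(v) >= 2]
    if not nodes:
        return 0.0
    return float(np.mean(list(nx.clustering(g, nodes).values())))


def _model_clustering(kappa: np.ndarray, beta: float, seed: int,
                      n_samples: int = 3) -> float:
    rng = np.random.default_rng(seed)
    mu = corrected_mu(kappa, beta, float(kappa.mean()))
    vals = [
        _mean_local_clustering(_sample_s1_adjacency(kappa, beta, rng, mu=mu))
        for _ in range(n_samples)
    ]
    return float(np.mean(vals))


def estimate_beta(g: nx.Graph, seed: int = 0, tol: float = 0.01,
                  beta_max: float = 10.0) -> float:
    """Fit beta by matching model-expected mean local clustering.

    Bisection on beta in (1, beta_max]: for each candidate, S1 graphs with the
    observed degree sequence as hidden degrees are sampled and their mean
    local clustering compared with the graph's. Clustering is monotone
    increasing in beta, so bisection converges; the search stops when the
    bracket is narrower than ``tol`` or the clustering matches within ``tol``.
    """
    if sum(nx.triangles(g).values()) == 0:
        raise ValueError("graph has no triangles; beta is unidentifiable")
    c_obs = _mean_local_clustering(g)
    kappa = np.array([d for _, d in g.degree()], dtype=float)
    kappa = np.maximum(kappa, 1e-6)
    lo, hi = 1.01, beta_max
    c_hi = _model_clustering(kappa, hi, seed)
    if c_obs >= c_hi:
        return hi
    c_lo = _model_clustering(kappa, lo, seed)
    if c_obs <= c_lo:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        c_mid = _model_clustering(kappa, mid, seed)
        if abs(c_mid - c_obs) < tol:
            return mid
        if c_mid < c_obs:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# angular coordinates


def initialize_angles_le(g: nx.Graph, equal_spacing: bool = True) -> np.ndarray:
    """Initial angles from a Laplacian-eigenmap projection onto a circle.

    Takes the two leading nontrivial eigenvectors of the symmetric normalized
    adjacency D^{-1/2} A D^{-1/2} (equivalently, the lowest nontrivial modes
    of the normalized Laplacian) and reads the angle of each node's 2D image,
    wrapped to [0, 2pi). With ``equal_spacing`` (default) nodes are then
    redistributed uniformly around the circle in their eigenmap circular
    order: the eigenmap is reliable about ordering but compresses angular
    spans, and likelihood refinement escapes that distortion poorly on its
    own. Circular rank order is identical either way. Nodes in sorted order.
    """
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    if not nx.is_connected(g):
        raise ValueError("graph must be connected")
    nodes = sorted(g.nodes())
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=float)
    deg = np.asarray(a.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    an = a.multiply(dinv[:, None]).multiply(dinv[None, :]).tocsr()
    n = len(nodes)
    if n <= 300:
        w, v = np.linalg.eigh(an.toarray())
        idx = np.argsort(w)[::-1]
        v = v[:, idx]
    else:
        w, v = eigsh(an, k=3, which="LA")
        idx = np.argsort(w)[::-1]
        v = v[:, idx]
    # column 0 is the trivial Perron mode; columns 1-2 span the circle
    x, y = v[:, 1], v[:, 2]
    theta = np.mod(np.arctan2(y, x), 2 * np.pi)
    if equal_spacing:
        rank = np.argsort(np.argsort(theta, kind="stable"), kind="stable")
        theta = 2 * np.pi * rank / n
    return theta


def _radial_coordinates(kappa: np.ndarray, beta: float, mean_degree: float):
    """Map hidden degrees to H2 radii: densest node innermost."""
    n = len(kappa)
    kappa0 = kappa.min()
    mu = _mu(beta, mean_degree)
    R_hat = 2.0 * np.log(n / (np.pi * mu * kappa0**2))
    r = R_hat - 2.0 * np.log(kappa / kappa0)
    return np.maximum(r, 0.0), float(R_hat)


def _pair_loglik(theta, r, adj, beta, R_hat):
    """Bernoulli log-likelihood of the adjacency under the Fermi rule."""
    n = len(theta)
    iu, ju = np.triu_indices(n, k=1)
    d = hyperbolic_distance_exact(r[iu], r[ju], theta[iu] - theta[ju])
    x = np.clip((beta / 2.0) * (d - R_hat), -_X_CLAMP, _X_CLAMP)
    a = adj[iu, ju]
    # ln p = -log(1+e^x); ln(1-p) = -log(1+e^-x)
    ll = -np.where(a, np.logaddexp(0.0, x), np.logaddexp(0.0, -x))
    return float(ll.sum())


def refine_angles_ml(g: nx.Graph, theta0, kappa, beta: float, seed: int = 0,
                     max_sweeps: int = 30, n_candidates: int = 20,
                     improve_tol: float = 1e-4) -> HyperbolicEmbedding:
    """Coordinate-wise likelihood ascent over angular coordinates.

    Each sweep visits every node and replaces its angle with the best of
    ``n_candidates`` proposals (the current angle, the degree-weighted
    circular mean of its neighbours' angles, and von-Mises-style jitters
    around that mean whose spread shrinks over sweeps). A node moves only if
    its conditional log-likelihood improves, so the total log-likelihood
    trace is non-decreasing. Stops when a sweep improves the total by less
    than ``improve_tol`` or after ``max_sweeps``.
    """
    if beta <= 1:
        raise ValueError("beta must exceed 1")
    nodes = sorted(g.nodes())
    n = len(nodes)
    theta = np.mod(np.asarray(theta0, dtype=float).copy(), 2 * np.pi)
    kappa = np.asarray(kappa, dtype=float)
    if len(theta) != n or len(kappa) != n:
        raise ValueError("theta0/kappa length does not match node count")
    k_obs = np.array([g.degree(v) for v in nodes], dtype=float)
    r, R_hat = _radial_coordinates(kappa, beta, k_obs.mean())
    index = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=bool)
    for u, v in g.edges():
        adj[index[u], index[v]] = True
        adj[index[v], index[u]] = True

    rng = np.random.default_rng(seed)
    cosh_r = np.cosh(r)
    tanh_r = np.tanh(r)
    half_beta = beta / 2.0
    neighbors = [np.flatnonzero(adj[i]) for i in range(n)]

    trace = [_pair_loglik(theta, r, adj, beta, R_hat)]
    for sweep in range(max_sweeps):
        sigma = max(np.pi / 2 * 0.7**sweep, 0.05)
        order = rng.permutation(n)
        for i in order:
            nb = neighbors[i]
            if nb.size == 0:
                continue
            w = kappa[nb]
            z = np.sum(w * np.exp(1j * theta[nb]))
            mean_dir = np.angle(z)
            cand = np.empty(n_candidates)
            cand[0] = theta[i]
            cand[1] = mean_dir
            cand[2:] = mean_dir + sigma * rng.standard_normal(n_candidates - 2)
            # conditional loglik of node i for every candidate angle
            dth = cand[:, None] - theta[None, :]
            arg = cosh_r[i] * cosh_r[None, :] * (
                1.0 - tanh_r[i] * tanh_r[None, :] * np.cos(dth)
            )
            d = np.arccosh(np.maximum(arg, 1.0))
            x = np.clip(half_beta * (d - R_hat), -_X_CLAMP, _X_CLAMP)
            ll = -np.where(adj[i][None, :], np.logaddexp(0.0, x),
                           np.logaddexp(0.0, -x))
            ll[:, i] = 0.0
            scores = ll.sum(axis=1)
            best = int(np.argmax(scores))
            if scores[best] > scores[0]:
                theta[i] = np.mod(cand[best], 2 * np.pi)
        total = _pair_loglik(theta, r, adj, beta, R_hat)
        if total < trace[-1] - 1e-9:  # greedy updates cannot decrease it
            raise RuntimeError("likelihood decreased during sweep")
        improved = total - trace[-1]
        trace.append(total)
        if improved < improve_tol:
            break

    return HyperbolicEmbedding(
        voxel_ids=np.array(nodes),
        r=r,
        theta=theta,
        degree=k_obs.astype(int),
        kappa=kappa,
        beta=float(beta),
        R_hat=R_hat,
        loglik=trace[-1],
        loglik_trace=trace,
    )


def embed(g: nx.Graph, seed: int = 0, max_sweeps: int = 30) -> HyperbolicEmbedding:
    """Full S1/H2 embedding pipeline for a connected binary graph.

    Composition: estimate beta from clustering, infer hidden degrees, seed
    angles with the Laplacian eigenmap, refine by likelihood ascent, and
    convert hidden degrees to radii.
    """
    beta = estimate_beta(g, seed=seed)
    kappa = infer_hidden_degrees(g, beta)
    theta0 = initialize_angles_le(g)
    return refine_angles_ml(g, theta0, kappa, beta, seed=seed,
                            max_sweeps=max_sweeps)


# ---------------------------------------------------------------------------
# gauge alignment


def align_angles(theta_ref, theta_other):
    """Best rotation/reflection taking ``theta_other`` onto ``theta_ref``.

    Similarity is the mean cosine of the aligned angular differences — the
    modulus of the mean phasor of (theta_other - theta_ref) — maximized over
    rotations analytically and over the two reflection states by enumeration.
    Returns (rotation, reflected, similarity): subtracting ``rotation`` from
    (possibly reflected) ``theta_other`` aligns it with ``theta_ref``.
    """
    t1 = np.asarray(theta_ref, dtype=float)
    t2 = np.asarray(theta_other, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError("angle arrays differ in length")
    z_plain = np.mean(np.exp(1j * (t2 - t1)))
    z_refl = np.mean(np.exp(1j * (-t2 - t1)))
    if abs(z_refl) > abs(z_plain):
        return float(np.angle(z_refl)), True, float(abs(z_refl))
    return float(np.angle(z_plain)), False, float(abs(z_plain))


def align_embeddings(e1: HyperbolicEmbedding, e2: HyperbolicEmbedding):
    """Resolve the disc's rotation/reflection gauge between two embeddings."""
    if not np.array_equal(np.sort(e1.voxel_ids), np.sort(e2.voxel_ids)):
        raise ValueError("embeddings cover different node sets")
    o1 = np.argsort(e1.voxel_ids)
    o2 = np.argsort(e2.voxel_ids)
    return align_angles(e1.theta[o1], e2.theta[o2])
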