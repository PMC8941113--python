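"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's needs without any imaging download:

* `sample_s1_network` — geometric S1-model graphs with known angular
  coordinates and hidden degrees, the ground truth for embedding recovery;
* `simulate_bold` — block-correlated Gaussian BOLD series whose thresholded
  correlation graph has modular structure;
* `plant_core` / `make_cohort` — planted dense cores and multi-subject
  cohorts with prescribed dominance patterns (default-mode-network dominant,
  visual-network dominant, or distributed), the ground truth for k-core
  composition and classification.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import BoldMatrix, LabelMap, FUNCTIONAL_15_LABELS

__all__ = [
    "S1GroundTruth",
    "CohortSpec",
    "sample_s1_network",
    "simulate_bold",
    "plant_core",
    "make_cohort",
]


@dataclass
class S1GroundTruth:
    """Planted coordinates and parameters of a sampled S1 network."""

    theta_true: np.ndarray
    kappa_true: np.ndarray
    beta_true: float
    gamma: float
    mean_degree_target: float
    seed: int
    mu: float = float("nan")  # realized density constant (finite-size corrected)


@dataclass
class CohortSpec:
    """Specification of a synthetic multi-subject cohort.

    ``pattern_mix`` gives the number of subjects per dominance pattern, e.g.
    ``{"DMN-dominant": 3, "VN-dominant": 3, "distributed": 3}``. ``within_r``
    is the within-module BOLD correlation of the (elevated) dense modules and
    ``between_r`` the background correlation across modules; ``noise_sd``
    adds white measurement noise on top of the unit-variance signal.
    """

    n_subjects: int
    pattern_mix: dict
    n_voxels: int = 210
    n_timepoints: int = 1200
    noise_sd: float = 0.0
    within_r: float = 0.55
    between_r: float = 0.10
    tr_seconds: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.pattern_mix.values()) != self.n_subjects:
            raise ValueError("pattern_mix counts must sum to n_subjects")
        unknown = set(self.pattern_mix) - {
            "DMN-dominant", "VN-dominant", "distributed"
        }
        if unknown:
            raise ValueError(f"unknown patterns {unknown}")
        if not (0 <= self.between_r < self.within_r < 1):
            raise ValueError("need 0 <= between_r < within_r < 1")


def sample_s1_network(n: int, gamma: float, mean_degree: float, beta: float,
                      seed: int):
    """Sample an S1-model network with power-law hidden degrees.

    Angles are uniform on the circle; hidden degrees follow a Pareto law with
    exponent ``gamma`` and minimum kappa_0 = mean_degree (gamma-2)/(gamma-1),
    so the expected degree of node i equals kappa_i and the expected mean
    degree equals ``mean_degree``. Pairs connect independently with

        p_ij = 1 / (1 + (d_ij / (mu kappa_i kappa_j))^beta),

    d_ij = R * dtheta_ij on a circle of radius R = n / (2 pi). The density
    constant mu starts from the closed form beta sin(pi/beta) / (2 pi
    mean_degree) and is corrected numerically for finite size so the
    expected mean degree equals ``mean_degree`` exactly.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    if gamma <= 2:
        raise ValueError("gamma must exceed 2 (finite-mean hidden degrees)")
    if beta <= 1:
        raise ValueError("beta must exceed 1 (clustered regime)")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2 * np.pi, size=n)
    kappa0 = mean_degree * (gamma - 2.0) / (gamma - 1.0)
    kappa = kappa0 * (1.0 - rng.random(n)) ** (-1.0 / (gamma - 1.0))
    from .hypembed import corrected_mu

    mu = corrected_mu(kappa, beta, mean_degree)
    R = n / (2.0 * np.pi)
    iu, ju = np.triu_indices(n, k=1)
    dtheta = np.abs(theta[iu] - theta[ju])
    dtheta = np.minimum(dtheta, 2 * np.pi - dtheta)
    chi = (R * dtheta) / (mu * kappa[iu] * kappa[ju])
    p = 1.0 / (1.0 + chi**beta)
    keep = rng.random(len(p)) < p
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    truth = S1GroundTruth(theta, kappa, float(beta), float(gamma),
                          float(mean_degree), int(seed), mu=float(mu))
    return g, truth


def _sample_gaussian(cov: np.ndarray, n_timepoints: int, rng) -> np.ndarray:
    """Sample (n, T) rows from N(0, cov); verifies cov is PSD first."""
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-8:
        raise ValueError(
            f"requested covariance is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})"
        )
    w2, v = np.linalg.eigh(cov)
    l = v * np.sqrt(np.clip(w2, 0.0, None))
    z = rng.standard_normal((cov.shape[0], n_timepoints))
    return l @ z


def _block_of(partition: LabelMap, voxel_ids) -> np.ndarray:
    order = {lab: i for i, lab in enumerate(partition.label_order)}
    blocks = []
    for v in voxel_ids:
        labels = partition.labels_of(int(v))
        if not labels:
            raise ValueError(f"partition does not cover voxel {v}")
        blocks.append(order[min(labels, key=lambda l: order[l])])
    return np.array(blocks)


def simulate_bold(n_voxels: int, partition: LabelMap, within_r: float,
                  between_r: float, n_timepoints: int, seed: int,
                  tr_seconds: float = 0.72) -> BoldMatrix:
    """Block-structured Gaussian BOLD series.

    The target correlation matrix has ``within_r`` inside each partition
    block, ``between_r`` across blocks and unit variance; the covariance is
    verified positive semi-definite before sampling.
    """
    if not (0 <= between_r < within_r < 1) and not (within_r == between_r == 0):
        raise ValueError("need 0 <= between_r < within_r < 1")
    rng = np.random.default_rng(seed)
    voxel_ids = np.arange(n_voxels)
    blocks = _block_of(partition, voxel_ids)
    same = blocks[:, None] == blocks[None, :]
    cov = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(cov, 1.0)
    values = _sample_gaussian(cov, n_timepoints, rng)
    grid = np.column_stack([voxel_ids, np.zeros(n_voxels, int),
                            np.zeros(n_voxels, int)])
    return BoldMatrix(values, voxel_ids, grid, grid.astype(float), tr_seconds)


def plant_core(background: nx.Graph, core_nodes, make_clique: bool = True,
               density: float = 1.0, seed: int = 0) -> nx.Graph:
    """Densify a node set inside a background graph (ground-truth core).

    With ``make_clique`` every within-core pair is connected; otherwise each
    missing pair is added independently with probability ``density``. The
    rest of the graph is untouched.
    """
    core = list(core_nodes)
    missing = [v for v in core if v not in background]
    if missing:
        raise ValueError(f"core nodes {missing} not in graph")
    g = background.copy()
    rng = np.random.default_rng(seed)
    for a in range(len(core)):
        for b in range(a + 1, len(core)):
            if make_clique or rng.random() < density:
                g.add_edge(core[a], core[b])
    return g


# ---------------------------------------------------------------------------
# cohort generator

# seven-category membership of the fifteen functional labels (kept local to
# avoid importing corecomp; corecomp owns the canonical mapping)
_CATEGORY_OF = {
    "DMN": "DMN", "aDMN": "DMN", "PCN": "DMN",
    "SN": "SN", "DAN": "DAN",
    "L CEN": "CEN", "R CEN": "CEN",
    "SMN1": "SMN", "SMN2": "SMN", "AN": "AN",
    "VN1": "VN", "VN2": "VN", "VN3": "VN", "VN4": "VN", "VAN": "VN",
}


def _cohort_partition(n_voxels: int) -> LabelMap:
    """Equal-size partition of voxels over the fifteen functional labels."""
    base = n_voxels // 15
    sizes = [base + (1 if i < n_voxels % 15 else 0) for i in range(15)]
    membership = {}
    v = 0
    for lab, size in zip(FUNCTIONAL_15_LABELS, sizes):
        for _ in range(size):
            membership[v] = {lab}
            v += 1
    return LabelMap("functional-15", membership, list(FUNCTIONAL_15_LABELS))


def _subject_covariance(blocks: np.ndarray, labels: list, pattern: str,
                        within_r: float, between_r: float) -> np.ndarray:
    """Correlation matrix implementing one dominance pattern.

    Distributed subjects: every label block at ``within_r``, ``between_r``
    elsewhere — all modules equally dense. Dominant subjects: the dominant
    category's blocks are fused into one dense module at ``within_r`` while
    the remaining blocks are suppressed to the midpoint of (within_r,
    between_r), below the 0.4 edge threshold, so only the dominant module
    survives thresholding as a dense core.
    """
    n = len(blocks)
    lab_of = np.array([labels[b] for b in blocks])
    cat_of = np.array([_CATEGORY_OF[l] for l in lab_of])
    same_block = blocks[:, None] == blocks[None, :]
    cov = np.full((n, n), between_r)
    if pattern == "distributed":
        cov[same_block] = within_r
    else:
        dom = "DMN" if pattern == "DMN-dominant" else "VN"
        in_dom = cat_of == dom
        dom_pair = in_dom[:, None] & in_dom[None, :]
        suppressed = 0.5 * (within_r + between_r)
        cov[same_block] = suppressed
        cov[dom_pair] = within_r
    np.fill_diagonal(cov, 1.0)
    return cov


def make_cohort(spec: CohortSpec):
    """Generate a synthetic cohort of (BoldMatrix, LabelMap, intended_pattern).

    Subjects are laid out pattern-by-pattern in the order DMN-dominant,
    VN-dominant, distributed; each gets an independent substream of the
    cohort seed.
    """
    partition = _cohort_partition(spec.n_voxels)
    blocks = _block_of(partition, np.arange(spec.n_voxels))
    out = []
    subject = 0
    for pattern in ("DMN-dominant", "VN-dominant", "distributed"):
        for _ in range(spec.pattern_mix.get(pattern, 0)):
            rng = np.random.default_rng([spec.seed % (2**31), subject])
            cov = _subject_covariance(blocks, partition.label_order, pattern,
                                      spec.within_r, spec.between_r)
            values = _sample_gaussian(cov, spec.n_timepoints, rng)
            if spec.noise_sd > 0:
                values = values + spec.noise_sd * rng.standard_normal(
                    values.shape
                )
            vids = np.arange(spec.n_voxels)
            grid = np.column_stack([vids, np.zeros_like(vids),
                                    np.zeros_like(vids)])
            bold = BoldMatrix(values, vids, grid, grid.astype(float),
                              spec.tr_seconds)
            out.append((bold, partition, pattern))
            subject += 1
    return out
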