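"""From BOLD matrices to thresholded, scale-free, largest-component binary graphs.

Functional connectivity between two voxels is the sample Pearson correlation of
their BOLD series; edges are kept where the correlation strictly exceeds a
positive threshold (negative correlations never form edges). The working
threshold is the smallest candidate for which (a) the degree distribution is
scale-free — a straight line on a log-log plot of the log-binned degree PDF —
and (b) the largest connected component retains at least 80% of the voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_formats import BoldMatrix

__all__ = [
    "CorrelationMatrix",
    "ScaleFreeReport",
    "NoAdmissibleThreshold",
    "sample_variance",
    "sample_pearson",
    "correlation_matrix",
    "threshold_graph",
    "largest_component",
    "check_scale_freeness",
    "select_threshold",
    "DEFAULT_CANDIDATES",
]

#: default tentative threshold grid; 0.40 is the reference operating point
DEFAULT_CANDIDATES = (0.30, 0.35, 0.40, 0.45, 0.50)

#: minimum fraction of voxels the largest component must retain
LCC_FRACTION_MIN = 0.80

#: linearity criterion on the log-log degree-PDF fit
R_SQUARED_MIN = 0.90


@dataclass
class CorrelationMatrix:
    """Symmetric voxel x voxel Pearson correlation matrix."""

    values: np.ndarray
    voxel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite correlation entries")
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if v.min() < -1 - 1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("correlations outside [-1, 1]")


@dataclass
class ScaleFreeReport:
    """Audit record for one tentative threshold."""

    threshold: float
    slope: float
    r_squared: float
    lcc_fraction: float
    passes_scalefree: bool
    passes_lcc: bool
    note: str = ""


class NoAdmissibleThreshold(ValueError):
    """No candidate threshold satisfies both criteria."""

    def __init__(self, reports):
        self.reports = reports
        near = "; ".join(
            f"t={r.threshold:g}: R2={r.r_squared:.3f} slope={r.slope:.2f} "
            f"lcc={r.lcc_fraction:.2f}"
            for r in reports
        )
        super().__init__(f"no admissible threshold; near-misses: {near}")


def sample_variance(x) -> float:
    """Unbiased (1/(N-1)) sample variance of a time series."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sum((x - x.mean()) ** 2) / (x.size - 1))


def sample_pearson(x, y) -> float:
    """Sample Pearson correlation of two equally long, non-constant series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series lengths differ")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sx = sample_variance(x)
    sy = sample_variance(y)
    if sx == 0 or sy == 0:
        raise ValueError("undefined correlation for a constant series")
    cov = np.sum((x - x.mean()) * (y - y.mean())) / (x.size - 1)
    return float(np.clip(cov / np.sqrt(sx * sy), -1.0, 1.0))


def correlation_matrix(b: BoldMatrix) -> CorrelationMatrix:
    """Pairwise sample Pearson correlations of all voxel series."""
    sd = b.values.std(axis=1)
    if np.any(sd == 0):
        bad = b.voxel_ids[sd == 0].tolist()
        raise ValueError(f"constant BOLD series for voxels {bad}")
    c = np.corrcoef(b.values)
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(c, b.voxel_ids)


def threshold_graph(c: CorrelationMatrix, rho_threshold: float) -> nx.Graph:
    """Binary graph with an edge wherever correlation > threshold (strict).

    Only positive correlations can form edges; the threshold must lie in (0, 1).
    All voxels appear as nodes even if isolated.
    """
    if not (0 < rho_threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    v = c.values
    iu, ju = np.triu_indices_from(v, k=1)
    keep = v[iu, ju] > rho_threshold
    g = nx.Graph()
    g.add_nodes_from(int(n) for n in c.voxel_ids)
    ids = c.voxel_ids
    g.add_edges_from(
        (int(ids[i]), int(ids[j])) for i, j in zip(iu[keep], ju[keep])
    )
    return g


def largest_component(g: nx.Graph):
    """Induced subgraph on the largest connected component and its node fraction.

    Ties between equally large components are broken toward the one containing
    the smallest node id.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(g))
    comps.sort(key=lambda s: (-len(s), min(s)))
    lcc = comps[0]
    return g.subgraph(lcc).copy(), len(lcc) / g.number_of_nodes()


def _log_binned_pdf(degrees: np.ndarray, bin_ratio: float = 2.0):
    """Logarithmically binned degree PDF; returns (bin centers, density)."""
    k = degrees[degrees > 0].astype(float)
    edges = [k.min()]
    while edges[-1] <= k.max():
        edges.append(edges[-1] * bin_ratio)
    edges = np.array(edges)
    counts, _ = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / (widths * k.size)
    keep = counts > 0
    return centers[keep], dens[keep]


def check_scale_freeness(degrees) -> ScaleFreeReport:
    """Fit a straight line to the log-binned degree PDF on log-log axes.

    A degree sequence passes when the ordinary-least-squares fit has
    R^2 >= 0.90 and slope < -1. The threshold/LCC fields of the report are
    left unset (NaN) — `select_threshold` fills them.
    """
    degrees = np.asarray(degrees)
    k = degrees[degrees > 0]
    if k.size < 20:
        raise ValueError("need at least 20 nonzero degrees")
    centers, dens = _log_binned_pdf(k)
    if len(centers) < 3:
        raise ValueError("degenerate degree distribution (< 3 distinct bins)")
    lx, ly = np.log(centers), np.log(dens)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    passes = bool(r2 >= R_SQUARED_MIN and slope < -1.0)
    return ScaleFreeReport(
        threshold=float("nan"),
        slope=float(slope),
        r_squared=float(r2),
        lcc_fraction=float("nan"),
        passes_scalefree=passes,
        passes_lcc=False,
    )


def select_threshold(c: CorrelationMatrix, candidates=DEFAULT_CANDIDATES):
    """Pick the smallest candidate threshold passing both admission criteria.

    Criteria: scale-free degree distribution of the thresholded graph, and a
    largest connected component holding >= 80% of all voxels. Returns the
    chosen threshold together with the full per-candidate audit trail; raises
    :class:`NoAdmissibleThreshold` listing near-misses when nothing passes.
    """
    candidates = list(candidates)
    if candidates != sorted(candidates):
        raise ValueError("candidates must be sorted ascending")
    reports = []
    chosen = None
    for t in candidates:
        g = threshold_graph(c, t)
        degrees = np.array([d for _, d in g.degree()])
        try:
            rep = check_scale_freeness(degrees)
        except ValueError as exc:
            rep = ScaleFreeReport(
                threshold=t, slope=float("nan"), r_squared=0.0,
                lcc_fraction=0.0, passes_scalefree=False, passes_lcc=False,
                note=str(exc),
            )
        rep.threshold = t
        if g.number_of_edges() > 0:
            _, frac = largest_component(g)
        else:
            frac = 0.0
        rep.lcc_fraction = frac
        rep.passes_lcc = bool(frac >= LCC_FRACTION_MIN)
        reports.append(rep)
        if chosen is None and rep.passes_scalefree and rep.passes_lcc:
            chosen = t
    if chosen is None:
        raise NoAdmissibleThreshold(reports)
    return chosen, reports
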