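"""Angular coherence of labeled voxel groups on the hyperbolic disc.

The angular coherence xi of a set of angles is the modulus of the mean unit
phasor, xi e^{i phi} = (1/N) sum_k e^{i theta_k}: 1 for perfectly
concentrated groups, 0 for balanced spread. phi is the mean direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hypembed import HyperbolicEmbedding
from .io_formats import LabelMap

__all__ = [
    "CoherenceResult",
    "angular_coherence",
    "group_coherence",
    "cohort_coherence_table",
    "laterality_test",
]


@dataclass
class CoherenceResult:
    label: str
    xi: float
    phi: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.xi <= 1.0 + 1e-12):
            raise ValueError("xi must lie in [0, 1]")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")


def angular_coherence(angles):
    """Mean resultant length xi and mean direction phi of a set of angles."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle set")
    z = np.mean(np.exp(1j * angles))
    xi = float(np.abs(z))
    phi = float(np.mod(np.angle(z), 2 * np.pi))
    return min(xi, 1.0), phi


def group_coherence(e: HyperbolicEmbedding, labels: LabelMap):
    """Per-label angular coherence over embedded voxels.

    Voxels outside the embedded node set are excluded; a voxel carrying
    several labels contributes to each of them. Labels with no embedded
    member are absent from the output (not reported as 0).
    """
    theta_of = dict(zip(e.voxel_ids.tolist(), e.theta))
    results = []
    for label in labels.label_order:
        members = [
            theta_of[v]
            for v, labs in labels.membership.items()
            if label in labs and v in theta_of
        ]
        if not members:
            continue
        xi, phi = angular_coherence(members)
        results.append(CoherenceResult(label, xi, phi, len(members)))
    return results


def cohort_coherence_table(per_subject_results) -> pd.DataFrame:
    """Long-format per-label summary (mean, median, SD, n) across subjects."""
    if not per_subject_results:
        raise ValueError("no subjects")
    rows = []
    for s, results in enumerate(per_subject_results):
        for res in results:
            rows.append({"subject": s, "label": res.label, "xi": res.xi})
    df = pd.DataFrame(rows)
    out = (
        df.groupby("label", sort=False)["xi"]
        .agg(mean="mean", median="median", sd="std", n="count")
        .reset_index()
    )
    return out


def laterality_test(left_xi, right_xi):
    """Paired two-sided Wilcoxon signed-rank on left-minus-right coherences.

    Returns (statistic, p_value); identical sides give p = 1 by convention.
    Requires at least 6 pairs.
    """
    left = np.asarray(left_xi, dtype=float)
    right = np.asarray(right_xi, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left/right must be paired (equal length)")
    if left.size < 6:
        raise ValueError("insufficient pairs (need >= 6)")
    diffs = left - right
    if np.all(diffs == 0):
        return 0.0, 1.0
    stat, p = stats.wilcoxon(left, right, alternative="two-sided")
    return float(stat), float(p)
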