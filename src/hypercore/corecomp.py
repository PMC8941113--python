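"""k_max-core composition, dominance classification and the common core.

After k-core percolation, each subject's k_max-core is profiled against the
seven functional categories obtained by combining fifteen ICA subnetworks
(DMN, SN, DAN, CEN, SMN, AN, VN). Subjects whose default-mode (resp. visual)
category holds more than 40% of the core voxels are DMN- (resp. VN-)
dominant; otherwise the pattern is distributed. Voxels appearing in several
categories are counted in each of them, so category fractions can sum above
one. Across subjects, the common core collects voxels present in the
k_max-cores of at least a given fraction (default 60%) of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io_formats import LabelMap

__all__ = [
    "CompositionProfile",
    "CommonCore",
    "SEVEN_CATEGORY_MAP",
    "SEVEN_CATEGORIES",
    "combine_to_seven",
    "kmaxcore_composition",
    "classify_pattern",
    "common_core",
    "kmaxcore_degree_histogram",
]

#: mapping from the fifteen ICA subnetworks to seven functional categories
SEVEN_CATEGORY_MAP = {
    "DMN": "DMN", "aDMN": "DMN", "PCN": "DMN",
    "SN": "SN",
    "DAN": "DAN",
    "L CEN": "CEN", "R CEN": "CEN",
    "SMN1": "SMN", "SMN2": "SMN",
    "AN": "AN",
    "VN1": "VN", "VN2": "VN", "VN3": "VN", "VN4": "VN", "VAN": "VN",
}

SEVEN_CATEGORIES = ["DMN", "SN", "DAN", "CEN", "SMN", "AN", "VN"]

#: a category is dominant when it holds more than this core fraction
DOMINANCE_FRACTION = 0.40


@dataclass
class CompositionProfile:
    """Label composition of one subject's k_max-core."""

    scheme: str
    counts: dict
    fractions: dict
    kmax: int
    core_size: int
    pattern: str = "unset"

    def __post_init__(self) -> None:
        for lab, f in self.fractions.items():
            if not (0.0 <= f <= 1.0 + 1e-12):
                raise ValueError(f"fraction of {lab} outside [0, 1]")
        if self.core_size < 1:
            raise ValueError("core_size must be >= 1")


@dataclass
class CommonCore:
    """Voxels shared by at least ``share_fraction`` of subjects' cores."""

    voxels: set
    share_fraction: float
    subject_counts: dict  # voxel -> number of subjects whose core holds it


def combine_to_seven(labels: LabelMap) -> LabelMap:
    """Collapse the fifteen functional subnetworks into seven categories.

    A voxel in several constituents of one category (e.g. VN1 and VN2) counts
    once in that category.
    """
    if labels.scheme != "functional-15":
        raise ValueError("combine_to_seven expects a functional-15 map")
    membership = {}
    for v, labs in labels.membership.items():
        cats = set()
        for lab in labs:
            if lab not in SEVEN_CATEGORY_MAP:
                raise ValueError(f"unknown source label {lab!r}")
            cats.add(SEVEN_CATEGORY_MAP[lab])
        membership[v] = cats
    return LabelMap("functional-7", membership, list(SEVEN_CATEGORIES))


def kmaxcore_composition(core: set, labels: LabelMap,
                         kmax: int) -> CompositionProfile:
    """Count k_max-core voxels per label (duplicates across labels allowed)."""
    if not core:
        raise ValueError("empty core")
    counts = {lab: 0 for lab in labels.label_order}
    for v in core:
        for lab in labels.labels_of(v):
            counts[lab] += 1
    size = len(core)
    fractions = {lab: c / size for lab, c in counts.items()}
    return CompositionProfile(
        scheme=labels.scheme,
        counts=counts,
        fractions=fractions,
        kmax=int(kmax),
        core_size=size,
    )


def classify_pattern(p: CompositionProfile) -> str:
    """Dominance pattern of a seven-category composition profile.

    VN- or DMN-dominant when the respective fraction exceeds 40%; when both
    exceed it the larger wins and an exact tie is distributed; anything else
    is distributed. The profile's ``pattern`` field is set in place.
    """
    if p.scheme != "functional-7":
        raise ValueError("classification requires the functional-7 scheme")
    f_vn = p.fractions.get("VN", 0.0)
    f_dmn = p.fractions.get("DMN", 0.0)
    if f_vn > DOMINANCE_FRACTION and f_dmn > DOMINANCE_FRACTION:
        if f_vn > f_dmn:
            pattern = "VN-dominant"
        elif f_dmn > f_vn:
            pattern = "DMN-dominant"
        else:
            pattern = "distributed"
    elif f_vn > DOMINANCE_FRACTION:
        pattern = "VN-dominant"
    elif f_dmn > DOMINANCE_FRACTION:
        pattern = "DMN-dominant"
    else:
        pattern = "distributed"
    p.pattern = pattern
    return pattern


def common_core(cores, share_fraction: float = 0.6) -> CommonCore:
    """Voxels present in at least ``share_fraction`` of subjects' cores.

    The threshold is inclusive: with 30 subjects and fraction 0.6, presence
    in 18 cores qualifies.
    """
    cores = list(cores)
    if len(cores) < 2:
        raise ValueError("need at least 2 subjects")
    if not (0 < share_fraction <= 1):
        raise ValueError("share_fraction must be in (0, 1]")
    counts: dict = {}
    for core in cores:
        for v in core:
            counts[v] = counts.get(v, 0) + 1
    need = share_fraction * len(cores) - 1e-9
    members = {v for v, c in counts.items() if c >= need}
    return CommonCore(members, share_fraction, counts)


def kmaxcore_degree_histogram(core: set, g: nx.Graph,
                              labels: LabelMap) -> pd.DataFrame:
    """Degrees of k_max-core voxels read off the full original graph.

    One record per (voxel, category); voxels in several categories appear
    once per category with the same degree, and unlabeled voxels are tagged
    "none". Degrees come from the original adjacency, not the core-induced
    subgraph.
    """
    missing = [v for v in core if v not in g]
    if missing:
        raise ValueError(f"core voxels {missing} missing from graph")
    rows = []
    for v in sorted(core):
        cats = sorted(labels.labels_of(v)) or ["none"]
        for cat in cats:
            rows.append({"voxel_id": v, "degree": g.degree(v),
                         "category": cat})
    return pd.DataFrame(rows)
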