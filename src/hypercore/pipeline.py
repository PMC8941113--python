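"""End-to-end per-subject analysis: BOLD -> graph -> core -> dominance pattern.

Glue over the module stages, used by the cohort analyses and the
classification contract of the synthetic-cohort generator. k-core
percolation runs on the full thresholded graph; the largest component is
reported for the embedding stages, which require a connected substrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .corecomp import (
    CompositionProfile,
    classify_pattern,
    combine_to_seven,
    kmaxcore_composition,
)
from .io_formats import BoldMatrix, LabelMap
from .kcore import CoreDecomposition, kcore_decomposition
from .netbuild import correlation_matrix, largest_component, threshold_graph

__all__ = ["SubjectResult", "analyze_subject"]


@dataclass
class SubjectResult:
    graph: nx.Graph
    lcc_fraction: float
    decomposition: CoreDecomposition
    profile: CompositionProfile
    pattern: str


def analyze_subject(bold: BoldMatrix, labels: LabelMap,
                    rho_threshold: float = 0.4) -> SubjectResult:
    """Threshold, percolate and classify one subject's BOLD matrix.

    Labels may be functional-15 (collapsed to seven categories here) or
    already functional-7.
    """
    c = correlation_matrix(bold)
    g = threshold_graph(c, rho_threshold)
    if g.number_of_edges() == 0:
        raise ValueError("thresholded graph has no edges")
    _, frac = largest_component(g)
    decomp = kcore_decomposition(g)
    seven = combine_to_seven(labels) if labels.scheme == "functional-15" else labels
    profile = kmaxcore_composition(decomp.kmax_core, seven, decomp.k_max)
    pattern = classify_pattern(profile)
    return SubjectResult(g, frac, decomp, profile, pattern)
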