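"""k-core percolation: coreness, k-cores, the k_max-core and S(k) curves.

The k-core of a graph is the maximal subgraph in which every node keeps
degree >= k; it is found by repeatedly deleting nodes of degree < k. A node's
coreness is the largest k whose k-core contains it, and the k_max-core is the
non-empty core with the largest k — one step further, at k_max + 1, the core
disintegrates. S(k), the size of the k-core as k grows, typically shows a
few abrupt drops where whole modules peel off at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import LabelMap

__all__ = [
    "CoreDecomposition",
    "kcore_decomposition",
    "k_core",
    "core_size_curve",
    "detect_abrupt_drops",
    "flag_data",
]


@dataclass
class CoreDecomposition:
    """Per-node coreness with derived core sizes and the k_max-core."""

    coreness: dict  # node -> int
    k_max: int
    core_sizes: dict  # k -> |k-core| for k = 1..k_max
    kmax_core: set

    @classmethod
    def from_coreness(cls, coreness: dict) -> "CoreDecomposition":
        if not coreness:
            raise ValueError("empty decomposition")
        values = np.array(list(coreness.values()))
        k_max = int(values.max())
        core_sizes = {
            k: int(np.sum(values >= k)) for k in range(1, k_max + 1)
        }
        kmax_core = {v for v, c in coreness.items() if c == k_max}
        return cls(coreness, k_max, core_sizes, kmax_core)


def kcore_decomposition(g: nx.Graph) -> CoreDecomposition:
    """Coreness of every node by iterative pruning (bucket algorithm).

    Coreness is independent of pruning order, so the linear-time bucket
    algorithm gives the same answer as naive repeated deletion.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if any(u == v for u, v in g.edges()):
        raise ValueError("graph must be simple (self-loop found)")
    coreness = nx.core_number(g)
    return CoreDecomposition.from_coreness(dict(coreness))


def k_core(g: nx.Graph, k: int) -> set:
    """Node set of the k-core: all nodes with coreness >= k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return set(g.nodes())
    coreness = nx.core_number(g)
    return {v for v, c in coreness.items() if c >= k}


def core_size_curve(d: CoreDecomposition) -> pd.Series:
    """S(k) = |k-core| for k = 1..k_max+1 (S at k_max+1 is 0 by definition)."""
    ks = list(range(1, d.k_max + 2))
    sizes = [d.core_sizes.get(k, 0) for k in ks]
    return pd.Series(sizes, index=pd.Index(ks, name="k"), name="S")


def detect_abrupt_drops(S: pd.Series, min_drop: int | None = None) -> list:
    """All k where the core size falls by at least ``min_drop`` in one step.

    Default ``min_drop`` is 5% of S at k=1 (rounded up). S must be
    non-increasing.
    """
    s = np.asarray(S.values, dtype=float)
    ks = np.asarray(S.index)
    if np.any(np.diff(s) > 0):
        raise ValueError("S(k) must be non-increasing")
    if min_drop is None:
        min_drop = int(np.ceil(0.05 * s[0]))
    drops = s[:-1] - s[1:]
    return [int(k) for k, dk in zip(ks[1:], drops) if dk >= min_drop]


def flag_data(d: CoreDecomposition, labels: LabelMap) -> pd.DataFrame:
    """Per-voxel (voxel, label, coreness) records for flag plots.

    A voxel carrying several labels yields one record per label; unlabeled
    voxels are tagged "none". Within each label, sorting the records by
    descending coreness gives the flag-plot bar order.
    """
    rows = []
    for v, c in d.coreness.items():
        labs = sorted(labels.labels_of(v)) or ["none"]
        for lab in labs:
            rows.append({"voxel_id": v, "label": lab, "coreness": c})
    df = pd.DataFrame(rows)
    order = {lab: i for i, lab in enumerate(labels.label_order + ["none"])}
    df["_o"] = df["label"].map(order)
    df = (
        df.sort_values(["_o", "coreness"], ascending=[True, False])
        .drop(columns="_o")
        .reset_index(drop=True)
    )
    return df
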