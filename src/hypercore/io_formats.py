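"""Readers/writers for neuroimaging and tabular artifacts, plus optional preprocessing.

BOLD series enter the pipeline as a voxel x time matrix (:class:`BoldMatrix`).
Label maps (:class:`LabelMap`) attach functional (ICA-derived) or anatomical
labels to voxels; multi-membership is allowed because a voxel can exceed the
Z-threshold in several independent-component maps at once.

On-disk artifact formats (all plain text):

* edge list — TSV, two 0-based integer columns, each undirected pair once with i<j
* embedding — CSV ``voxel_id,r,theta,degree,kappa`` with ``#``-prefixed header
  lines carrying the model parameters (beta, R_hat, curvature, loglik)
* core decomposition — CSV ``voxel_id,coreness``
* composition profile — JSON ``{scheme, kmax, core_size, counts, fractions, pattern}``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "BoldMatrix",
    "LabelMap",
    "read_bold",
    "bandpass_filter",
    "downsample_blocks",
    "binarize_ic_maps",
    "write_graph",
    "read_graph",
    "write_embedding",
    "read_embedding",
    "write_decomposition",
    "read_decomposition",
    "write_profile",
    "read_profile",
    "FUNCTIONAL_15_LABELS",
]

#: canonical order of the fifteen ICA-derived functional subnetwork labels
FUNCTIONAL_15_LABELS = [
    "DMN", "aDMN", "PCN", "SN", "DAN", "L CEN", "R CEN",
    "SMN1", "SMN2", "AN", "VN1", "VN2", "VN3", "VN4", "VAN",
]

VALID_SCHEMES = {"functional-15", "functional-7", "anatomical-15", "anatomical-8"}


@dataclass
class BoldMatrix:
    """Voxel x time BOLD signal matrix with voxel bookkeeping.

    Attributes
    ----------
    values : ndarray, shape (n_voxels, n_timepoints)
        BOLD signal in arbitrary units.
    voxel_ids : ndarray of int
        Unique 0-based voxel identifiers, one per row.
    grid_index : ndarray, shape (n_voxels, 3)
        Integer (i, j, k) voxel grid coordinates.
    mni_mm : ndarray, shape (n_voxels, 3)
        MNI coordinates in millimetres (from the image affine).
    tr_seconds : float
        Repetition time in seconds.
    """

    values: np.ndarray
    voxel_ids: np.ndarray
    grid_index: np.ndarray
    mni_mm: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        self.grid_index = np.asarray(self.grid_index, dtype=int)
        self.mni_mm = np.asarray(self.mni_mm, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD matrix contains non-finite values")
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("BOLD matrix needs at least 2 timepoints")
        if len(self.voxel_ids) != self.values.shape[0]:
            raise ValueError("row count does not match number of voxel ids")
        if len(np.unique(self.voxel_ids)) != len(self.voxel_ids):
            raise ValueError("voxel ids must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelMap:
    """Voxel -> set-of-labels mapping under a named labeling scheme."""

    scheme: str
    membership: dict  # voxel_id -> set of label names
    label_order: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scheme not in VALID_SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        known = set(self.label_order)
        for v, labels in self.membership.items():
            if not isinstance(labels, (set, frozenset)):
                self.membership[v] = set(labels)
            extra = self.membership[v] - known
            if extra:
                raise ValueError(f"labels {extra} of voxel {v} not in label_order")

    def labels_of(self, voxel_id) -> set:
        return self.membership.get(voxel_id, set())


def read_bold(path, mask=None, tr_seconds=None) -> BoldMatrix:
    """Read a 4D NIfTI BOLD image into a :class:`BoldMatrix`.

    One row per in-mask voxel; ordering is the ascending flattened (C-order)
    grid index, so repeated reads give identical matrices. ``mask`` is an
    optional 3D NIfTI whose nonzero voxels are retained.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got {data.ndim}D")
    if data.shape[3] < 2:
        raise ValueError("need at least 2 timepoints")

    if mask is not None:
        mimg = nib.load(str(mask))
        mdat = np.asanyarray(mimg.dataobj)
        if mdat.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mdat.shape} does not match image {data.shape[:3]}"
            )
        keep = mdat != 0
    else:
        keep = np.ones(data.shape[:3], dtype=bool)
    if not keep.any():
        raise ValueError("empty mask")

    flat = np.flatnonzero(keep.ravel(order="C"))
    ijk = np.column_stack(np.unravel_index(flat, data.shape[:3]))
    affine = img.affine
    mni = nib.affines.apply_affine(affine, ijk)
    values = data[keep.nonzero()].reshape(len(flat), data.shape[3])
    # rows of data[keep.nonzero()] follow C-order of the nonzero mask == flat order
    tr = tr_seconds
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    if tr <= 0:
        tr = 1.0
    return BoldMatrix(values, np.arange(len(flat)), ijk, mni, tr)


def bandpass_filter(b: BoldMatrix, low_hz: float, high_hz: float) -> BoldMatrix:
    """Zero-phase Butterworth band-pass of every voxel series.

    Fourth-order Butterworth applied forward and backward (``filtfilt``), so the
    filter is phase-preserving; each row is demeaned first, making the filter
    exactly DC-free on constant input.
    """
    fs = 1.0 / b.tr_seconds
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyq:.4g}) Hz"
        )
    if not np.all(np.isfinite(b.values)):
        raise ValueError("non-finite input")
    x = b.values - b.values.mean(axis=1, keepdims=True)
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=1)
    return replace(b, values=y)


def downsample_blocks(b: BoldMatrix, factor: int) -> BoldMatrix:
    """Aggregate voxels into ``factor``-cubed grid blocks by mean time series.

    Blocks with no in-mask constituent are dropped; the output grid index is
    the block index (ceil-divided axes) and the MNI coordinate is the mean of
    the constituents'. Output voxel ids are renumbered 0..n_blocks-1 in
    ascending flattened block order.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return b
    block = b.grid_index // factor
    # group rows by block triple, deterministic C-order of block index
    order_key = (block[:, 0], block[:, 1], block[:, 2])
    uniq, inverse = np.unique(block, axis=0, return_inverse=True)
    n_blocks = len(uniq)
    values = np.zeros((n_blocks, b.n_timepoints))
    counts = np.bincount(inverse, minlength=n_blocks).astype(float)
    np.add.at(values, inverse, b.values)
    values /= counts[:, None]
    mni = np.zeros((n_blocks, 3))
    np.add.at(mni, inverse, b.mni_mm)
    mni /= counts[:, None]
    del order_key
    return BoldMatrix(values, np.arange(n_blocks), uniq, mni, b.tr_seconds)


def binarize_ic_maps(zmaps: dict, z_threshold: float = 6.0) -> LabelMap:
    """Binarize per-IC spatial Z-maps into a functional-15 label map.

    ``zmaps`` maps label name -> 3D Z-score array (all on one grid). A voxel
    carries a label iff its Z strictly exceeds ``z_threshold``; voxels may end
    up with several labels (overlapping IC maps). Voxel ids are ascending
    flattened grid indices of the shared grid.
    """
    if not zmaps:
        raise ValueError("no Z-maps given")
    shapes = {np.asarray(z).shape for z in zmaps.values()}
    if len(shapes) != 1:
        raise ValueError(f"Z-map grids do not match: {shapes}")
    (shape,) = shapes
    membership: dict = {}
    labels = [l for l in FUNCTIONAL_15_LABELS if l in zmaps]
    labels += [l for l in zmaps if l not in labels]
    for name in labels:
        z = np.asarray(zmaps[name], dtype=float)
        hits = np.flatnonzero((z > z_threshold).ravel(order="C"))
        for v in hits:
            membership.setdefault(int(v), set()).add(name)
    return LabelMap("functional-15", membership, labels)


# ---------------------------------------------------------------------------
# tabular artifact round-trips


def write_graph(g: nx.Graph, path) -> None:
    """Write an undirected simple graph as a two-column TSV edge list (i<j)."""
    with open(path, "w") as fh:
        fh.write("# nodes\t" + ",".join(str(n) for n in sorted(g.nodes())) + "\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")


def read_graph(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# nodes\t"):
                nodes = line.split("\t", 1)[1]
                if nodes:
                    g.add_nodes_from(int(n) for n in nodes.split(","))
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {line!r}")
            u, v = int(parts[0]), int(parts[1])
            if u == v:
                raise ValueError(f"self-loop on node {u}")
            if g.has_edge(u, v):
                raise ValueError(f"duplicate edge ({u}, {v})")
            g.add_edge(u, v)
    return g


def write_embedding(e, path) -> None:
    """Write a HyperbolicEmbedding as CSV with model parameters in # headers."""
    with open(path, "w") as fh:
        fh.write(f"# beta={float(e.beta)!r}\n")
        fh.write(f"# R_hat={float(e.R_hat)!r}\n")
        fh.write(f"# curvature={float(e.curvature)!r}\n")
        fh.write(f"# loglik={float(e.loglik)!r}\n")
        fh.write("voxel_id,r,theta,degree,kappa\n")
        for i, vid in enumerate(e.voxel_ids):
            fh.write(
                f"{int(vid)},{float(e.r[i])!r},{float(e.theta[i])!r},"
                f"{int(e.degree[i])},{float(e.kappa[i])!r}\n"
            )


def read_embedding(path):
    from .hypembed import HyperbolicEmbedding

    params = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            params[key.strip()] = float(val)
        else:
            body.append(line)
    header = body[0].strip().split(",")
    if header != ["voxel_id", "r", "theta", "degree", "kappa"]:
        raise ValueError(f"unexpected embedding header {header}")
    rows = [line.strip().split(",") for line in body[1:] if line.strip()]
    vids = np.array([int(r[0]) for r in rows])
    return HyperbolicEmbedding(
        voxel_ids=vids,
        r=np.array([float(r[1]) for r in rows]),
        theta=np.array([float(r[2]) for r in rows]),
        degree=np.array([int(r[3]) for r in rows]),
        kappa=np.array([float(r[4]) for r in rows]),
        beta=params["beta"],
        R_hat=params["R_hat"],
        curvature=params["curvature"],
        loglik=params["loglik"],
    )


def write_decomposition(d, path) -> None:
    pd.DataFrame(
        {"voxel_id": list(d.coreness.keys()), "coreness": list(d.coreness.values())}
    ).to_csv(path, index=False)


def read_decomposition(path):
    from .kcore import CoreDecomposition

    df = pd.read_csv(path)
    coreness = dict(zip(df["voxel_id"].astype(int), df["coreness"].astype(int)))
    return CoreDecomposition.from_coreness(coreness)


def write_profile(p, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "scheme": p.scheme,
                "kmax": p.kmax,
                "core_size": p.core_size,
                "counts": dict(p.counts),
                "fractions": dict(p.fractions),
                "pattern": p.pattern,
            },
            fh,
            indent=1,
        )


def read_profile(path):
    from .corecomp import CompositionProfile

    with open(path) as fh:
        d = json.load(fh)
    return CompositionProfile(
        scheme=d["scheme"],
        counts=d["counts"],
        fractions=d["fractions"],
        kmax=d["kmax"],
        core_size=d["core_size"],
        pattern=d["pattern"],
    )
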