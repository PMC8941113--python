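"""Figures: hyperbolic disc scatter, flag plot, S(k) curve, stacked histogram.

Every plot function writes an image file plus a small JSON sidecar
(``<out_path>.json``) recording glyph counts so tests can assert on plot
content without parsing pixels. All functions are deterministic for fixed
inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .hypembed import HyperbolicEmbedding
from .io_formats import LabelMap
from .kcore import detect_abrupt_drops

__all__ = ["PlotSpec", "plot_disc", "plot_flag", "plot_sk_and_hist"]

_KINDS = {"disc", "flag", "sk_curve", "stacked_hist"}

_DEFAULT_COLORS = plt.rcParams["axes.prop_cycle"].by_key()["color"]


@dataclass
class PlotSpec:
    kind: str
    out_path: str
    highlight: set = field(default_factory=set)
    palette: dict = field(default_factory=dict)
    log_radial: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown plot kind {self.kind!r}")


def _sidecar(path, meta: dict) -> None:
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def plot_disc(e: HyperbolicEmbedding, spec: PlotSpec,
              labels: LabelMap | None = None):
    """Polar scatter of the embedding; highlighted voxels colored, rest gray.

    ``spec.highlight`` may contain label names (resolved through ``labels``)
    or voxel ids. Radius is plotted linearly in r by default; with
    ``log_radial`` the radial axis shows log(1 + r).
    """
    if spec.kind != "disc":
        raise ValueError("spec.kind must be 'disc'")
    highlight_ids: dict = {}
    if spec.highlight:
        label_names = {h for h in spec.highlight if isinstance(h, str)}
        node_ids = {h for h in spec.highlight if not isinstance(h, str)}
        if label_names:
            if labels is None:
                raise ValueError("label highlights need a LabelMap")
            unknown = label_names - set(labels.label_order)
            if unknown:
                raise ValueError(f"unknown highlight labels {unknown}")
            for v, labs in labels.membership.items():
                hit = labs & label_names
                if hit:
                    highlight_ids[v] = sorted(hit)[0]
        for v in node_ids:
            highlight_ids[v] = "_nodes"

    r = np.log1p(e.r) if spec.log_radial else e.r
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    is_hl = np.array([v in highlight_ids for v in e.voxel_ids])
    ax.scatter(e.theta[~is_hl], r[~is_hl], s=6, c="0.8", linewidths=0)
    n_highlighted = 0
    if is_hl.any():
        groups: dict = {}
        for i, v in enumerate(e.voxel_ids):
            if v in highlight_ids:
                groups.setdefault(highlight_ids[v], []).append(i)
        for gi, (name, idx) in enumerate(sorted(groups.items())):
            color = spec.palette.get(name,
                                     _DEFAULT_COLORS[gi % len(_DEFAULT_COLORS)])
            ax.scatter(e.theta[idx], r[idx], s=10, c=color, label=str(name),
                       linewidths=0)
            n_highlighted += len(idx)
        ax.legend(loc="upper right", fontsize=7)
    ax.set_title(f"hyperbolic disc (n={e.n_nodes}, beta={e.beta:.2f})")
    fig.savefig(spec.out_path, dpi=120)
    plt.close(fig)
    _sidecar(spec.out_path, {"kind": "disc", "glyphs": int(e.n_nodes),
                             "highlighted": int(n_highlighted)})
    return spec.out_path


def plot_flag(records: pd.DataFrame, spec: PlotSpec,
              label_order: list | None = None):
    """Flag plot: one horizontal bar per (voxel, label), length = coreness.

    Bars are grouped by label and sorted descending by coreness within each
    group, mirroring how core membership thins out as k grows.
    """
    if spec.kind != "flag":
        raise ValueError("spec.kind must be 'flag'")
    if records.empty:
        raise ValueError("no flag records")
    labels = label_order or list(dict.fromkeys(records["label"]))
    fig, ax = plt.subplots(figsize=(6, 8))
    y = 0
    yticks, ylabels = [], []
    n_bars = 0
    for gi, lab in enumerate(labels):
        block = records[records["label"] == lab].sort_values(
            "coreness", ascending=False
        )
        if block.empty:
            continue
        color = spec.palette.get(lab,
                                 _DEFAULT_COLORS[gi % len(_DEFAULT_COLORS)])
        ys = np.arange(y, y + len(block))
        ax.barh(ys, block["coreness"].values, height=1.0, color=color)
        yticks.append(y + len(block) / 2)
        ylabels.append(lab)
        y += len(block) + 2
        n_bars += len(block)
    ax.set_yticks(yticks, ylabels)
    ax.set_xlabel("coreness k")
    ax.invert_yaxis()
    fig.savefig(spec.out_path, dpi=120)
    plt.close(fig)
    _sidecar(spec.out_path, {"kind": "flag", "glyphs": int(n_bars)})
    return spec.out_path


def plot_sk_and_hist(data, spec: PlotSpec, min_drop: int | None = None):
    """S(k) percolation curve with drop markers, or a stacked degree histogram.

    ``data`` is the S(k) series for ``kind='sk_curve'`` (drops detected with
    `detect_abrupt_drops` and marked), or the (voxel, degree, category)
    records for ``kind='stacked_hist'``.
    """
    if spec.kind == "sk_curve":
        S = data
        drops = detect_abrupt_drops(S, min_drop=min_drop)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(S.index, S.values, drawstyle="steps-post")
        for k in drops:
            ax.axvline(k, color="crimson", ls="--", lw=0.8)
        ax.set_xlabel("k")
        ax.set_ylabel("S(k)")
        fig.savefig(spec.out_path, dpi=120)
        plt.close(fig)
        _sidecar(spec.out_path, {"kind": "sk_curve", "glyphs": int(len(S)),
                                 "drops": drops})
    elif spec.kind == "stacked_hist":
        df = data
        cats = list(dict.fromkeys(df["category"]))
        dmin, dmax = int(df["degree"].min()), int(df["degree"].max())
        bins = np.linspace(dmin, dmax + 1, min(30, dmax - dmin + 2))
        fig, ax = plt.subplots(figsize=(6, 4))
        stacks = [df.loc[df["category"] == c, "degree"].values for c in cats]
        colors = [
            spec.palette.get(c, _DEFAULT_COLORS[i % len(_DEFAULT_COLORS)])
            for i, c in enumerate(cats)
        ]
        ax.hist(stacks, bins=bins, stacked=True, label=cats, color=colors)
        ax.set_xlabel("degree in original graph")
        ax.set_ylabel("k_max-core voxels")
        ax.legend(fontsize=7)
        fig.savefig(spec.out_path, dpi=120)
        plt.close(fig)
        _sidecar(spec.out_path, {"kind": "stacked_hist",
                                 "glyphs": int(len(df)),
                                 "categories": len(cats)})
    else:
        raise ValueError("spec.kind must be 'sk_curve' or 'stacked_hist'")
    return spec.out_path
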