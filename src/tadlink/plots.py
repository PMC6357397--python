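"""Figures: correlation-derived pseudo Hi-C maps and per-pair scatters.

Rendering is a pure view of the precomputed pair table: nothing here
recomputes a statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import GenomicInterval, SampleGroups, TADSet

logger = logging.getLogger("tadlink")

NEUTRAL = "#9e9e9e"


@dataclass
class LocusWindow:
    """A genomic window with the features and TADs intersecting it."""

    chrom: str
    start: int
    end: int
    enhancers: list[GenomicInterval]
    genes: list[GenomicInterval]
    tads: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty window {self.chrom}:{self.start}-{self.end}")
        for iv in [*self.enhancers, *self.genes, *self.tads]:
            if iv.chrom != self.chrom or iv.end <= self.start or iv.start >= self.end:
                raise ValueError(f"{iv.id} does not intersect the window")

    @classmethod
    def build(cls, chrom: str, start: int, end: int,
              enhancers: Sequence[GenomicInterval],
              genes: Sequence[GenomicInterval],
              tads: TADSet | Sequence[GenomicInterval]) -> "LocusWindow":
        tad_list = tads.tads if isinstance(tads, TADSet) else list(tads)

        def hits(ivs):
            return [iv for iv in ivs
                    if iv.chrom == chrom and iv.start < end and iv.end > start]

        return cls(chrom, start, end, hits(enhancers), hits(genes),
                   hits(tad_list))

    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def correlation_map(records: pd.DataFrame, window: LocusWindow,
                    stat: str = "correlation",
                    path: str | Path | None = None):
    """Pseudo Hi-C map of pair statistics over a locus.

    Builds the (#enhancers × #genes) matrix of ``stat`` ('correlation'
    or 'neg_log10_q') for the window, both axes in genomic order;
    cells for pairs not co-located in a TAD are NaN (absent — distinct
    from 0) and rendered grey. Enhancers run along x, genes along y;
    TAD extents appear as dashed boxes. Returns (matrix, figure); the
    figure is also written to ``path`` when given (format by extension).
    """
    if stat not in ("correlation", "neg_log10_q"):
        raise ValueError("stat must be 'correlation' or 'neg_log10_q'")
    if not window.enhancers or not window.genes:
        raise ValueError(f"window {window.label()} contains no "
                         f"{'enhancers' if not window.enhancers else 'genes'}")
    enh = sorted(window.enhancers, key=lambda e: (e.start, e.id))
    genes = sorted(window.genes, key=lambda g: (g.start, g.id))
    mat = pd.DataFrame(np.nan, index=[e.id for e in enh],
                       columns=[g.id for g in genes])
    sub = records[records["enhancer_id"].isin(mat.index)
                  & records["gene_id"].isin(mat.columns)]
    vals = sub["correlation"] if stat == "correlation" else \
        -np.log10(np.maximum(sub["q_value"], 1e-300))
    for eid, gid, v in zip(sub["enhancer_id"], sub["gene_id"], vals):
        mat.loc[eid, gid] = v

    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(enh)),
                                    max(3, 0.5 * len(genes))))
    masked = np.ma.masked_invalid(mat.to_numpy().T)
    if stat == "correlation":
        vmax = max(1e-9, np.nanmax(np.abs(mat.to_numpy())) if sub.shape[0] else 1)
        cmap = plt.get_cmap("RdBu_r").copy()
        norm = matplotlib.colors.Normalize(vmin=-vmax, vmax=vmax)
    else:
        cmap = plt.get_cmap("viridis").copy()
        norm = None
    cmap.set_bad(NEUTRAL)
    im = ax.pcolormesh(np.arange(len(enh) + 1), np.arange(len(genes) + 1),
                       masked, cmap=cmap, norm=norm)
    fig.colorbar(im, ax=ax, label="r" if stat == "correlation" else "-log10 q")
    # dashed TAD boxes around the block of co-domained features
    for tad in window.tads:
        ei = [i for i, e in enumerate(enh)
              if tad.start <= e.midpoint < tad.end]
        gi = [j for j, g in enumerate(genes)
              if tad.start <= g.tss < tad.end]
        if ei and gi:
            ax.add_patch(plt.Rectangle(
                (min(ei), min(gi)), max(ei) - min(ei) + 1,
                max(gi) - min(gi) + 1, fill=False, ls="--", lw=1.2,
                ec="black"))
    ax.set_xticks(np.arange(len(enh)) + 0.5)
    ax.set_xticklabels(mat.index, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(len(genes)) + 0.5)
    ax.set_yticklabels(mat.columns, fontsize=7)
    ax.set_xlabel("enhancers")
    ax.set_ylabel("genes")
    ax.set_title(window.label())
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return mat, fig


def pair_plot(enh_vector: pd.Series, expr_vector: pd.Series,
              groups: SampleGroups | None = None,
              labels: tuple[str, str] = ("enhancer signal", "expression"),
              r: float | None = None, q: float | None = None,
              path: str | Path | None = None):
    """Scatter of one enhancer–gene pair across the cohort.

    One point per sample, colored by group (neutral grey for samples
    missing from the annotation, with a warning), least-squares line,
    and an annotation carrying r (2 decimals) and q when provided.
    """
    if list(enh_vector.index) != list(expr_vector.index):
        expr_vector = expr_vector.reindex(enh_vector.index)
        if expr_vector.isna().any():
            raise ValueError("enhancer and expression vectors are not "
                             "aligned to the same samples")
    fig, ax = plt.subplots(figsize=(4.5, 4))
    x = enh_vector.to_numpy(dtype=float)
    y = expr_vector.to_numpy(dtype=float)
    if groups is not None and groups.groups:
        missing = [s for s in enh_vector.index if s not in groups.groups]
        if missing:
            logger.warning("%d samples missing from group annotation; "
                           "drawn in neutral color", len(missing))
        glabels = groups.labels()
        cycle = plt.get_cmap("tab10")
        colors = groups.colors or {g: cycle(i % 10)
                                   for i, g in enumerate(glabels)}
        for g in glabels:
            sel = [i for i, s in enumerate(enh_vector.index)
                   if groups.groups.get(s) == g]
            ax.scatter(x[sel], y[sel], label=g, color=colors[g], s=30,
                       edgecolor="white", linewidth=0.5)
        sel = [i for i, s in enumerate(enh_vector.index)
               if s not in groups.groups]
        if sel:
            ax.scatter(x[sel], y[sel], color=NEUTRAL, s=30, label="n/a")
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.scatter(x, y, color="#3465a4", s=30)
    if np.ptp(x) > 0:
        slope, intercept = np.polyfit(x, y, 1)
        xs = np.array([x.min(), x.max()])
        ax.plot(xs, slope * xs + intercept, color="black", lw=1)
    note = []
    if r is not None:
        note.append(f"r = {r:.2f}")
    if q is not None:
        note.append(f"q = {q:.2g}")
    if note:
        ax.annotate(", ".join(note), xy=(0.03, 0.96),
                    xycoords="axes fraction", va="top", fontsize=9)
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
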