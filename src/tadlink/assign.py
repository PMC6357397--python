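"""Assigning features to TADs and enumerating within-TAD pairs.

Enhancer–gene pairs are only ever tested when both members map to the
same TAD. Features falling in TAD-free territory can optionally be
rescued to the nearest TAD on their chromosome (the default for genes),
so cell-type differences in TAD annotation do not silently discard
candidate target genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .model import GenomicInterval, TADSet

logger = logging.getLogger("tadlink")

ANCHORS = ("midpoint", "tss", "body")

PAIR_COLUMNS = ["tad_id", "enhancer_id", "gene_id", "distance_bp",
                "signed_offset_bp", "enh_in_tad", "gene_in_tad"]


class AssignedTad(NamedTuple):
    tad_id: str
    inside: bool          # anchor overlaps the TAD
    distance_to_tad: int  # bp to the nearest TAD edge; 0 when inside


@dataclass
class TadAssignment:
    """feature id → (tad id, inside flag, distance)."""

    assignments: dict[str, AssignedTad]
    n_unassigned: int = 0

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.assignments

    def __getitem__(self, feature_id: str) -> AssignedTad:
        return self.assignments[feature_id]

    def by_tad(self) -> dict[str, list[str]]:
        """tad id → feature ids, in insertion (input) order."""
        out: dict[str, list[str]] = {}
        for fid, a in self.assignments.items():
            out.setdefault(a.tad_id, []).append(fid)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f, a.tad_id, a.inside, a.distance_to_tad)
             for f, a in self.assignments.items()],
            columns=["feature_id", "tad_id", "inside", "distance_to_tad"])


def _anchor_point(iv: GenomicInterval, anchor: str) -> int:
    return iv.midpoint if anchor == "midpoint" else iv.tss


def _assign_point(pos: int, starts: np.ndarray, ends: np.ndarray,
                  ids: list[str], rescue: bool) -> AssignedTad | None:
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i >= 0 and pos < ends[i]:
        return AssignedTad(ids[i], True, 0)
    if not rescue:
        return None
    # nearest edge: left neighbour i, right neighbour i+1; ties upstream
    best_id, best_d = None, None
    if i >= 0:
        best_id, best_d = ids[i], int(pos - ends[i])
    if i + 1 < len(starts):
        d_right = int(starts[i + 1] - pos)
        if best_d is None or d_right < best_d:
            best_id, best_d = ids[i + 1], d_right
    return AssignedTad(best_id, False, best_d)


def _assign_body(iv: GenomicInterval, starts: np.ndarray, ends: np.ndarray,
                 ids: list[str], rescue: bool) -> AssignedTad | None:
    lo = int(np.searchsorted(ends, iv.start, side="right"))
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    if lo < hi:  # overlaps TADs lo..hi-1; maximal overlap wins, ties leftmost
        ovs = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
        return AssignedTad(ids[lo + int(np.argmax(ovs))], True, 0)
    if not rescue:
        return None
    best_id, best_d = None, None
    if lo - 1 >= 0:
        best_id, best_d = ids[lo - 1], int(iv.start - ends[lo - 1])
    if lo < len(starts):
        d_right = int(starts[lo] - iv.end)
        if best_d is None or d_right < best_d:
            best_id, best_d = ids[lo], d_right
    return AssignedTad(best_id, False, best_d)


def assign_features(features: Sequence[GenomicInterval], tads: TADSet,
                    anchor: str = "midpoint",
                    rescue_nearest: bool = False) -> TadAssignment:
    """Map each feature to a TAD.

    ``anchor`` decides membership: ``midpoint``/``tss`` use a point (a
    point inside a TAD is unambiguous because TADs never overlap);
    ``body`` assigns to the TAD with maximal overlap. Features outside
    every TAD are rescued to the nearest TAD on the same chromosome
    (edge-to-anchor distance, equidistant ties going to the
    lower-coordinate TAD) when ``rescue_nearest`` is set, and omitted
    otherwise. Features on chromosomes with no TAD at all are never
    assigned.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}, got {anchor!r}")
    if len(tads) == 0:
        raise ValueError("empty TAD set")
    assignments: dict[str, AssignedTad] = {}
    n_no_chrom = n_outside = 0
    for iv in features:
        starts, ends, ids = tads.arrays(iv.chrom)
        if len(starts) == 0:
            n_no_chrom += 1
            continue
        if anchor == "body":
            a = _assign_body(iv, starts, ends, ids, rescue_nearest)
        else:
            a = _assign_point(_anchor_point(iv, anchor), starts, ends, ids,
                              rescue_nearest)
        if a is None:
            n_outside += 1
        else:
            assignments[iv.id] = a
    n_un = n_no_chrom + n_outside
    if n_un:
        logger.info("%d features unassigned (%d on TAD-free chromosomes, "
                    "%d outside TADs without rescue)", n_un, n_no_chrom,
                    n_outside)
    n_rescued = sum(1 for a in assignments.values() if not a.inside)
    if n_rescued:
        logger.info("%d features rescued to their nearest TAD", n_rescued)
    return TadAssignment(assignments, n_un)


def enumerate_pairs(enh_assign: TadAssignment, gene_assign: TadAssignment,
                    enh_features: Sequence[GenomicInterval],
                    gene_features: Sequence[GenomicInterval]) -> pd.DataFrame:
    """All enhancer–gene pairs sharing a TAD (Cartesian product per TAD).

    Returns one row per pair with the unsigned enhancer-midpoint to
    gene-TSS distance and a strand-aware signed offset (negative when the
    enhancer lies upstream of the gene), ordered by
    (tad id, enhancer id, gene id). Cross-TAD pairs never appear.
    """
    enh_by = {iv.id: iv for iv in enh_features}
    gene_by = {iv.id: iv for iv in gene_features}
    genes_per_tad = gene_assign.by_tad()
    rows = []
    for tad_id, enh_ids in sorted(enh_assign.by_tad().items()):
        gene_ids = genes_per_tad.get(tad_id)
        if not gene_ids:
            continue
        for eid in sorted(enh_ids):
            mid = enh_by[eid].midpoint
            for gid in sorted(gene_ids):
                g = gene_by[gid]
                delta = mid - g.tss            # + : enhancer right of TSS
                if g.strand == "-":
                    delta = -delta             # + : downstream of the gene
                rows.append((tad_id, eid, gid, abs(delta), delta,
                             enh_assign[eid].inside, gene_assign[gid].inside))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


@dataclass
class TadSetPartition:
    """Ids of TADs common to / specific to two TAD annotations."""

    common_a: list[str]
    common_b: list[str]
    specific_a: list[str]
    specific_b: list[str]
    reciprocal_overlap: float


def compare_tad_sets(tads_a: TADSet, tads_b: TADSet,
                     reciprocal_overlap: float = 0.8) -> TadSetPartition:
    """Partition two TAD sets into common and set-specific TADs.

    A TAD is *common* when some TAD in the other set overlaps it with
    reciprocal overlap ≥ the threshold, i.e. overlap/len ≥ threshold on
    both sides. Each TAD is labeled exactly once.
    """
    if not (0 < reciprocal_overlap <= 1):
        raise ValueError("reciprocal_overlap must be in (0, 1]")

    def common_ids(xs: TADSet, ys: TADSet) -> set[str]:
        out: set[str] = set()
        for x in xs.tads:
            starts, ends, _ids = ys.arrays(x.chrom)
            if len(starts) == 0:
                continue
            lo = int(np.searchsorted(ends, x.start, side="right"))
            hi = int(np.searchsorted(starts, x.end, side="left"))
            for j in range(lo, hi):
                ov = min(ends[j], x.end) - max(starts[j], x.start)
                if ov <= 0:
                    continue
                if (ov / x.length >= reciprocal_overlap
                        and ov / (ends[j] - starts[j]) >= reciprocal_overlap):
                    out.add(x.id)
                    break
        return out

    ca = common_ids(tads_a, tads_b)
    cb = common_ids(tads_b, tads_a)
    return TadSetPartition(
        common_a=sorted(ca),
        common_b=sorted(cb),
        specific_a=sorted({t.id for t in tads_a.tads} - ca),
        specific_b=sorted({t.id for t in tads_b.tads} - cb),
        reciprocal_overlap=reciprocal_overlap,
    )
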