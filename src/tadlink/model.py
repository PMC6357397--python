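"""Core genomic data containers.

All coordinates are 0-based half-open (BED convention). GTF input is
converted at the parsing boundary (see :mod:`tadlink.io`); nothing
downstream ever sees 1-based coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tadlink")

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A located feature: enhancer, gene or TAD.

    ``start``/``end`` are 0-based half-open. ``strand`` is ``'+'``, ``'-'``
    or ``'.'`` (unstranded); enhancers and TADs are normally unstranded.
    """

    chrom: str
    start: int
    end: int
    id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.id}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def tss(self) -> int:
        """Transcription start site: leftmost base for +/unstranded,
        rightmost base (end − 1) for − strand."""
        return self.start if self.strand != "-" else self.end - 1


def _check_unique_ids(intervals: Sequence[GenomicInterval], what: str) -> None:
    ids = [iv.id for iv in intervals]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicated {what} ids: {dups[:10]}")


@dataclass
class FeatureMatrix:
    """A features × samples numeric matrix bound to genomic coordinates.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample-id columns; finite,
        non-negative normalized signal (e.g. RPKM).
    features
        ``GenomicInterval`` per row, in row order.
    feature_meta
        Optional per-feature attributes (e.g. ``gene_name``,
        ``gene_biotype``), indexed like ``values``.
    """

    values: pd.DataFrame
    features: list[GenomicInterval]
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.features) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.features)} coordinate records for "
                f"{self.values.shape[0]} matrix rows"
            )
        ids = [f.id for f in self.features]
        if list(self.values.index) != ids:
            raise ValueError("matrix row order does not match feature order")
        _check_unique_ids(self.features, "feature")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicated sample ids: {sorted(set(dups))}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            n_bad = int((~np.isfinite(arr)).sum())
            raise ValueError(f"matrix contains {n_bad} missing/non-finite entries")
        if self.feature_meta is not None and list(self.feature_meta.index) != ids:
            raise ValueError("feature_meta index does not match features")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def interval(self, feature_id: str) -> GenomicInterval:
        return self._by_id[feature_id]

    @property
    def _by_id(self) -> dict[str, GenomicInterval]:
        d = getattr(self, "_by_id_cache", None)
        if d is None:
            d = {f.id: f for f in self.features}
            object.__setattr__(self, "_by_id_cache", d)
        return d

    def subset_samples(self, samples: Sequence[str]) -> "FeatureMatrix":
        """Column-subset (and reorder) to ``samples``; features unchanged."""
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return FeatureMatrix(self.values[list(samples)], list(self.features),
                             self.feature_meta)

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        """Row-subset (and reorder) to ``feature_ids``."""
        wanted = set(feature_ids)
        missing = wanted - set(self.values.index)
        if missing:
            raise KeyError(f"features absent from matrix: {sorted(missing)[:10]}")
        keep = [f for f in self.features if f.id in wanted]
        order = [f.id for f in keep]
        meta = self.feature_meta.loc[order] if self.feature_meta is not None else None
        return FeatureMatrix(self.values.loc[order], keep, meta)


@dataclass
class TADSet:
    """An ordered, per-chromosome collection of non-overlapping TADs."""

    tads: list[GenomicInterval]
    source_label: str = ""

    def __post_init__(self) -> None:
        self.tads = sorted(self.tads, key=lambda t: (t.chrom, t.start))
        _check_unique_ids(self.tads, "TAD")
        for prev, cur in zip(self.tads, self.tads[1:]):
            if prev.chrom == cur.chrom and cur.start < prev.end:
                raise ValueError(
                    f"overlapping TADs on {cur.chrom}: {prev.id} "
                    f"[{prev.start},{prev.end}) and {cur.id} "
                    f"[{cur.start},{cur.end}); merge or fix the input"
                )
        self._by_chrom_cache: dict | None = None

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval],
                       source_label: str = "",
                       on_overlap: str = "reject") -> "TADSet":
        """Build a TADSet, optionally auto-merging overlapping input.

        ``on_overlap='merge'`` unions overlapping intervals per chromosome
        (merged TAD ids are joined with ``'+'``); the default rejects.
        """
        ivs = sorted(intervals, key=lambda t: (t.chrom, t.start))
        if on_overlap == "merge":
            merged: list[GenomicInterval] = []
            for iv in ivs:
                if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
                    last = merged.pop()
                    merged.append(GenomicInterval(
                        last.chrom, last.start, max(last.end, iv.end),
                        f"{last.id}+{iv.id}"))
                else:
                    merged.append(iv)
            if len(merged) != len(ivs):
                logger.warning("merged %d overlapping TADs", len(ivs) - len(merged))
            ivs = merged
        elif on_overlap != "reject":
            raise ValueError(f"unknown on_overlap policy {on_overlap!r}")
        return cls(ivs, source_label)

    def __len__(self) -> int:
        return len(self.tads)

    def by_id(self, tad_id: str) -> GenomicInterval:
        for t in self.tads:
            if t.id == tad_id:
                return t
        raise KeyError(tad_id)

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for t in self.tads:
            if not out or out[-1] != t.chrom:
                out.append(t.chrom)
        return out

    def per_chromosome(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for t in self.tads:
            out.setdefault(t.chrom, []).append(t)
        return out

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(starts, ends, ids) for one chromosome, sorted by start."""
        if self._by_chrom_cache is None:
            cache = {}
            for c, tads in self.per_chromosome().items():
                cache[c] = (np.array([t.start for t in tads]),
                            np.array([t.end for t in tads]),
                            [t.id for t in tads])
            self._by_chrom_cache = cache
        if chrom not in self._by_chrom_cache:
            return np.array([], dtype=int), np.array([], dtype=int), []
        return self._by_chrom_cache[chrom]


@dataclass
class SampleGroups:
    """Sample → group-label annotation used for plotting.

    ``colors`` optionally maps group label → matplotlib color.
    """

    groups: dict[str, str] = field(default_factory=dict)
    colors: dict[str, str] | None = None

    def labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen

    def check_samples(self, samples: Iterable[str]) -> list[str]:
        """Return annotated samples missing from ``samples`` (for warnings)."""
        pool = set(samples)
        return [s for s in self.groups if s not in pool]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str],
                     colors: Mapping[str, str] | None = None) -> "SampleGroups":
        return cls(dict(mapping), dict(colors) if colors else None)
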