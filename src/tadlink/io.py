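"""Readers, writers and input consistency checks.

Two text matrices (enhancer signal, gene expression) plus their
coordinates (BED for enhancers, GTF or BED for genes) and a TAD BED are
the tool's inputs. Matrices are tab-separated with a header row of
sample ids and a first column of feature ids.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FeatureMatrix, GenomicInterval, SampleGroups, TADSet

logger = logging.getLogger("tadlink")

#: Column order of the pair result table (the signed offset is an extra
#: strand-aware column: negative = enhancer upstream of the gene TSS).
PAIR_TABLE_COLUMNS = [
    "enhancer_id", "enhancer_chrom", "enhancer_start", "enhancer_end",
    "gene_id", "gene_name", "tad_id", "gene_in_tad", "distance_bp",
    "signed_offset_bp", "correlation", "p_value", "q_value",
    "euclidean_distance",
]


def read_bed_intervals(path: str | Path, id_prefix: str = "") -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (0-based half-open, as on disk).

    The name column (4th) provides feature ids; unnamed records get
    ``{id_prefix}{chrom}:{start}-{end}``. A 6th column, if present, is
    the strand.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out: list[GenomicInterval] = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        name = str(row[3]) if df.shape[1] >= 4 and not pd.isna(row[3]) else \
            f"{id_prefix}{chrom}:{start}-{end}"
        strand = str(row[5]) if df.shape[1] >= 6 and str(row[5]) in "+-" else "."
        out.append(GenomicInterval(chrom, start, end, name, strand))
    ids = [iv.id for iv in out]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"{path}: duplicated feature ids {dups[:10]}")
    return out


def read_gtf_genes(path: str | Path) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Read gene coordinates from a GTF.

    One interval per ``gene_id``, spanning the union of all its records
    (so multi-transcript genes get min(start)..max(end)); strand from the
    first record. GTF's 1-based inclusive coordinates are converted to the
    internal 0-based half-open convention by the parser. Returns the
    intervals (file order of first appearance) and a metadata frame with
    ``gene_name`` and ``gene_biotype`` where present.
    """
    import pyranges as pr

    df = pr.read_gtf(str(path)).df  # pyranges converts to 0-based half-open
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: GTF has no gene_id attribute")
    df = df[df["gene_id"].notna()]
    order = df["gene_id"].drop_duplicates().tolist()
    intervals: list[GenomicInterval] = []
    meta_rows = []
    grouped = df.groupby("gene_id", sort=False)
    for gid in order:
        g = grouped.get_group(gid)
        intervals.append(GenomicInterval(
            str(g["Chromosome"].iloc[0]), int(g["Start"].min()),
            int(g["End"].max()), gid,
            str(g["Strand"].iloc[0]) if "Strand" in g else "."))
        meta_rows.append({
            "gene_name": g["gene_name"].iloc[0] if "gene_name" in g else gid,
            "gene_biotype": g["gene_biotype"].iloc[0] if "gene_biotype" in g else "",
        })
    meta = pd.DataFrame(meta_rows, index=order)
    return intervals, meta


def read_tads(path: str | Path, source_label: str = "",
              on_overlap: str = "reject") -> TADSet:
    """Read a TAD BED into a :class:`TADSet` (default: reject overlaps)."""
    ivs = read_bed_intervals(path, id_prefix="tad|")
    return TADSet.from_intervals(ivs, source_label or str(path), on_overlap)


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    # locate non-numeric cells precisely before failing
    bad_cols = [c for c in df.columns
                if not np.issubdtype(df[c].dtype, np.number)]
    if bad_cols:
        col = bad_cols[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[col].notna()]
        raise ValueError(
            f"{path}: non-numeric value at row {bad_rows[0]!r}, "
            f"column {col!r}: {df.loc[bad_rows[0], col]!r}")
    return df


def load_feature_matrix(table_path: str | Path,
                        coords: str | Path | Sequence[GenomicInterval],
                        kind: str = "signal",
                        feature_meta: pd.DataFrame | None = None,
                        drop_incomplete: bool = False) -> FeatureMatrix:
    """Load a signal or expression matrix and bind it to coordinates.

    Parameters
    ----------
    table_path
        TSV with header of sample ids, first column of feature ids.
    coords
        BED path (``kind='signal'``), GTF or BED path (``kind='expression'``;
        GTF recognized by ``.gtf``/``.gff`` suffix), or a pre-built list of
        intervals.
    drop_incomplete
        Drop features containing any missing value instead of rejecting
        the whole matrix.

    Features are matched 1:1 to coordinate records by id; the order of the
    coordinates file is preserved. Ids present on only one side are a hard
    error listing the offenders.
    """
    if kind not in ("signal", "expression"):
        raise ValueError(f"kind must be 'signal' or 'expression', got {kind!r}")
    meta = feature_meta
    if isinstance(coords, (str, Path)):
        suffix = Path(coords).suffix.lower()
        if kind == "expression" and suffix in (".gtf", ".gff"):
            intervals, meta = read_gtf_genes(coords)
        else:
            intervals = read_bed_intervals(coords)
    else:
        intervals = list(coords)

    table = _read_table(table_path)
    if table.index.duplicated().any():
        dups = sorted(set(table.index[table.index.duplicated()]))
        raise ValueError(f"{table_path}: duplicated feature ids {dups[:10]}")
    if drop_incomplete:
        n0 = table.shape[0]
        keep = table.notna().all(axis=1) & np.isfinite(table).all(axis=1)
        table = table[keep]
        if table.shape[0] < n0:
            logger.warning("dropped %d features with missing values",
                           n0 - table.shape[0])
        intervals = [iv for iv in intervals if iv.id in set(table.index)]
        if meta is not None:
            meta = meta.loc[[iv.id for iv in intervals]]

    coord_ids = [iv.id for iv in intervals]
    table_ids = set(table.index)
    missing_coords = sorted(table_ids - set(coord_ids))
    missing_table = sorted(set(coord_ids) - table_ids)
    if missing_coords or missing_table:
        parts = []
        if missing_coords:
            parts.append(f"in table but not in coordinates: {missing_coords[:10]}")
        if missing_table:
            parts.append(f"in coordinates but not in table: {missing_table[:10]}")
        raise ValueError(f"{table_path}: feature/coordinate mismatch — "
                         + "; ".join(parts))
    values = table.loc[coord_ids].astype(float)
    if meta is not None:
        meta = meta.loc[coord_ids]
    return FeatureMatrix(values, intervals, meta)


def check_cohort_consistency(enh: FeatureMatrix, expr: FeatureMatrix,
                             min_samples: int = 4,
                             ) -> tuple[list[str], FeatureMatrix, FeatureMatrix]:
    """Intersect the sample sets of the two matrices.

    Returns the common samples (in enhancer-matrix order) and both
    matrices subset and column-reordered to them. Dropping samples is
    logged; fewer than ``min_samples`` common samples is a hard error,
    since correlation across a smaller cohort is meaningless.
    """
    expr_set = set(expr.samples)
    common = [s for s in enh.samples if s in expr_set]
    if len(common) < min_samples:
        raise ValueError(
            f"only {len(common)} samples shared between the matrices "
            f"(minimum {min_samples})")
    dropped = (len(enh.samples) - len(common)) + (len(expr.samples) - len(common))
    if dropped:
        logger.warning("dropped %d unmatched samples; %d common samples kept",
                       dropped, len(common))
    return common, enh.subset_samples(common), expr.subset_samples(common)


def write_matrix(fm: FeatureMatrix, table_path: str | Path,
                 bed_path: str | Path | None = None) -> None:
    """Write a FeatureMatrix back to TSV (+ optional BED6 of coordinates)."""
    fm.values.to_csv(table_path, sep="\t", index_label="feature_id")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for iv in fm.features:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t"
                         f"{iv.strand if iv.strand != '.' else '.'}\n")


def sort_pair_table(records: pd.DataFrame) -> pd.DataFrame:
    """Deterministic result order: (q asc, |r| desc, enhancer_id, gene_id)."""
    if records.empty:
        return records
    key = records.assign(_absr=-records["correlation"].abs())
    idx = key.sort_values(["q_value", "_absr", "enhancer_id", "gene_id"],
                          kind="mergesort").index
    return records.loc[idx].reset_index(drop=True)


def write_pair_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write the pair result table as TSV in the documented column order."""
    out = records.reindex(columns=PAIR_TABLE_COLUMNS)
    sort_pair_table(out).to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != PAIR_TABLE_COLUMNS:
        raise ValueError(f"{path}: not a pair table (unexpected columns)")
    return df


def write_eag_list(gene_ids: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gene_ids):
            fh.write(g + "\n")


def load_sample_groups(path: str | Path) -> SampleGroups:
    """Read a 2–3 column TSV: sample id, group label[, color]."""
    # no comment handling: hex colors like #ff0000 are legitimate cells
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least sample and group columns")
    groups = dict(zip(df[0], df[1]))
    colors = None
    if df.shape[1] >= 3 and df[2].notna().any():
        colors = {g: c for g, c in zip(df[1], df[2]) if pd.notna(c)}
    return SampleGroups(groups, colors)
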