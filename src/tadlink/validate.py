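"""Validation procedures for a TAD-constrained correlation analysis.

Three independent checks that the TAD constraint carries signal:

* **Random-TAD permutation** — rerun the whole analysis against many
  randomized TAD sets that conserve TAD count, lengths and gap structure;
  real TADs should yield more enhancer-associated genes (EAGs) than any
  random set at every significance threshold.
* **Sample saturation** — subsample the cohort and measure how much of
  the full-cohort EAG set is recovered as a function of sample count.
* **Closest-gene comparison** — contrast the correlation-based calls
  with the naive "k nearest genes" annotation and quantify how many
  nearest-gene calls are not even co-located in a TAD with their
  enhancer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .assign import TadSetPartition
from .model import FeatureMatrix, GenomicInterval, TADSet
from .stats import CorrelationConfig, extract_eags, prepare_analysis

logger = logging.getLogger("tadlink")

DEFAULT_THRESHOLDS = (1e-4, 1e-3, 0.01, 0.05, 0.1)


# ---------------------------------------------------------------------------
# random TADs

def _derive_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_random_tads(tads: TADSet, seed: int,
                         shuffle_gaps: bool = False) -> TADSet:
    """Randomize TAD order while conserving the genome's territory.

    Per chromosome, the covered span decomposes into the alternating
    sequence gap₀ tad₁ gap₁ tad₂ … ; the TAD lengths (with their ids) are
    permuted uniformly at random while the gap lengths stay fixed in
    place, and coordinates are rebuilt from the original first TAD start.
    Conserved exactly: TAD count, TAD-length multiset, gap-length
    multiset, and per-chromosome covered span. ``shuffle_gaps``
    additionally permutes the gap-length order (the covered span is still
    conserved). A chromosome with a single TAD is returned unchanged.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    new: list[GenomicInterval] = []
    for chrom in tads.chromosomes:
        chrom_tads = tads.per_chromosome()[chrom]
        if len(chrom_tads) == 1:
            new.extend(chrom_tads)
            continue
        lengths = np.array([t.length for t in chrom_tads])
        ids = [t.id for t in chrom_tads]
        gaps = np.array([nxt.start - cur.end
                         for cur, nxt in zip(chrom_tads, chrom_tads[1:])])
        perm = rng.permutation(len(lengths))
        lengths = lengths[perm]
        ids = [ids[i] for i in perm]
        if shuffle_gaps and len(gaps) > 1:
            gaps = gaps[rng.permutation(len(gaps))]
        pos = chrom_tads[0].start
        for i, (L, tid) in enumerate(zip(lengths, ids)):
            new.append(GenomicInterval(chrom, int(pos), int(pos + L), tid))
            pos += L
            if i < len(gaps):
                pos += gaps[i]
    return TADSet(new, source_label=f"{tads.source_label}|randomized")


@dataclass
class PermutationResult:
    """Observed vs random-TAD EAG counts across a threshold sweep."""

    q_thresholds: list[float]
    observed: np.ndarray           # per threshold
    null_counts: np.ndarray        # (replicate, threshold)
    empirical_p: np.ndarray        # per threshold
    normal_p: np.ndarray           # per threshold; NaN when null sd = 0
    seeds: list[int]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "q_threshold": self.q_thresholds,
            "observed_eags": self.observed,
            "null_mean": self.null_counts.mean(axis=0),
            "null_sd": self.null_counts.std(axis=0, ddof=1),
            "empirical_p": self.empirical_p,
            "normal_p": self.normal_p,
        })


def summarize_permutation(observed: np.ndarray, null_counts: np.ndarray,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical and Gaussian-tail p-values from observed vs null counts.

    empirical_p = (1 + #{null ≥ observed}) / (R + 1) — never below
    1/(R+1), so an extreme observation with R replicates reports exactly
    that bound. The Gaussian upper tail on the fitted null (mean, sd) is
    the only way a claim like p < 1e-10 is expressible with a few hundred
    replicates; it is reported *alongside* the empirical p, never instead.
    """
    R = null_counts.shape[0]
    emp = (1 + (null_counts >= observed[None, :]).sum(axis=0)) / (R + 1)
    mean = null_counts.mean(axis=0)
    sd = null_counts.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        normal = np.where(sd > 0, sps.norm.sf((observed - mean) / np.where(sd > 0, sd, 1.0)),
                          np.nan)
    if (sd == 0).any():
        logger.warning("null sd = 0 at %d thresholds; normal_p undefined there",
                       int((sd == 0).sum()))
    return emp, normal


def permutation_test(enh: FeatureMatrix, expr: FeatureMatrix, tads: TADSet,
                     config: CorrelationConfig = CorrelationConfig(),
                     q_thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                     n_replicates: int = 100, base_seed: int = 0,
                     shuffle_gaps: bool = False) -> PermutationResult:
    """Compare EAG counts under real vs randomized TADs.

    Replicate i (1..R) randomizes the TADs with a seed derived from
    (base_seed, i) and reruns the TAD-dependent analysis stages; EAGs are
    counted at each threshold in the sweep.
    """
    thresholds = sorted(q_thresholds)
    prep = prepare_analysis(enh, expr, config)

    def eag_counts(records: pd.DataFrame) -> np.ndarray:
        return np.array([len(extract_eags(records, t, config.require_positive))
                         for t in thresholds])

    observed = eag_counts(prep.analyze(tads))
    seeds = [_derive_seed(base_seed, i) for i in range(1, n_replicates + 1)]
    null = np.zeros((n_replicates, len(thresholds)), dtype=int)
    for i, seed in enumerate(seeds):
        rt = generate_random_tads(tads, seed, shuffle_gaps)
        null[i] = eag_counts(prep.analyze(rt))
    emp, normal = summarize_permutation(observed, null)
    return PermutationResult(list(thresholds), observed, null, emp, normal,
                             seeds)


# ---------------------------------------------------------------------------
# saturation

@dataclass
class SaturationResult:
    """EAG recovery as a function of cohort size."""

    table: pd.DataFrame      # columns: n, repetition, recovery, count_ratio
    full_eag_count: int

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby("n")
        return pd.DataFrame({
            "mean_recovery": g["recovery"].mean(),
            "sd_recovery": g["recovery"].std(ddof=1),
            "mean_count_ratio": g["count_ratio"].mean(),
            "sd_count_ratio": g["count_ratio"].std(ddof=1),
        }).reset_index()


def saturation_analysis(enh: FeatureMatrix, expr: FeatureMatrix, tads: TADSet,
                        config: CorrelationConfig = CorrelationConfig(),
                        n_range: Sequence[int] = (),
                        repetitions: int = 10, base_seed: int = 0,
                        p_threshold: float | None = None) -> SaturationResult:
    """Subsample the cohort and measure EAG recovery per subsample size.

    For each n in ``n_range`` and each repetition, n samples are drawn
    without replacement (seeded), the TAD-dependent analysis is rerun on
    the subset, and two fractions are reported against the full-cohort
    EAG set: ``recovery`` = |EAG_subset ∩ EAG_full| / |EAG_full| and
    ``count_ratio`` = |EAG_subset| / |EAG_full|. ``p_threshold`` switches
    the EAG definition from q ≤ config.q_threshold to raw p ≤ threshold
    (the usual choice for saturation, where subsampled power is low).
    """
    prep = prepare_analysis(enh, expr, config)
    n_total = prep.enh.shape[1]
    if not n_range:
        n_range = range(max(config.min_samples, n_total - 14), n_total + 1)

    def eags(records: pd.DataFrame) -> set[str]:
        if p_threshold is not None:
            mask = records["p_value"] <= p_threshold
            if config.require_positive:
                mask &= records["correlation"] > 0
            return set(records.loc[mask, "gene_id"])
        return extract_eags(records, config.q_threshold,
                            config.require_positive)

    full = eags(prep.analyze(tads))
    if not full:
        raise ValueError("no EAGs in the full cohort; saturation undefined")
    rows = []
    for n in n_range:
        if n < config.min_samples:
            logger.warning("skipping n=%d (< %d samples)", n,
                           config.min_samples)
            continue
        if n > n_total:
            raise ValueError(f"n={n} exceeds cohort size {n_total}")
        for rep in range(repetitions):
            rng = np.random.default_rng(_derive_seed(base_seed, n, rep))
            idx = np.sort(rng.choice(n_total, size=n, replace=False))
            sub = eags(prep.analyze(tads, sample_idx=idx))
            rows.append((n, rep, len(sub & full) / len(full),
                         len(sub) / len(full)))
    table = pd.DataFrame(rows, columns=["n", "repetition", "recovery",
                                        "count_ratio"])
    return SaturationResult(table, len(full))


# ---------------------------------------------------------------------------
# closest-gene comparison

def closest_genes(enhancer: GenomicInterval,
                  genes: Sequence[GenomicInterval], k: int) -> list[str]:
    """The k nearest genes on each side of the enhancer midpoint.

    Distance is |gene TSS − enhancer midpoint| on the same chromosome;
    up to k genes with TSS left of the midpoint plus up to k with TSS at
    or right of it (fewer near chromosome ends). Returned sorted by
    (distance, gene id); ties break on gene id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mid = enhancer.midpoint
    left = []
    right = []
    for g in genes:
        if g.chrom != enhancer.chrom:
            continue
        d = g.tss - mid
        (left if d < 0 else right).append((abs(d), g.id))
    left.sort()
    right.sort()
    chosen = left[:k] + right[:k]
    chosen.sort()
    return [gid for _, gid in chosen]


def compare_closest_vs_correlation(records: pd.DataFrame,
                                   enhancers: Sequence[GenomicInterval],
                                   genes: Sequence[GenomicInterval],
                                   k_range: Sequence[int] = range(2, 11),
                                   q_threshold: float = 0.01,
                                   require_positive: bool = True,
                                   ) -> pd.DataFrame:
    """Mutual agreement of correlation-based and closest-gene annotation.

    Per k: the fraction of correlation EAGs found among the k-closest
    gene sets, the converse fraction, and — the false-positive
    diagnostic — the fraction of closest-only genes that are not
    co-located in any TAD with the enhancer that nominated them (the
    candidate-pair table in ``records`` is the co-location oracle).
    """
    eag_corr = extract_eags(records, q_threshold, require_positive)
    candidate_pairs = set(zip(records["enhancer_id"], records["gene_id"]))
    rows = []
    for k in k_range:
        closest_links: set[tuple[str, str]] = set()
        for e in enhancers:
            for gid in closest_genes(e, genes, k):
                closest_links.add((e.id, gid))
        eag_closest = {g for _, g in closest_links}
        corr_in_closest = (len(eag_corr & eag_closest) / len(eag_corr)
                           if eag_corr else np.nan)
        closest_in_corr = (len(eag_closest & eag_corr) / len(eag_closest)
                           if eag_closest else np.nan)
        only = eag_closest - eag_corr
        if only:
            colocated = {g for e, g in closest_links
                         if g in only and (e, g) in candidate_pairs}
            frac_outside = 1.0 - len(colocated) / len(only)
        else:
            frac_outside = np.nan
        rows.append((k, len(eag_corr), len(eag_closest), corr_in_closest,
                     closest_in_corr, frac_outside))
    return pd.DataFrame(rows, columns=[
        "k", "n_eag_correlation", "n_eag_closest", "corr_in_closest",
        "closest_in_corr", "closest_only_no_shared_tad"])


# ---------------------------------------------------------------------------
# TAD-class stratification

def stratify_correlations_by_tad_class(records_a: pd.DataFrame,
                                       records_b: pd.DataFrame,
                                       partition: TadSetPartition,
                                       ) -> pd.DataFrame:
    """Correlation summaries per TAD class (common / specific to A or B).

    ``records_a``/``records_b`` are analyses against the two TAD sets of
    ``partition``. Pairs in TADs common to both annotations are taken
    from the A analysis (each pair counted once); set-specific classes
    come from their own analysis. Empty classes report n = 0.
    """
    classes = {
        "common": records_a[records_a["tad_id"].isin(set(partition.common_a))],
        "specific_a": records_a[records_a["tad_id"].isin(set(partition.specific_a))],
        "specific_b": records_b[records_b["tad_id"].isin(set(partition.specific_b))],
    }
    rows = []
    for name, rec in classes.items():
        r = rec["correlation"]
        if len(r):
            rows.append((name, len(r), r.median(), r.quantile(0.25),
                         r.quantile(0.75)))
        else:
            rows.append((name, 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["tad_class", "n", "median_r", "q1_r",
                                       "q3_r"])
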