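"""Synthetic cohorts with planted enhancer→gene links.

Emulates the statistical structure the analysis assumes: a heterogeneous
sample cohort (e.g. tumor subgroups) profiled for enhancer signal and
gene expression, where a known subset of enhancer–gene pairs co-located
in a TAD shares a latent activation — partly subgroup driven, giving the
bimodal two-cluster scatter seen for subgroup-specific enhancers — while
everything else is independent noise. The planted links are the ground
truth against which sensitivity and false discovery are measured.

Signal model (per planted pair, on the log2 scale):

    u_s  = √w·ĝ_s + √(1−w)·η_s              shared latent, unit variance
    x_s  = μ_e + σ·(√ρ·u_s + √(1−ρ)·ε_s)    enhancer
    y_s  = μ_g + σ·(√ρ·u_s + √(1−ρ)·ε'_s)   gene

where ĝ is the standardized subgroup indicator of the pair's active
group and w the subgroup share of the latent variance; corr(x, y) = ρ by
construction. Values are mapped to a non-negative RPKM-like scale via
v = 2^x − 1 (clipped at 0), the exact inverse of the analysis transform
log2(v + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FeatureMatrix, GenomicInterval, SampleGroups, TADSet


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the simulated cohort (all lengths in bp, log2 scale
    for means/sds of signal).

    Defaults model a 24-sample tumor cohort over ~100 TADs of realistic
    human scale (mean ≈ 0.8 Mb) with a handful of genes and enhancers per
    TAD, 30% of genes carrying one planted enhancer link of strength
    ρ = 0.9, and a two-subgroup structure contributing 30% of the shared
    latent variance.
    """

    n_samples: int = 24
    n_tads: int = 100
    n_chromosomes: int = 4
    tad_length_mean: float = 800_000
    tad_length_sd: float = 250_000
    tad_length_min: float = 150_000
    gap_mean: float = 120_000
    gap_sd: float = 60_000
    gap_min: float = 10_000
    genes_per_tad_mean: float = 3.0
    enhancers_per_tad_mean: float = 4.0
    linked_gene_fraction: float = 0.3
    rho: float = 0.9
    distal_fraction: float = 0.25
    outside_gene_fraction: float = 0.05
    group_effect: float = 0.3
    n_groups: int = 2
    noise_sd: float = 1.0
    gene_mean_loc: float = 5.0
    gene_mean_sd: float = 1.5
    enh_mean_loc: float = 3.0
    enh_mean_sd: float = 1.0
    low_expression_fraction: float = 0.1
    gene_length: int = 2_000
    enhancer_length: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("linked_gene_fraction", "distal_fraction",
                     "outside_gene_fraction", "group_effect",
                     "low_expression_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.tad_length_min < self.gene_length + self.enhancer_length + 4000:
            raise ValueError("TADs too short to hold genes and enhancers")
        if self.n_tads < self.n_chromosomes:
            raise ValueError("need at least one TAD per chromosome")

    def with_(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground-truth planted links and the generated subgroup labels.

    ``links`` columns: enhancer_id, gene_id, rho, is_distal (the
    enhancer's globally nearest gene is not its partner, verified
    geometrically after layout), gene_outside_tad.
    """

    links: pd.DataFrame
    groups: SampleGroups

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.links["enhancer_id"], self.links["gene_id"]))


@dataclass
class RecoveryResult:
    sensitivity: float
    fdr: float | None          # None when nothing was called
    n_called: int
    n_planted: int
    by_distal: pd.DataFrame    # sensitivity split by is_distal


def _layout(spec: SyntheticSpec, rng: np.random.Generator):
    """Place TADs, genes and enhancers; returns (tads, genes, enhancers,
    gene_outside flags)."""
    per_chrom = np.full(spec.n_chromosomes, spec.n_tads // spec.n_chromosomes)
    per_chrom[: spec.n_tads % spec.n_chromosomes] += 1
    tads: list[GenomicInterval] = []
    genes: list[GenomicInterval] = []
    enhancers: list[GenomicInterval] = []
    gene_outside: dict[str, bool] = {}
    gene_home: dict[str, str] = {}
    k_gene = k_enh = 0
    for c, n_t in enumerate(per_chrom):
        chrom = f"chrS{c + 1}"
        pos = int(max(spec.gap_min,
                      rng.normal(spec.gap_mean, spec.gap_sd)))
        chrom_tads = []
        for i in range(int(n_t)):
            L = int(max(spec.tad_length_min,
                        rng.normal(spec.tad_length_mean, spec.tad_length_sd)))
            tad = GenomicInterval(chrom, pos, pos + L, f"tad_{chrom}_{i}")
            chrom_tads.append(tad)
            pos = tad.end + int(max(spec.gap_min,
                                    rng.normal(spec.gap_mean, spec.gap_sd)))
        tads.extend(chrom_tads)
        for ti, tad in enumerate(chrom_tads):
            margin = 1_000
            lo = tad.start + margin
            hi = tad.end - margin - max(spec.gene_length, spec.enhancer_length)
            n_g = rng.poisson(spec.genes_per_tad_mean)
            for _ in range(n_g):
                gid = f"gene_{k_gene}"
                k_gene += 1
                outside = rng.random() < spec.outside_gene_fraction
                gap_end = (chrom_tads[ti + 1].start if ti + 1 < len(chrom_tads)
                           else tad.end + int(spec.gap_mean))
                gap_len = gap_end - tad.end
                hi_out = tad.end + int(0.4 * gap_len) - spec.gene_length
                if outside and gap_len > 4 * spec.gene_length \
                        and hi_out > tad.end + 1:
                    # whole gene within the first 40% of the following gap,
                    # so its nearest TAD is guaranteed to be this one
                    s = int(rng.integers(tad.end + 1, hi_out))
                else:
                    outside = False
                    s = int(rng.integers(lo, hi))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GenomicInterval(chrom, s, s + spec.gene_length,
                                             gid, strand))
                gene_outside[gid] = outside
                gene_home[gid] = tad.id
            n_e = rng.poisson(spec.enhancers_per_tad_mean)
            for _ in range(n_e):
                s = int(rng.integers(lo, hi))
                enhancers.append(GenomicInterval(
                    chrom, s, s + spec.enhancer_length, f"enh_{k_enh}"))
                k_enh += 1
    return tads, genes, enhancers, gene_outside, gene_home


def _nearest_gene(enh: GenomicInterval,
                  genes_by_chrom: dict[str, list[GenomicInterval]]) -> str | None:
    best, best_d = None, None
    for g in genes_by_chrom.get(enh.chrom, ()):
        d = abs(g.tss - enh.midpoint)
        if best_d is None or (d, g.id) < (best_d, best):
            best, best_d = g.id, d
    return best


def generate_cohort(spec: SyntheticSpec
                    ) -> tuple[FeatureMatrix, FeatureMatrix, TADSet,
                               SampleGroups, SyntheticTruth]:
    """Generate (enhancer matrix, expression matrix, TADs, groups, truth).

    Fully reproducible from ``spec.seed``: the same spec yields
    bit-identical matrices. Raises before generation when the spec is
    geometrically infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    tads_list, genes, enhancers, gene_outside, gene_home = _layout(spec, rng)
    tadset = TADSet(tads_list, source_label="synthetic")
    if not genes or not enhancers:
        raise ValueError("spec produced no genes or no enhancers; increase "
                         "densities")

    samples = [f"s{i + 1}" for i in range(spec.n_samples)]
    labels = [f"G{(i % spec.n_groups) + 1}" for i in range(spec.n_samples)]
    groups = SampleGroups(dict(zip(samples, labels)))

    genes_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    enh_by_tad: dict[str, list[GenomicInterval]] = {}
    for e in enhancers:
        starts, ends, ids = tadset.arrays(e.chrom)
        i = int(np.searchsorted(starts, e.midpoint, side="right")) - 1
        enh_by_tad.setdefault(ids[i], []).append(e)
    nearest = {e.id: _nearest_gene(e, genes_by_chrom) for e in enhancers}

    # plant links: one enhancer per linked gene, enhancers never reused
    link_rows = []
    used: set[str] = set()
    linked_mask = rng.random(len(genes)) < spec.linked_gene_fraction
    for g, is_linked in zip(genes, linked_mask):
        if not is_linked:
            continue
        pool = [e for e in enh_by_tad.get(gene_home[g.id], ())
                if e.id not in used]
        if not pool:
            continue
        want_distal = rng.random() < spec.distal_fraction
        matching = [e for e in pool
                    if (nearest[e.id] != g.id) == want_distal]
        cand = matching if matching else pool
        e = cand[int(rng.integers(len(cand)))]
        used.add(e.id)
        link_rows.append((e.id, g.id, spec.rho, nearest[e.id] != g.id,
                          gene_outside[g.id]))
    links = pd.DataFrame(link_rows, columns=[
        "enhancer_id", "gene_id", "rho", "is_distal", "gene_outside_tad"])

    # signal generation on the log2 scale
    n = spec.n_samples
    glab = np.asarray(labels)
    gene_log = np.empty((len(genes), n))
    enh_log = np.empty((len(enhancers), n))
    gene_idx = {g.id: i for i, g in enumerate(genes)}
    enh_idx = {e.id: i for i, e in enumerate(enhancers)}

    low = rng.random(len(genes)) < spec.low_expression_fraction
    mu_g = np.where(low, rng.normal(0.8, 0.3, len(genes)),
                    np.clip(rng.normal(spec.gene_mean_loc, spec.gene_mean_sd,
                                       len(genes)), 0.5, None))
    mu_e = np.clip(rng.normal(spec.enh_mean_loc, spec.enh_mean_sd,
                              len(enhancers)), 0.5, None)
    for i in range(len(genes)):
        gene_log[i] = mu_g[i] + spec.noise_sd * rng.normal(size=n)
    for i in range(len(enhancers)):
        enh_log[i] = mu_e[i] + spec.noise_sd * rng.normal(size=n)

    group_names = sorted(set(labels))
    w, rho = spec.group_effect, spec.rho
    for row in links.itertuples(index=False):
        active = group_names[int(rng.integers(len(group_names)))]
        ind = (glab == active).astype(float)
        if ind.std() > 0:
            ghat = (ind - ind.mean()) / ind.std()
        else:  # single group: no subgroup component
            ghat = np.zeros(n)
        u = np.sqrt(w) * ghat + np.sqrt(1 - w) * rng.normal(size=n)
        gi, ei = gene_idx[row.gene_id], enh_idx[row.enhancer_id]
        gene_log[gi] = mu_g[gi] + spec.noise_sd * (
            np.sqrt(rho) * u + np.sqrt(1 - rho) * rng.normal(size=n))
        enh_log[ei] = mu_e[ei] + spec.noise_sd * (
            np.sqrt(rho) * u + np.sqrt(1 - rho) * rng.normal(size=n))

    def to_rpkm(log_vals: np.ndarray) -> np.ndarray:
        return np.clip(np.exp2(log_vals) - 1.0, 0.0, None)

    expr = FeatureMatrix(
        pd.DataFrame(to_rpkm(gene_log), index=[g.id for g in genes],
                     columns=samples),
        genes,
        pd.DataFrame({"gene_name": [g.id.upper() for g in genes],
                      "gene_biotype": "protein_coding"},
                     index=[g.id for g in genes]))
    enh = FeatureMatrix(
        pd.DataFrame(to_rpkm(enh_log), index=[e.id for e in enhancers],
                     columns=samples),
        enhancers)
    return enh, expr, tadset, groups, SyntheticTruth(links, groups)


def evaluate_recovery(records: pd.DataFrame, truth: SyntheticTruth,
                      q_threshold: float = 0.01,
                      require_positive: bool = True) -> RecoveryResult:
    """Sensitivity and observed FDR of the analysis against the truth.

    A planted link is recovered when its (enhancer, gene) pair is called
    at q ≤ threshold (and r > 0 when required); any called pair that was
    not planted counts as a false discovery. Sensitivity is also split
    by whether the planted enhancer is distal (not the gene's nearest).
    """
    mask = records["q_value"] <= q_threshold
    if require_positive:
        mask &= records["correlation"] > 0
    called = set(zip(records.loc[mask, "enhancer_id"],
                     records.loc[mask, "gene_id"]))
    planted = truth.pairs
    n_called = len(called)
    tp = len(called & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdr = (n_called - tp) / n_called if n_called else None
    rows = []
    for flag, sub in truth.links.groupby("is_distal"):
        pairs = set(zip(sub["enhancer_id"], sub["gene_id"]))
        rows.append((bool(flag), len(pairs),
                     len(pairs & called) / len(pairs) if pairs else np.nan))
    by_distal = pd.DataFrame(rows, columns=["is_distal", "n_planted",
                                            "sensitivity"])
    return RecoveryResult(sensitivity, fdr, n_called, len(planted), by_distal)


def write_cohort(out_dir, enh: FeatureMatrix, expr: FeatureMatrix,
                 tads: TADSet, groups: SampleGroups,
                 truth: SyntheticTruth) -> dict[str, str]:
    """Write the generated cohort as the tool's plain-text input files."""
    from pathlib import Path

    from .io import write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "enh_table": out / "enhancer_signal.tsv",
        "enh_bed": out / "enhancers.bed",
        "expr_table": out / "expression.tsv",
        "gene_bed": out / "genes.bed",
        "tad_bed": out / "tads.bed",
        "groups": out / "sample_groups.tsv",
        "truth": out / "truth_links.tsv",
    }
    write_matrix(enh, paths["enh_table"], paths["enh_bed"])
    write_matrix(expr, paths["expr_table"], paths["gene_bed"])
    with open(paths["tad_bed"], "w") as fh:
        for t in tads.tads:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.id}\n")
    with open(paths["groups"], "w") as fh:
        for s, g in groups.groups.items():
            fh.write(f"{s}\t{g}\n")
    truth.links.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
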