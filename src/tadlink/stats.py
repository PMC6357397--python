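"""The statistical core: gene filtering, correlation, FDR, full analysis.

Every within-TAD enhancer–gene pair is tested for correlation between
enhancer signal and gene expression across the cohort (Pearson, Spearman
or Kendall). P-values are adjusted once, jointly over all pairs, with
Storey q-values (or plain Benjamini–Hochberg). The Euclidean distance on
the transformed scale is reported alongside r because correlation is
scale invariant: a pair can correlate perfectly while living on wildly
different magnitudes, and the distance flags exactly those cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .assign import assign_features, enumerate_pairs
from .io import PAIR_TABLE_COLUMNS, check_cohort_consistency
from .model import FeatureMatrix, TADSet

logger = logging.getLogger("tadlink")

METHODS = ("pearson", "spearman", "kendall")
Q_METHODS = ("storey", "bh")

#: λ grid for Storey's π0 smoother.
_LAMBDAS = np.arange(0.05, 0.96, 0.05)


@dataclass(frozen=True)
class CorrelationConfig:
    """Tunable knobs of the analysis workflow.

    ``log_transform`` applies log2(x+1) to both matrices before
    correlation and distance; RPKM-like inputs are heavy-tailed and the
    log stabilizes them. ``require_positive`` restricts enhancer calls to
    co-activation (r > 0), the expected direction for activating
    elements.
    """

    method: str = "pearson"
    q_method: str = "storey"
    q_threshold: float = 0.01
    require_positive: bool = True
    log_transform: bool = True
    gene_filter: str = "none"                 # none | mixture | biotype
    biotypes: frozenset = frozenset({"protein_coding"})
    gene_anchor: str = "tss"                  # tss | midpoint | body
    enh_anchor: str = "midpoint"
    rescue_genes: bool = True
    rescue_enhancers: bool = False
    min_samples: int = 4

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.q_method not in Q_METHODS:
            raise ValueError(f"q_method must be one of {Q_METHODS}")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0, 1)")

    def with_(self, **kw) -> "CorrelationConfig":
        return replace(self, **kw)


def transform(values: np.ndarray | pd.DataFrame, log_transform: bool = True):
    """The analysis scale: log2(x+1) when enabled, identity otherwise."""
    return np.log2(np.asarray(values, dtype=float) + 1.0) if log_transform \
        else np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# gene filtering

def filter_genes(expr: FeatureMatrix,
                 mode: str | Sequence[str] = "mixture",
                 biotypes: Iterable[str] = ("protein_coding",),
                 log_transform: bool = True,
                 random_state: int = 0) -> FeatureMatrix:
    """Drop genes unlikely to be informative, before pairing.

    ``mixture`` fits a two-component Gaussian mixture to the per-gene
    mean log2(x+1) expression and keeps genes assigned (posterior > 0.5)
    to the higher-mean component — a data-driven expressed/silent split.
    ``biotype`` keeps genes whose annotated biotype is in ``biotypes``.
    Modes compose when given as a sequence; ``none`` is the identity.
    Returns a new matrix, never mutates.
    """
    modes = [mode] if isinstance(mode, str) else list(mode)
    out = expr
    for m in modes:
        if m == "none":
            continue
        elif m == "biotype":
            if out.feature_meta is None or "gene_biotype" not in out.feature_meta:
                raise ValueError("biotype filtering requires gene_biotype metadata")
            wanted = set(biotypes)
            keep = [f.id for f in out.features
                    if out.feature_meta.loc[f.id, "gene_biotype"] in wanted]
            out = out.subset_features(keep)
        elif m == "mixture":
            out = _mixture_filter(out, log_transform, random_state)
        else:
            raise ValueError(f"unknown gene filter mode {m!r}")
    if out is not expr:
        logger.info("gene filter %s: %d of %d genes kept", modes,
                    out.shape[0], expr.shape[0])
    return out


def _mixture_filter(expr: FeatureMatrix, log_transform: bool,
                    random_state: int) -> FeatureMatrix:
    from sklearn.mixture import GaussianMixture

    means = transform(expr.values.to_numpy(), log_transform).mean(axis=1)
    if np.allclose(means, means[0]):
        logger.warning("mixture filter: degenerate expression means; "
                       "keeping all genes")
        return expr
    gm = GaussianMixture(n_components=2, n_init=3, random_state=random_state)
    gm.fit(means.reshape(-1, 1))
    hi = int(np.argmax(gm.means_.ravel()))
    post = gm.predict_proba(means.reshape(-1, 1))[:, hi]
    keep = [f.id for f, p in zip(expr.features, post) if p > 0.5]
    if not keep:
        logger.warning("mixture filter kept no genes; returning input unchanged")
        return expr
    return expr.subset_features(keep)


# ---------------------------------------------------------------------------
# correlation

def _rank_rows(a: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, a)


def _pearson_rows(x: np.ndarray, y: np.ndarray):
    """Row-wise Pearson r and two-sided t-test p for paired rows."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum(axis=1))
    degenerate = (sx == 0) | (sy == 0)
    denom = np.where(degenerate, 1.0, sx * sy)
    r = np.clip((xc * yc).sum(axis=1) / denom, -1.0, 1.0)
    r[degenerate] = 0.0
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), n - 2))
    p[degenerate] = 1.0
    return r, p, degenerate


def correlate_many(x: np.ndarray, y: np.ndarray, method: str = "pearson"):
    """Correlate paired rows of ``x`` and ``y``.

    Returns ``(r, p, degenerate)`` arrays; a row with zero variance in
    either vector is flagged degenerate and reported as r = 0, p = 1 so a
    single dead feature cannot abort a genome-scale run.

    Pearson: product-moment r with the two-sided t test (df = n−2).
    Spearman: Pearson on average-tie ranks, same t approximation.
    Kendall: τ-b via :func:`scipy.stats.kendalltau` (exact null
    distribution for small tie-free samples, tie-corrected normal
    approximation otherwise).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    n = x.shape[1]
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    if method == "pearson":
        return _pearson_rows(x, y)
    if method == "spearman":
        return _pearson_rows(_rank_rows(x), _rank_rows(y))
    if method == "kendall":
        r = np.zeros(x.shape[0])
        p = np.ones(x.shape[0])
        degenerate = np.zeros(x.shape[0], dtype=bool)
        for i in range(x.shape[0]):
            if np.ptp(x[i]) == 0 or np.ptp(y[i]) == 0:
                degenerate[i] = True
                continue
            res = sps.kendalltau(x[i], y[i])
            r[i], p[i] = res.statistic, res.pvalue
        return r, p, degenerate
    raise ValueError(f"method must be one of {METHODS}, got {method!r}")


def correlate_pair(x, y, method: str = "pearson") -> tuple[float, float]:
    """(r, p) for one sample-vector pair; see :func:`correlate_many`."""
    r, p, degenerate = correlate_many(np.asarray(x)[None, :],
                                      np.asarray(y)[None, :], method)
    if degenerate[0]:
        logger.warning("zero-variance vector: correlation undefined, "
                       "reporting r=0, p=1")
    return float(r[0]), float(p[0])


def euclidean_distance(x, y) -> float:
    """Plain (non-standardized) Euclidean distance between two vectors.

    Deliberately scale sensitive: applied on the same transformed scale
    as the correlation, it separates genuinely co-varying pairs from
    pairs that only correlate because correlation ignores magnitude.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.linalg.norm(x - y))


# ---------------------------------------------------------------------------
# FDR

def estimate_pi0(p_values: np.ndarray, lambdas: np.ndarray = _LAMBDAS) -> float:
    """Storey's smoother estimate of π0, the proportion of true nulls.

    π̂0(λ) = #{p > λ} / (m(1−λ)) on the λ grid, smoothed with a cubic
    polynomial and evaluated at max λ, clamped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lam, 3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    if pi0 > 1.0:
        pi0 = 1.0
    if pi0 <= 0.0:
        logger.warning("π0 smoother gave %.3g; clamping to smallest positive "
                       "grid estimate", pi0)
        positive = pi0_lam[pi0_lam > 0]
        pi0 = float(positive.min()) if positive.size else 1.0 / m
        pi0 = min(pi0, 1.0)
    return pi0


def compute_qvalues(p_values, method: str = "storey",
                    pi0: float | None = None) -> np.ndarray:
    """FDR q-values for a set of p-values, in input order.

    ``storey`` scales the Benjamini–Hochberg step-up by the estimated
    null proportion π0 (q_i = π0 · min over p_(j)≥p_(i) of m·p_(j)/j);
    ``bh`` is the identical computation with π0 fixed at 1, so the two
    agree exactly whenever π0 estimates to 1. Fewer than 100 p-values
    make the π0 smoother unstable, so ``storey`` then falls back to
    ``bh`` with a warning. ``pi0`` overrides the estimate when given.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if method not in Q_METHODS:
        raise ValueError(f"q method must be one of {Q_METHODS}")
    if method == "storey" and pi0 is None and p.size < 100:
        logger.warning("only %d p-values: π0 estimation unstable, using BH",
                       p.size)
        method = "bh"
    if pi0 is None:
        pi0 = estimate_pi0(p) if method == "storey" else 1.0
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, pi0 * np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# full workflow

def _correlate_candidates(pairs: pd.DataFrame, enh_t: np.ndarray,
                          expr_t: np.ndarray, enh_index: dict,
                          gene_index: dict, config: CorrelationConfig,
                          ) -> pd.DataFrame:
    ei = pairs["enhancer_id"].map(enh_index).to_numpy()
    gi = pairs["gene_id"].map(gene_index).to_numpy()
    x = enh_t[ei]
    y = expr_t[gi]
    r, p, degenerate = correlate_many(x, y, config.method)
    if degenerate.any():
        logger.warning("%d pairs with zero-variance vectors reported as "
                       "r=0, p=1", int(degenerate.sum()))
    q = compute_qvalues(p, config.q_method)
    dist = np.linalg.norm(x - y, axis=1)
    out = pairs.copy()
    out["correlation"] = r
    out["p_value"] = p
    out["q_value"] = q
    out["euclidean_distance"] = dist
    out["degenerate"] = degenerate
    return out


def run_full_analysis(enh: FeatureMatrix, expr: FeatureMatrix, tads: TADSet,
                      config: CorrelationConfig = CorrelationConfig(),
                      ) -> pd.DataFrame:
    """The complete workflow: one row per within-TAD enhancer–gene pair.

    Stages: sample-consistency check → gene filtering → TAD assignment
    (genes rescued to the nearest TAD by default, enhancers not) → pair
    enumeration → correlation + Euclidean distance per pair → one joint
    q-value computation across *all* pairs. The returned table is the
    full result; significance is a downstream filter, never a truncation.
    """
    _, enh, expr = check_cohort_consistency(enh, expr, config.min_samples)
    expr = filter_genes(expr, config.gene_filter, config.biotypes,
                        config.log_transform)
    prepared = _Prepared(enh, expr, config)
    return prepared.analyze(tads)


@dataclass
class _Prepared:
    """Matrices readied for repeated analysis against different TAD sets.

    The permutation and saturation procedures rerun the TAD-dependent
    stages many times; the consistency check, gene filter and log
    transform are TAD independent and done once here.
    """

    enh: FeatureMatrix
    expr: FeatureMatrix
    config: CorrelationConfig
    enh_t: np.ndarray = field(init=False)
    expr_t: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.enh_t = transform(self.enh.values.to_numpy(),
                               self.config.log_transform)
        self.expr_t = transform(self.expr.values.to_numpy(),
                                self.config.log_transform)
        self._enh_index = {f: i for i, f in enumerate(self.enh.feature_ids)}
        self._gene_index = {f: i for i, f in enumerate(self.expr.feature_ids)}

    def candidates(self, tads: TADSet,
                   rescue_genes: bool | None = None,
                   rescue_enhancers: bool | None = None) -> pd.DataFrame:
        cfg = self.config
        ea = assign_features(self.enh.features, tads, cfg.enh_anchor,
                             cfg.rescue_enhancers if rescue_enhancers is None
                             else rescue_enhancers)
        ga = assign_features(self.expr.features, tads, cfg.gene_anchor,
                             cfg.rescue_genes if rescue_genes is None
                             else rescue_genes)
        pairs = enumerate_pairs(ea, ga, self.enh.features, self.expr.features)
        return pairs

    def analyze(self, tads: TADSet, sample_idx: np.ndarray | None = None,
                ) -> pd.DataFrame:
        pairs = self.candidates(tads)
        if pairs.empty:
            return pd.DataFrame(columns=PAIR_TABLE_COLUMNS + ["degenerate"])
        enh_t = self.enh_t if sample_idx is None else self.enh_t[:, sample_idx]
        expr_t = self.expr_t if sample_idx is None else self.expr_t[:, sample_idx]
        rec = _correlate_candidates(pairs, enh_t, expr_t, self._enh_index,
                                    self._gene_index, self.config)
        return self._decorate(rec)

    def _decorate(self, rec: pd.DataFrame) -> pd.DataFrame:
        enh_by = {f.id: f for f in self.enh.features}
        meta = self.expr.feature_meta
        rec["enhancer_chrom"] = [enh_by[e].chrom for e in rec["enhancer_id"]]
        rec["enhancer_start"] = [enh_by[e].start for e in rec["enhancer_id"]]
        rec["enhancer_end"] = [enh_by[e].end for e in rec["enhancer_id"]]
        if meta is not None and "gene_name" in meta.columns:
            rec["gene_name"] = meta.loc[rec["gene_id"], "gene_name"].to_numpy()
        else:
            rec["gene_name"] = rec["gene_id"]
        return rec[PAIR_TABLE_COLUMNS + ["enh_in_tad", "degenerate"]]


def prepare_analysis(enh: FeatureMatrix, expr: FeatureMatrix,
                     config: CorrelationConfig = CorrelationConfig(),
                     ) -> _Prepared:
    """Run the TAD-independent stages once; reuse across TAD sets."""
    _, enh, expr = check_cohort_consistency(enh, expr, config.min_samples)
    expr = filter_genes(expr, config.gene_filter, config.biotypes,
                        config.log_transform)
    return _Prepared(enh, expr, config)


def extract_eags(records: pd.DataFrame, q_threshold: float = 0.01,
                 require_positive: bool = True) -> set[str]:
    """Enhancer-associated genes: genes with ≥1 pair at q ≤ threshold.

    Gene-level set semantics: a gene with many significant enhancers
    counts once. ``require_positive`` keeps only co-activations (r > 0).
    """
    if records.empty:
        return set()
    mask = records["q_value"] <= q_threshold
    if require_positive:
        mask &= records["correlation"] > 0
    return set(records.loc[mask, "gene_id"])


def significant_pairs(records: pd.DataFrame, q_threshold: float = 0.01,
                      require_positive: bool = True) -> pd.DataFrame:
    mask = records["q_value"] <= q_threshold
    if require_positive:
        mask &= records["correlation"] > 0
    return records.loc[mask]
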