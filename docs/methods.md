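# Methods

## The analysis model

`tadlink` treats enhancer–gene linking as a constrained multiple-testing
problem. Given an enhancer signal matrix E (features × samples), an
expression matrix G, and a set of non-overlapping TADs per chromosome,
the tested hypotheses are exactly the pairs (e, g) whose members map to
the same TAD. For each pair the correlation between the two sample
vectors is computed on a common transformed scale, and all p-values are
adjusted jointly, once, over the full pair list. Significance is a
downstream filter on the complete result table, never a truncation of
it.

The underlying assumptions: (1) the cohort is heterogeneous enough that
a regulating enhancer and its target co-vary across samples (a cohort of
near-identical samples has no variance to correlate); (2) TAD boundaries
— borrowed from whatever Hi-C source the user supplies — are a useful
proxy for which contacts are physically possible, even if not sample
matched; (3) activating regulation dominates, so co-activation (r > 0)
is the default call direction.

### Coordinates and anchors

All coordinates are 0-based half-open (BED convention) internally; GTF
input is converted at the parsing boundary (handled by `pyranges`). A
gene is one interval per gene id spanning the union of its transcripts;
its TSS is the leftmost base on +/unstranded and the rightmost base on −.
TAD membership is decided by point anchors — enhancer midpoint and gene
TSS by default — because a point inside a non-overlapping TAD set is
unambiguous; `body` anchoring (maximal-overlap assignment) is available
for both feature classes. Genes outside every TAD are rescued to the
nearest TAD edge on their chromosome by default (equidistant ties go to
the lower-coordinate TAD — deterministic and tested); enhancers are not
rescued by default, since an enhancer in TAD-free territory has weaker
evidence of belonging anywhere. Both rescues are switchable.

Reported distances: `distance_bp` is the unsigned enhancer-midpoint to
gene-TSS distance; `signed_offset_bp` orients it by gene strand
(negative = enhancer upstream of the TSS), since upstream/downstream is
the biologically meaningful direction.

### Correlation and p-values

Three coefficients are supported. Pearson r uses the two-sided t test
with n − 2 degrees of freedom; Spearman is Pearson on average-tie ranks
with the same t approximation; Kendall τ-b uses the exact null
distribution for tie-free samples up to n = 33 and the tie-corrected
normal approximation otherwise (the convention of `scipy.stats`, which
the implementation delegates to for Kendall). Pearson and Spearman are
computed by vectorized in-package formulas so that the permutation test
can rerun thousands of pairs hundreds of times cheaply; the test suite
verifies them against both `scipy.stats` and independently coded
textbook oracles (including an exact inversion-count enumeration for
Kendall) to 1e−10 in r and 1e−8 in p.

A zero-variance vector makes r undefined; such pairs are reported as
r = 0, p = 1 and flagged `degenerate` (with a logged warning) rather
than raised, so one dead feature cannot abort a genome-scale run.
Fewer than 4 common samples is a hard error — correlation across fewer
is meaningless.

Both matrices are transformed with log2(x + 1) before correlation and
distance by default: RPKM-like inputs are heavy-tailed and the log
stabilizes Pearson in particular. The transform is a documented,
switchable default (`log_transform`). The Euclidean distance is taken on
the same transformed scale and deliberately **not** standardized — its
purpose is to flag pairs whose high r coexists with very different
magnitudes, which standardizing would erase.

### FDR control

Storey q-values: π̂₀(λ) = #{p > λ}/(m(1 − λ)) on λ = 0.05, 0.10, …,
0.95, smoothed by a cubic polynomial fit and evaluated at λ = 0.95,
clamped to (0, 1]; then q_i = π̂₀ · min over p_(j) ≥ p_(i) of m·p_(j)/j.
BH is the identical step-up with π₀ ≡ 1, so the two agree exactly
whenever π̂₀ = 1. The cubic-polynomial smoother was cross-checked
against R's `smooth.spline(df = 3)` on uniform p-value draws and agrees
to ~0.001; its single-draw sampling sd at m = 10,000 is about 0.033,
which is the scale to expect when judging π̂₀ against its true value.
With fewer than 100 p-values the smoother is unstable and `storey`
falls back to BH with a warning. Adjustment is always one global
computation over all pairs — per-TAD or per-chromosome adjustment would
invalidate the genome-wide threshold the EAG definition uses.

EAGs use gene-level set semantics: a gene with many significant
enhancers counts once. This makes the EAG count anti-monotone in the
q threshold, a property the test suite asserts.

## Validation procedures

**Random-TAD permutation.** Per chromosome the covered span decomposes
into gap₀ tad₁ gap₁ tad₂ …; TAD lengths (carrying their ids) are
permuted uniformly while gap lengths stay fixed in place, and
coordinates are rebuilt from the original first start. This conserves
exactly — and the tests assert on every call — TAD count, TAD-length
multiset, gap-length multiset and covered span per chromosome, so the
null keeps the genome's accessible-territory structure and only breaks
the pairing. Jointly shuffling the gap order as well is available
behind `shuffle_gaps`. Replicate i derives its seed from (base_seed, i)
via `numpy.random.SeedSequence`. Reported per threshold: the empirical
p = (1 + #{null ≥ observed})/(R + 1), bounded below by 1/(R + 1), and
the upper Gaussian tail of a normal fitted to the null counts — the
only way a claim sharper than the empirical bound is expressible with a
few hundred replicates; the normal p is reported alongside the
empirical one, never instead of it (undefined when the null sd is 0).

Note that the permutation null is not trivially empty: a pair whose
members are close relative to typical TAD length often stays co-domained
under a re-tiling of the same territory, so null EAG counts are a
substantial fraction of the observed count, and the comparison is a real
one.

**Saturation.** For each subsample size n, samples are drawn without
replacement (seeded per (n, repetition)) and the TAD-dependent stages
rerun. Two fractions are reported against the full-cohort EAG set:
intersection recovery |EAG_sub ∩ EAG_full|/|EAG_full| and the count
ratio |EAG_sub|/|EAG_full| — the two readings of "EAGs retained" —
aggregated as mean ± sd per n. Recovery at n = full cohort is exactly 1
by construction. An optional raw-p threshold (typically 0.05) replaces
the q threshold for the EAG definition, the usual choice when
subsampled power is low.

**Closest-gene comparison.** For each enhancer the k nearest genes per
side (by |TSS − midpoint|, ties broken by gene id) define the naive
annotation. Per k the procedure reports the fraction of correlation
EAGs found among the closest sets, the converse fraction, and — the
false-positive diagnostic — the fraction of closest-only genes that are
not co-located in any TAD with the enhancer that nominated them, with
the candidate-pair table as the co-location oracle.

**TAD-class stratification.** Two TAD sets are partitioned by reciprocal
overlap (≥ 0.8 on both sides by default → common); pair correlations
from the two analyses are summarized (median, quartiles, n) per class,
with common pairs taken from the first analysis so each pair counts
once.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:
a 24-sample cohort (the typical scale of tumor-cohort enhancer studies)
over ~100 TADs of human scale (mean 0.8 Mb, sd 0.25 Mb, min 0.15 Mb,
gaps mean 0.12 Mb) on 4 synthetic chromosomes, with Poisson(3) genes and
Poisson(4) enhancers per TAD. 30% of genes carry one planted link to a
same-TAD enhancer (enhancers never reused); a planted pair shares a
latent activation

u_s = √w·ĝ_s + √(1 − w)·η_s,  x_s = μ + σ(√ρ·u_s + √(1 − ρ)·ε_s)

where ĝ is the standardized indicator of the pair's randomly chosen
active subgroup (2 groups by default) and w = 0.3 its variance share —
giving corr(x, y) = ρ (default 0.9) plus the bimodal two-cluster scatter
characteristic of subgroup-specific enhancers. w = 0.3 is deliberately
moderate: with two groups, two planted pairs sharing a TAD and an active
group have cross-correlation ρ·w ≈ 0.27, visible but rarely significant
at q ≤ 0.01 with n = 24, keeping the planted truth interpretable.
Everything unlinked is independent noise; 10% of genes are drawn lowly
expressed (mean 0.8 on the log2 scale) for realism. Log-scale values map
to the RPKM-like input scale via v = 2^x − 1 clipped at 0 — the exact
inverse of the analysis transform, so planted correlations survive the
round trip (clipping affects only the negligible left tail of the
means used). A configurable fraction of genes is placed wholly within
the first 40% of the gap following their TAD, which guarantees their
nearest TAD is the one holding their planted enhancer — the geometry
that exercises nearest-TAD rescue. `distal_fraction` controls how many
planted enhancers are chosen so that their globally nearest gene is not
their partner; the truth table records the realized flag geometrically,
since a TAD with a single gene cannot host a distal link.

What the generator does **not** emulate: mapping artifacts, batch
effects, spatially correlated background signal along the genome,
copy-number-driven co-variation, and enhancers regulating multiple
genes. Passing tests therefore demonstrate the statistical machinery's
correctness and calibration under the stated model, not robustness to
real-data confounders.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use reduced problem sizes
chosen to make the checks sharp but quick: ~500 TADs / ~2,000 pairs for
type-I calibration (binomial 99% interval around p < 0.05), ~150 TADs
for power/FDR on planted ρ = 0.9 links, 60 TADs × 100 replicates for the
permutation sweep, 5×5 subsample grid for saturation. The statistical
conclusions at these sizes (calibration, recovery, direction of the
permutation comparison) are size stable; counts scale with the genome.

Other choices: q monotone in p is enforced by construction (cumulative
minimum over the sorted step-up); π̂₀ > 1 clamps to 1 and a
non-positive smoothed π̂₀ falls back to the smallest positive grid
estimate (warned); nearest-TAD ties go upstream; body-anchor overlap
ties go to the leftmost TAD; pair enumeration and the output table have
deterministic orders ((tad, enhancer, gene) and (q, |r| desc, enhancer,
gene) respectively); matrices with any non-finite entry are rejected at
load unless the caller opts into dropping incomplete features — silent
imputation would distort correlations.

## Limitations

Correlation is not causation: a significant within-TAD pair is a
hypothesis about regulation, not a demonstrated contact. The method
cannot compensate for a TAD annotation from a distant cell type beyond
the nearest-TAD rescue, and all statistical guarantees quantified here
are under the generator's model. Kendall correlation is the slowest
path (per-pair exact/asymptotic computation rather than vectorized
algebra) and is best reserved for smaller pair sets.
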