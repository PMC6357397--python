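"""Gene filtering, correlation, FDR and the composed workflow."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ORACLES, bh_oracle
from tadlink import (CorrelationConfig, FeatureMatrix, GenomicInterval,
                     TADSet, compute_qvalues, correlate_many, correlate_pair,
                     estimate_pi0, euclidean_distance, extract_eags,
                     filter_genes, run_full_analysis)


def _expr_matrix(values, biotypes=None, samples=None):
    n_feat, n_samp = np.shape(values)
    samples = samples or [f"s{i}" for i in range(n_samp)]
    feats = [GenomicInterval("chr1", 1000 * i + 1, 1000 * i + 500, f"g{i}", "+")
             for i in range(n_feat)]
    ids = [f.id for f in feats]
    meta = None
    if biotypes is not None:
        meta = pd.DataFrame({"gene_name": ids, "gene_biotype": biotypes},
                            index=ids)
    return FeatureMatrix(pd.DataFrame(values, index=ids, columns=samples),
                         feats, meta)


class TestFilterGenes:
    def test_biotype_filter_keeps_requested_types(self):
        expr = _expr_matrix(np.ones((5, 4)),
                            biotypes=["protein_coding"] * 3 + ["lincRNA"] * 2)
        out = filter_genes(expr, "biotype", {"protein_coding"})
        assert out.feature_ids == ["g0", "g1", "g2"]

    def test_none_mode_is_identity(self):
        expr = _expr_matrix(np.random.default_rng(0).random((5, 4)))
        out = filter_genes(expr, "none")
        assert out is expr

    def test_mixture_separates_bimodal_expression(self):
        # 500 silent genes ~N(0.5, 0.2^2) and 500 expressed ~N(6, 1) mean
        # log2 expression: the mixture should recover the split almost
        # perfectly (>=99% of the high component, <=1% of the low one).
        rng = np.random.default_rng(42)
        n = 24
        low = rng.normal(0.5, 0.2, size=500).clip(0.01)
        high = rng.normal(6.0, 1.0, size=500).clip(0.01)
        means = np.concatenate([low, high])
        values = 2.0 ** (means[:, None] + rng.normal(0, 0.05, (1000, n))) - 1
        expr = _expr_matrix(values.clip(0))
        kept = set(filter_genes(expr, "mixture").feature_ids)
        high_kept = sum(f"g{i}" in kept for i in range(500, 1000)) / 500
        low_kept = sum(f"g{i}" in kept for i in range(500)) / 500
        assert high_kept >= 0.99
        assert low_kept <= 0.01

    def test_degenerate_means_keep_everything(self, caplog):
        expr = _expr_matrix(np.full((6, 4), 3.0))
        with caplog.at_level("WARNING", logger="tadlink"):
            out = filter_genes(expr, "mixture")
        assert out.feature_ids == expr.feature_ids

    def test_modes_compose(self):
        expr = _expr_matrix(np.ones((4, 4)),
                            biotypes=["protein_coding", "lincRNA"] * 2)
        out = filter_genes(expr, ["biotype", "none"], {"lincRNA"})
        assert out.feature_ids == ["g1", "g3"]


class TestCorrelatePair:
    def test_exact_linearity_gives_r_one(self):
        r, p = correlate_pair([1, 2, 3, 4], [2, 4, 6, 8], "pearson")
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_perfect_rank_reversal_spearman(self):
        r, _ = correlate_pair([1, 2, 3, 4], [4, 3, 2, 1], "spearman")
        assert r == pytest.approx(-1.0)

    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall"])
    def test_matches_textbook_oracle(self, method):
        rng = np.random.default_rng(7)
        for _ in range(25):
            x, y = rng.normal(size=24), rng.normal(size=24)
            r, p = correlate_pair(x, y, method)
            r0, p0 = ORACLES[method](x, y)
            assert r == pytest.approx(r0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-8)

    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall"])
    def test_scipy_cross_check(self, method):
        import scipy.stats as sps
        fn = {"pearson": sps.pearsonr, "spearman": sps.spearmanr,
              "kendall": sps.kendalltau}[method]
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = correlate_pair(x, y, method)
        ref = fn(x, y)
        assert r == pytest.approx(float(ref.statistic), abs=1e-12)
        assert p == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_zero_variance_reports_degenerate_not_error(self, caplog):
        with caplog.at_level("WARNING", logger="tadlink"):
            r, p = correlate_pair([1, 1, 1, 1], [1, 2, 3, 4])
        assert (r, p) == (0.0, 1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4"):
            correlate_pair([1, 2, 3], [1, 2, 3])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 50), st.floats(-10, 10))
    def test_pearson_invariant_under_positive_affine_maps(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r0, p0 = correlate_pair(x, y, "pearson")
        r1, p1 = correlate_pair(a * x + b, y, "pearson")
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert p1 == pytest.approx(p0, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @pytest.mark.parametrize("method", ["spearman", "kendall"])
    @given(seed=st.integers(0, 10_000))
    def test_rank_methods_invariant_under_monotone_transforms(self, method,
                                                             seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r0, p0 = correlate_pair(x, y, method)
        r1, p1 = correlate_pair(np.exp(x), y ** 3, method)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-10)


class TestEuclideanDistance:
    def test_identical_vectors_distance_zero(self):
        assert euclidean_distance([1.5, 2.5, 3.5], [1.5, 2.5, 3.5]) == 0.0

    def test_three_four_five(self):
        assert euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_scale_sensitivity_flags_perfect_correlation(self):
        # y = 10x correlates perfectly but lies far away: the flag the
        # distance exists for
        x = np.array([1.0, 2.0, 3.0])
        r, _ = correlate_pair([1, 2, 3, 4], [10, 20, 30, 40], "pearson")
        assert r == pytest.approx(1.0)
        assert euclidean_distance(x, 10 * x) == pytest.approx(np.sqrt(1134))


class TestQValues:
    def test_bh_step_up_worked_example(self):
        q = compute_qvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_identical_pvalues_unchanged(self):
        q = compute_qvalues([0.05] * 10, "bh")
        assert q == pytest.approx([0.05] * 10)

    def test_bh_matches_literal_step_up_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.random(500)
        q = compute_qvalues(p, "bh")
        assert q == pytest.approx(bh_oracle(list(p)), abs=1e-12)
        assert q == pytest.approx(multipletests(p, method="fdr_bh")[1],
                                  abs=1e-12)

    def test_storey_with_pi0_one_equals_bh_exactly(self):
        rng = np.random.default_rng(5)
        p = rng.random(300)
        np.testing.assert_array_equal(compute_qvalues(p, "storey", pi0=1.0),
                                      compute_qvalues(p, "bh"))

    def test_storey_pi0_unbiased_on_uniform_pvalues(self):
        # the smoother's single-draw sd is ~0.033 at m=10,000 (matches
        # R smooth.spline df=3); test the mean over draws, which pins
        # unbiasedness rather than one draw's noise
        estimates = [estimate_pi0(np.random.default_rng(s).random(10_000))
                     for s in range(10)]
        assert np.mean(estimates) == pytest.approx(1.0, abs=0.03)
        assert np.max(np.abs(np.array(estimates) - 1.0)) <= 0.12

    def test_storey_shrinks_q_when_signal_present(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.random(800), rng.random(200) * 1e-4])
        qs = compute_qvalues(p, "storey")
        qb = compute_qvalues(p, "bh")
        assert estimate_pi0(p) < 1.0
        assert (qs <= qb + 1e-12).all()

    def test_small_input_falls_back_to_bh(self, caplog):
        p = [0.01, 0.2, 0.5, 0.9]
        with caplog.at_level("WARNING", logger="tadlink"):
            q = compute_qvalues(p, "storey")
        assert q == pytest.approx(compute_qvalues(p, "bh"))
        assert any("π0" in r.message or "BH" in r.message
                   for r in caplog.records)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_q_monotone_in_p(self, pvals):
        q = compute_qvalues(pvals, "bh")
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestWorkflow:
    def _single_pair_inputs(self):
        tads = TADSet([GenomicInterval("chr1", 0, 10_000, "T")])
        enh = FeatureMatrix(
            pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["e"],
                         columns=list("abcdef")),
            [GenomicInterval("chr1", 100, 200, "e")])
        expr = FeatureMatrix(
            pd.DataFrame([[2.0, 4, 6, 8, 10, 12]], index=["g"],
                         columns=list("abcdef")),
            [GenomicInterval("chr1", 5000, 6000, "g", "+")])
        return enh, expr, tads

    def test_single_cohoused_pair_yields_one_record(self):
        enh, expr, tads = self._single_pair_inputs()
        rec = run_full_analysis(enh, expr, tads)
        assert len(rec) == 1
        assert rec.loc[0, "tad_id"] == "T"
        assert rec.loc[0, "gene_in_tad"]

    def test_qvalues_joint_over_all_pairs(self, default_records):
        # q-values must be a monotone function of p across the whole
        # table, which fails if adjustment were per TAD
        rec = default_records.sort_values("p_value")
        assert (np.diff(rec["q_value"]) >= -1e-12).all()

    def test_full_table_not_truncated_by_significance(self, default_records):
        assert (default_records["q_value"] > 0.5).any()
        assert (default_records["q_value"] <= 0.01).any()

    def test_eag_set_antimonotone_in_threshold(self, default_records):
        sizes = [len(extract_eags(default_records, t))
                 for t in (1e-4, 1e-3, 0.01, 0.05, 0.1)]
        assert sizes == sorted(sizes)

    def test_extract_eags_counts_genes_once(self):
        rec = pd.DataFrame({
            "gene_id": ["g1", "g1", "g1", "g2"],
            "correlation": [0.9, 0.8, 0.7, -0.95],
            "q_value": [0.001, 0.002, 0.003, 0.001],
        })
        assert extract_eags(rec, 0.01) == {"g1"}  # 3 enhancers, one gene
        assert extract_eags(rec, 0.01, require_positive=False) == {"g1", "g2"}
        assert extract_eags(rec.iloc[:0], 0.01) == set()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CorrelationConfig(method="biweight")
        with pytest.raises(ValueError):
            CorrelationConfig(q_threshold=1.5)


def test_correlate_many_agrees_with_scalar_path():
    rng = np.random.default_rng(21)
    X, Y = rng.normal(size=(5, 16)), rng.normal(size=(5, 16))
    r, p, _ = correlate_many(X, Y, "spearman")
    for i in range(5):
        ri, pi = correlate_pair(X[i], Y[i], "spearman")
        assert ri == pytest.approx(r[i], abs=1e-14)
        assert pi == pytest.approx(p[i], abs=1e-14)
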