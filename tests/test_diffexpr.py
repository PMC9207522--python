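import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oostager import SimConfig, StageDesign, generate_counts, generate_design, generate_truth
from oostager import diffexpr as de
from oostager.diffexpr import MedianOfRatiosNormalizer, NegativeBinomialDE


class TestFilterLowCounts:
    @pytest.mark.parametrize("row,kept", [
        ([1, 1, 1, 1, 1, 0], False),   # sum 5: "less than 6" is strict
        ([1, 1, 1, 1, 1, 1], True),    # sum 6: boundary retained
        ([0, 0, 0, 0, 0, 0], False),
    ])
    def test_boundary(self, row, kept):
        counts = pd.DataFrame([row], index=["g"],
                              columns=[f"s{i}" for i in range(6)])
        out = de.filter_low_count_genes(counts)
        assert ("g" in out.index) is kept

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(5, size=(50, 4)),
                              index=[f"g{i}" for i in range(50)])
        out = de.filter_low_count_genes(counts)
        assert list(out.index) == [g for g in counts.index if g in out.index]


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        np.testing.assert_allclose(de.estimate_size_factors(counts), [1, 1])

    def test_doubled_sample(self):
        # B = 2 x A exactly: geometric mean splits the factor of 2
        counts = pd.DataFrame({"A": [10, 4, 7], "B": [20, 8, 14]})
        sf = de.estimate_size_factors(counts)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_zero_genes_excluded_from_reference(self):
        counts = pd.DataFrame([[0, 0], [2, 2]], columns=["a", "b"])
        np.testing.assert_allclose(de.estimate_size_factors(counts), [1, 1])

    def test_no_reference_gene_errors(self):
        counts = pd.DataFrame([[0, 5], [3, 0]], columns=["a", "b"])
        with pytest.raises(de.NormalizationError):
            de.estimate_size_factors(counts)

    def test_equivariance_on_all_positive_matrix(self):
        # scaling one sample's counts by c scales its factor by c relative
        # to the others (factors are defined up to the global geometric mean)
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, size=(40, 3)),
                              columns=["a", "b", "c"])
        sf = de.estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 3
        sf2 = de.estimate_size_factors(scaled)
        np.testing.assert_allclose(sf2["b"] / sf2["a"],
                                   3 * sf["b"] / sf["a"], rtol=1e-10)
        np.testing.assert_allclose(sf2["c"] / sf2["a"], sf["c"] / sf["a"],
                                   rtol=1e-10)

    def test_agrees_with_pydeseq2(self):
        """Independent cross-check of median-of-ratios against pydeseq2."""
        pydeseq2_pp = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 500, size=(100, 6)))
        _, sf_ref = pydeseq2_pp.deseq2_norm(counts.T)
        np.testing.assert_allclose(de.estimate_size_factors(counts),
                                   np.asarray(sf_ref), rtol=1e-10)


class TestNormalize:
    def test_unit_factors_identity(self, small_counts):
        sf = pd.Series(1.0, index=small_counts.columns)
        pd.testing.assert_frame_equal(de.normalize(small_counts, sf),
                                      small_counts.astype(float))

    def test_scaling_invariance(self, small_counts):
        sf = de.estimate_size_factors(small_counts)
        scaled = small_counts.copy()
        scaled["B1"] = scaled["B1"] * 2
        sf2 = sf.copy()
        sf2["B1"] = sf2["B1"] * 2
        pd.testing.assert_frame_equal(de.normalize(scaled, sf2),
                                      de.normalize(small_counts, sf))

    def test_basemean_is_mean_of_normalized_row(self):
        counts = pd.DataFrame([[2, 4, 6, 8], [1, 1, 1, 1]],
                              columns=["a", "b", "c", "d"])
        sf = de.estimate_size_factors(counts)
        normalized = de.normalize(counts, sf)
        np.testing.assert_allclose(de._base_mean(normalized),
                                   normalized.mean(axis=1))


class TestDispersion:
    @staticmethod
    def _study(alpha, n_reps, n_genes=10_000, seed=0):
        cfg = SimConfig(n_genes=n_genes, fraction_null=1.0,
                        dispersion=(alpha, alpha), n_stages=2, n_reps=n_reps,
                        baseline_mean=(100.0, 100.0),
                        size_factor_range=(1.0, 1.0), seed=seed)
        design = generate_design(cfg)
        counts, _ = generate_counts(generate_truth(cfg), design, cfg)
        return counts, design

    def test_poisson_data_estimate_at_floor(self):
        counts, design = self._study(alpha=0.0, n_reps=5)
        alpha = de.estimate_dispersion(counts.astype(float), design,
                                       smooth=False)
        assert alpha.median() <= 2 * de.DISPERSION_FLOOR

    def test_consistency_at_ten_replicates(self):
        counts, design = self._study(alpha=0.2, n_reps=10)
        alpha = de.estimate_dispersion(counts.astype(float), design,
                                       smooth=False)
        assert abs(alpha.median() - 0.2) <= 0.25 * 0.2

    def test_constant_row_at_floor(self, two_stage_design):
        frame = pd.DataFrame([[7.0] * 4, [5, 9, 2, 14]],
                             columns=list(two_stage_design.samples))
        alpha = de.estimate_dispersion(frame, two_stage_design, smooth=False)
        assert alpha.iloc[0] == de.DISPERSION_FLOOR

    def test_no_replicates_errors(self):
        design = StageDesign(("A", "B"), {"a1": "A", "b1": "B"})
        frame = pd.DataFrame([[1.0, 2.0]], columns=["a1", "b1"])
        with pytest.raises(ValueError, match="replicates"):
            de.estimate_dispersion(frame, design)


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([0.04, 0.01], [0.04, 0.02]),
    ])
    def test_hand_computed(self, p, expected):
        np.testing.assert_allclose(de.bh_adjust(p), expected)

    def test_nan_passthrough_excluded_from_m(self):
        out = de.bh_adjust([0.04, np.nan, 0.01])
        np.testing.assert_allclose(out[[0, 2]], [0.04, 0.02])
        assert np.isnan(out[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariant_and_bounded(self, pvals, rnd):
        p = np.asarray(pvals)
        order = list(range(len(p)))
        rnd.shuffle(order)
        adj = de.bh_adjust(p)
        adj_perm = de.bh_adjust(p[order])
        np.testing.assert_allclose(adj[order], adj_perm)
        assert (adj <= 1 + 1e-12).all()


class TestLRT:
    def test_df_is_stages_minus_one(self, null_study):
        cfg, design, truth, counts = null_study
        sub = counts.iloc[:50]
        sf = de.estimate_size_factors(sub)
        disp = pd.Series(0.1, index=sub.index)
        res = de.lrt_stage_test(sub, design, sf, disp)
        from scipy import stats
        np.testing.assert_allclose(
            res["pvalue"], stats.chi2.sf(res["stat"], len(design.stages) - 1))

    def test_null_type_one_error_in_band(self, null_study):
        """Flat genes, 5 stages x 2 reps, alpha=0.1: p<0.05 fraction near
        nominal (small-sample liberality up to 2x nominal tolerated)."""
        cfg, design, truth, counts = null_study
        cf = de.filter_low_count_genes(counts)
        sf = de.estimate_size_factors(cf)
        disp = de.estimate_dispersion(de.normalize(cf, sf), design)
        res = de.lrt_stage_test(cf, design, sf, disp)
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.10

    def test_power_on_planted_eightfold(self):
        cfg = SimConfig(n_genes=500, fraction_null=0.0,
                        effect_fold=(8.0, 8.0), baseline_mean=(100.0, 100.0),
                        dispersion=(0.05, 0.05), seed=13)
        design = generate_design(cfg)
        counts, _ = generate_counts(generate_truth(cfg), design, cfg)
        sf = de.estimate_size_factors(counts)
        disp = de.estimate_dispersion(de.normalize(counts, sf), design)
        res = de.lrt_stage_test(counts, design, sf, disp)
        assert (res["pvalue"] < 1e-4).mean() >= 0.90


class TestWald:
    @staticmethod
    def _fit(counts, design):
        sf = de.estimate_size_factors(counts)
        disp = de.estimate_dispersion(de.normalize(counts, sf), design)
        return sf, disp

    def test_antisymmetry(self, null_study):
        cfg, design, truth, counts = null_study
        sub = counts.iloc[:100]
        sf, disp = self._fit(sub, design)
        ab = de.wald_pairwise(sub, design, sf, disp, "Nuc", "MatBb")
        ba = de.wald_pairwise(sub, design, sf, disp, "MatBb", "Nuc")
        np.testing.assert_allclose(ab["log2FoldChange"],
                                   -ba["log2FoldChange"], atol=1e-6)
        np.testing.assert_allclose(ab["pvalue"], ba["pvalue"], atol=1e-8)

    def test_null_median_lfc_near_zero(self):
        # equal stage means in expectation, sampling noise small enough
        # (alpha=0.005, 5 reps, mu=200) that any systematic offset would show
        cfg = SimConfig(n_genes=3000, fraction_null=1.0, n_stages=2,
                        n_reps=5, dispersion=(0.005, 0.005),
                        baseline_mean=(200.0, 200.0), seed=15)
        design = generate_design(cfg)
        counts, _ = generate_counts(generate_truth(cfg), design, cfg)
        sf, disp = self._fit(counts, design)
        res = de.wald_pairwise(counts, design, sf, disp, "stage1", "stage2")
        assert res["log2FoldChange"].abs().median() < 0.1

    def test_planted_fourfold_estimate(self):
        # true fold 4 between low and high stages, mu=200, alpha=0.02
        cfg = SimConfig(n_genes=2000, fraction_null=0.0, n_stages=2,
                        effect_fold=(4.0, 4.0), baseline_mean=(200.0, 200.0),
                        dispersion=(0.02, 0.02), seed=14)
        design = generate_design(cfg)
        truth = generate_truth(cfg)
        counts, _ = generate_counts(truth, design, cfg)
        sf, disp = self._fit(counts, design)
        res = de.wald_pairwise(counts, design, sf, disp, "stage1", "stage2")
        signed = res["log2FoldChange"].abs()
        assert 1.8 <= signed.median() <= 2.2

    def test_basemean_identical_across_contrasts(self, null_study):
        cfg, design, truth, counts = null_study
        sub = counts.iloc[:80]
        sf, disp = self._fit(sub, design)
        r1 = de.wald_pairwise(sub, design, sf, disp, "Nuc", "MatBb")
        r2 = de.wald_pairwise(sub, design, sf, disp, "StageII", "StageIII")
        pd.testing.assert_series_equal(r1["baseMean"], r2["baseMean"])


class TestEstimators:
    def test_normalizer_transform_divides_by_factors(self, small_counts):
        X = small_counts.T  # samples x genes
        norm = MedianOfRatiosNormalizer().fit(X)
        out = norm.transform(X)
        np.testing.assert_allclose(
            out.to_numpy(), X.to_numpy() / norm.size_factors_[:, None])

    def test_de_estimator_matches_functions(self, null_study):
        cfg, design, truth, counts = null_study
        sub = counts.iloc[:100]
        est = NegativeBinomialDE().fit(
            sub.T, [design.sample_to_stage[s] for s in sub.columns])
        sf = de.estimate_size_factors(de.filter_low_count_genes(sub))
        pd.testing.assert_series_equal(est.size_factors_, sf)
        res = est.wald_results("Nuc", "MatBb")
        assert res["contrast"].iloc[0] == "MatBb_vs_Nuc"

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        est = NegativeBinomialDE(min_total=10)
        assert clone(est).get_params()["min_total"] == 10
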