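"""Normalization, activity thresholding and SPE pattern classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from spehet import expression_spe as es
from spehet import synthetic_data as sd
from spehet.genotype_regions import ZYG_HET, ZYG_HOM_A, ZYG_HOM_B, ZYG_NO_INFO
from spehet.io import CLASS_BC_A, CLASS_BC_B, CLASS_F1


class TestArtifactSmoother:
    def test_artifact_free_counts_give_flat_prediction(self):
        rng = np.random.default_rng(0)
        n = 500
        gc = rng.uniform(0.3, 0.7, n)
        loglen = np.log(rng.uniform(500, 8000, n))
        counts = np.full(n, 100.0) * rng.lognormal(0, 0.05, n)
        pred = es.fit_artifact_smoother(counts, gc, loglen)
        assert pred.std() / pred.mean() < 0.10

    def test_monotone_gc_bias_recovered(self):
        rng = np.random.default_rng(1)
        n = 800
        gc = rng.uniform(0.2, 0.8, n)
        loglen = np.log(rng.uniform(500, 8000, n))
        truth = np.exp(2.5 * gc)
        counts = 50 * truth * rng.lognormal(0, 0.3, n)
        pred = es.fit_artifact_smoother(counts, gc, loglen)
        assert spearmanr(pred, truth).statistic > 0.9

    def test_duplicated_gene_gets_identical_prediction(self):
        gc = np.array([0.4] * 100 + [0.6] * 100)
        loglen = np.array([7.0] * 100 + [8.0] * 100)
        counts = np.array([50.0] * 100 + [200.0] * 100)
        pred = es.fit_artifact_smoother(counts, gc, loglen)
        assert np.allclose(pred[:100], pred[0])
        assert np.allclose(pred[100:], pred[100])

    def test_constant_covariates_fall_back_with_warning(self):
        counts = np.random.default_rng(2).lognormal(4, 1, 100)
        with pytest.warns(UserWarning, match="constant"):
            pred = es.fit_artifact_smoother(counts, np.full(100, 0.5),
                                            np.full(100, 7.0))
        assert np.allclose(pred, pred[0]) and (pred > 0).all()

    def test_gene_norm_factors_are_inverse_predictions(self):
        assert es.gene_norm_factors(np.array([4.0]))[0] == 0.25
        assert np.allclose(es.gene_norm_factors(np.full(5, 2.0)), 0.5)
        with pytest.raises(ValueError):
            es.gene_norm_factors(np.array([0.0]))


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        counts = pd.DataFrame(np.tile(np.arange(1, 101)[:, None], (1, 4)),
                              columns=list("abcd"))
        assert np.allclose(es.tmm_factors(counts), 1.0)

    def test_doubled_library_factor_ratio_is_half(self):
        """Direct-computation oracle: a library that is an exact doubling has
        zero trimmed mean of M, so the factor ratio is the depth ratio."""
        rng = np.random.default_rng(3)
        base = rng.lognormal(4, 1, 500).round() + 1
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        f = es.tmm_factors(counts)
        # oracle: M = log2((2b/2N)/(b/N)) = 0 for every gene -> pure depth
        assert f["b"] / f["a"] == pytest.approx(0.5, rel=1e-12)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_disjoint_expression_support_rejected(self):
        counts = pd.DataFrame({"a": [5, 5, 0, 0], "b": [0, 0, 5, 5]})
        with pytest.raises(ValueError, match="reference"):
            es.tmm_factors(counts)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [5, 5], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            es.tmm_factors(counts)


class TestNormalizeAndThreshold:
    def test_normalization_arithmetic(self):
        raw = pd.DataFrame({"s1": [10.0, 0.0]})
        out = es.normalize(raw, np.array([0.5, 0.5]), pd.Series({"s1": 2.0}))
        assert out.loc[0, "s1"] == 10.0
        assert out.loc[1, "s1"] == 0.0

    def test_genotype_means_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        raw = pd.DataFrame(rng.poisson(50, (20, 6)),
                           columns=[f"g{i//3}_e{i%3}" for i in range(6)])
        samples = pd.DataFrame({"sample": raw.columns,
                                "genotype_id": [c.split("_")[0] for c in raw.columns]})
        a = es.genotype_means(raw, samples)
        perm = raw[raw.columns[::-1]]
        b = es.genotype_means(perm, samples.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b[a.columns])

    def test_quantile_threshold_hand_computed(self):
        means = pd.DataFrame({"g1": [4.0, 12.0], "g2": [8.0, 16.0]})
        assert es.activity_threshold(means) == pytest.approx(7.0)

    def test_zeros_do_not_move_threshold(self):
        means = pd.DataFrame({"g1": [4.0, 12.0, 0.0, 0.0], "g2": [8.0, 16.0, 0.0, 0.0]})
        assert es.activity_threshold(means) == pytest.approx(7.0)

    def test_equal_means_leave_no_gene_active(self):
        means = pd.DataFrame({"g1": [3.0, 3.0], "g2": [3.0, 3.0]})
        tau = es.activity_threshold(means)
        assert tau == 3.0
        assert not es.call_activity(means, tau).any().any()

    def test_no_nonzero_means_rejected(self):
        with pytest.raises(ValueError):
            es.activity_threshold(pd.DataFrame({"g": [0.0, 0.0]}))

    def test_activity_is_strict(self):
        means = pd.DataFrame({"g": [1.0, 1.0 + 1e-9, 0.0]})
        act = es.call_activity(means, 1.0)
        assert act["g"].tolist() == [False, True, False]

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_threshold_scales_and_activity_invariant(self, scale):
        rng = np.random.default_rng(5)
        means = pd.DataFrame(rng.lognormal(2, 1, (30, 4)))
        tau = es.activity_threshold(means)
        tau_s = es.activity_threshold(means * scale)
        assert tau_s == pytest.approx(tau * scale, rel=1e-9)
        pd.testing.assert_frame_equal(es.call_activity(means, tau),
                                      es.call_activity(means * scale, tau_s))


class TestSpeClassification:
    def _activity(self, hybrid, mat, pat):
        return pd.DataFrame({"H": [hybrid], "M": [mat], "P": [pat]},
                            index=["g1"]).astype(bool)

    def test_pattern_1_maternal_het(self):
        act = self._activity(True, True, False)
        zyg = pd.Series({"g1": ZYG_HET})
        out = es.classify_spe("H", "M", "P", CLASS_BC_A, act, zyg)
        assert out.loc[0, "pattern"] == 1

    def test_pattern_7_maternal_hom_mo17(self):
        act = self._activity(True, True, False)
        zyg = pd.Series({"g1": ZYG_HOM_B})
        out = es.classify_spe("H", "M", "P", CLASS_BC_B, act, zyg)
        assert out.loc[0, "pattern"] == 7

    def test_both_parents_active_is_non_spe(self):
        act = self._activity(True, True, True)
        zyg = pd.Series({"g1": ZYG_HET})
        out = es.classify_spe("H", "M", "P", CLASS_BC_A, act, zyg)
        assert out.loc[0, "pattern"] == es.NON_SPE

    def test_unknown_zygosity_is_unclassified(self):
        act = self._activity(True, False, True)
        zyg = pd.Series({"g1": ZYG_NO_INFO})
        out = es.classify_spe("H", "M", "P", CLASS_BC_A, act, zyg)
        assert out.loc[0, "pattern"] == es.UNCLASSIFIED

    def test_reference_hybrid_patterns(self):
        act = self._activity(True, False, True)
        out = es.classify_spe("H", "M", "P", CLASS_F1, act)
        assert out.loc[0, "pattern"] == es.REF_SPE_PATERNAL

    def test_summary_counts_conserve_total(self):
        rng = np.random.default_rng(6)
        rows = []
        for h in ("h1", "h2"):
            for g in range(50):
                pat = rng.choice([1, 2, 3, 4, es.NON_SPE], p=[.1, .1, .1, .1, .6])
                rows.append((h, f"g{g}", pat, ZYG_HET, ""))
        asg = pd.DataFrame(rows, columns=["hybrid_id", "gene_id", "pattern",
                                          "zygosity", "active_parent"])
        summary = es.summarize_spe(asg)
        pattern_cols = [c for c in summary.columns if c != "total"]
        assert (summary[pattern_cols].sum(axis=1) == summary["total"]).all()


class TestPatternCountTest:
    def _counts(self, deltas, n_hyb=50, seed=0):
        rng = np.random.default_rng(seed)
        hyb_eff = rng.normal(0, 30, n_hyb)
        data = {p: 300 + d + hyb_eff + rng.normal(0, 20, n_hyb)
                for p, d in deltas.items()}
        return pd.DataFrame(data, index=[f"h{i}" for i in range(n_hyb)])

    def test_identical_counts_not_significant(self):
        res = es.pattern_count_test(self._counts({1: 0, 2: 0, 3: 0, 4: 0}))
        assert (res["p_value"] > 0.05).all()

    def test_large_shift_detected(self):
        res = es.pattern_count_test(self._counts({1: 200, 2: 0, 3: 0, 4: 0}))
        row = res[(res["pattern_a"] == 1) & (res["pattern_b"] == 3)].iloc[0]
        assert row["p_value"] < 1e-4

    def test_type1_error_controlled_under_permutation(self):
        """Null pattern labels: rejection rate at alpha=0.05 stays nominal."""
        rng = np.random.default_rng(7)
        n_sig = 0
        n_rep = 120
        for r in range(n_rep):
            counts = self._counts({1: 0, 2: 0}, n_hyb=30, seed=100 + r)
            res = es.pattern_count_test(counts)
            n_sig += int(res["p_value"].iloc[0] < 0.05)
        rate = n_sig / n_rep
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_single_hybrid_rejected(self):
        with pytest.raises(ValueError):
            es.pattern_count_test(pd.DataFrame({1: [3]}, index=["h1"]))


class TestActiveGeneSummary:
    def test_hybrid_union_exceeds_parent_max(self):
        act = pd.DataFrame({"P1": [1, 1, 0, 0], "P2": [0, 0, 1, 1],
                            "H": [1, 1, 1, 1]}).astype(bool)
        s = es.active_gene_summary(act)
        assert s["active_counts"]["H"] >= s["active_counts"].drop("H").max()

    def test_correlation_with_heterozygosity_on_simulation(self, activity,
                                                           region_set):
        from spehet import genotype_regions as gr
        het = {}
        for rid in region_set.kept_rils:
            reg = region_set.for_ril(rid)
            het[f"B73x{rid}"] = gr.heterozygosity_fraction(reg, CLASS_BC_A)
            het[f"MO17x{rid}"] = gr.heterozygosity_fraction(reg, CLASS_BC_B)
        hybrids = [h for h in het if h in activity.active.columns]
        s = es.active_gene_summary(activity.active[hybrids],
                                   pd.Series(het).loc[hybrids])
        assert s["pearson_r"] > 0
        assert s["pearson_p"] < 0.01

    def test_degenerate_identical_genotypes_report_nan(self):
        act = pd.DataFrame({"a": [1, 0], "b": [1, 0]}).astype(bool)
        s = es.active_gene_summary(act, pd.Series({"a": 0.4, "b": 0.6}))
        assert np.isnan(s["pearson_r"])

    def test_hybrid_surplus_under_spe_mechanism(self, activity, expression):
        """Simulated hybrids express more genes than their parental average."""
        act = activity.active
        surplus = []
        for m_id in expression["genotypes"].query("klass == 'RIL'")["ril_id"]:
            for prefix, parent in (("B73x", "B73"), ("MO17x", "MO17")):
                h = f"{prefix}{m_id}"
                surplus.append(act[h].sum() - 0.5 * (act[parent].sum()
                                                     + act[m_id].sum()))
        assert np.mean(surplus) > 0
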