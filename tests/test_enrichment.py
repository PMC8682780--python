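import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chromacontact import ConfigurationError, DataError
from chromacontact import enrichment as en
from chromacontact.io_formats import ProteinQuantTable


def make_ratio_table(ratios: dict[str, list]) -> ProteinQuantTable:
    n = len(next(iter(ratios.values())))
    data = pd.DataFrame(ratios, index=pd.Index([f"P{i}" for i in range(n)], name="protein_id"))
    data["gene_name"] = "g"
    for flag in ("is_reverse_decoy", "is_contaminant", "only_identified_by_site"):
        data[flag] = False
    return ProteinQuantTable(data, ratio_columns=list(ratios))


class TestAssembleLogRatios:
    def test_forward_ratio_two_gives_plus_one(self):
        table = make_ratio_table({"ratio_f1": [2.0]})
        m = en.assemble_log_ratios(table, [("ratio_f1", "forward")])
        assert m.iloc[0, 0] == pytest.approx(1.0)

    def test_reverse_ratio_half_gives_plus_one(self):
        table = make_ratio_table({"ratio_r1": [0.5]})
        m = en.assemble_log_ratios(table, [("ratio_r1", "reverse")])
        assert m.iloc[0, 0] == pytest.approx(1.0)

    def test_missing_ratios_stay_missing(self):
        table = make_ratio_table({"ratio_f1": [np.nan, 2.0]})
        m = en.assemble_log_ratios(table, [("ratio_f1", "forward")])
        assert np.isnan(m.iloc[0, 0]) and m.iloc[1, 0] == 1.0

    def test_unknown_orientation_is_config_error(self):
        table = make_ratio_table({"ratio_f1": [2.0]})
        with pytest.raises(ConfigurationError, match="orientation"):
            en.assemble_log_ratios(table, [("ratio_f1", "sideways")])


class TestFilterMinEvidence:
    ORIENT = {"f1": "forward", "f2": "forward", "r1": "reverse"}

    def test_one_forward_plus_one_reverse_retained(self):
        m = pd.DataFrame({"f1": [1.0], "f2": [np.nan], "r1": [0.5]})
        kept = en.filter_min_evidence(m, "forward_and_reverse", orientations=self.ORIENT)
        assert len(kept) == 1

    def test_forward_only_removed(self):
        m = pd.DataFrame({"f1": [1.0], "f2": [1.0], "r1": [np.nan]})
        kept = en.filter_min_evidence(m, "forward_and_reverse", orientations=self.ORIENT)
        assert len(kept) == 0

    def test_min_k_boundary_retained(self):
        m = pd.DataFrame([[1.0, 2.0, np.nan, np.nan, np.nan]])
        kept = en.filter_min_evidence(m, "min_k_replicates", min_k=2)
        assert len(kept) == 1

    def test_empty_matrix_passes_through(self):
        m = pd.DataFrame(columns=["a", "b"], dtype=float)
        assert len(en.filter_min_evidence(m, "min_k_replicates", min_k=2)) == 0


class TestQuantileNormalize:
    def test_two_columns_take_per_rank_mean(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = en.quantile_normalize(m)
        expected = [2.5, 3.5, 4.5]
        assert list(out["a"]) == expected and list(out["b"]) == expected

    def test_identical_columns_are_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(en.quantile_normalize(m), m)

    def test_single_column_group_unchanged(self):
        m = pd.DataFrame({"a": [5.0, 1.0], "b": [2.0, 3.0]})
        out = en.quantile_normalize(m, groups={"a": "g1", "b": "g2"})
        pd.testing.assert_frame_equal(out, m)

    def test_groups_normalized_separately(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0],
                          "c": [10.0, 20.0], "d": [30.0, 40.0]})
        out = en.quantile_normalize(
            m, groups={"a": "x", "b": "x", "c": "y", "d": "y"})
        assert list(out["a"]) == [2.0, 3.0]
        assert list(out["c"]) == [20.0, 30.0]

    def test_missing_cells_stay_missing_and_rank_order_kept(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 3.0, 2.0], "b": [4.0, 5.0, 6.0, 7.0]})
        out = en.quantile_normalize(m)
        assert np.isnan(out.loc[1, "a"])
        assert out.loc[2, "a"] > out.loc[3, "a"] > out.loc[0, "a"]

    def test_observed_multiset_identical_across_complete_columns(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.lognormal(0, 1, size=(50, 4)))
        out = en.quantile_normalize(m)
        ref = np.sort(out[0].to_numpy())
        for c in (1, 2, 3):
            np.testing.assert_allclose(np.sort(out[c].to_numpy()), ref)


class TestImpute:
    GROUPS5 = {f"c{i}": "crosslinked" for i in range(5)} | {f"n{i}": "control" for i in range(5)}

    def test_sicap_two_missing_imputed_with_row_mean(self):
        row = {"c0": 10.0, "c1": 12.0, "c2": np.nan, "c3": 11.0, "c4": np.nan}
        row |= {f"n{i}": 1.0 for i in range(5)}
        m = pd.DataFrame([row])
        out = en.impute(m, "sicap_protein", self.GROUPS5, control_group="control")
        assert out.loc[0, "c2"] == pytest.approx(11.0)
        assert out.loc[0, "c4"] == pytest.approx(11.0)

    def test_sicap_three_missing_left_missing(self):
        row = {"c0": 10.0, "c1": 12.0, "c2": np.nan, "c3": np.nan, "c4": np.nan}
        row |= {f"n{i}": 1.0 for i in range(5)}
        out = en.impute(pd.DataFrame([row]), "sicap_protein", self.GROUPS5,
                        control_group="control")
        assert out.loc[0, ["c2", "c3", "c4"]].isna().all()

    def test_sicap_all_missing_control_gets_column_minima(self):
        rows = [
            {f"c{i}": 10.0 + i for i in range(5)} | {f"n{i}": float(2 + i) for i in range(5)},
            {f"c{i}": 20.0 + i for i in range(5)} | {f"n{i}": np.nan for i in range(5)},
        ]
        out = en.impute(pd.DataFrame(rows), "sicap_protein", self.GROUPS5,
                        control_group="control")
        for i in range(5):
            assert out.loc[1, f"n{i}"] == pytest.approx(2.0 + i)

    def test_complete_rows_unchanged(self):
        rows = [{f"c{i}": 10.0 for i in range(5)} | {f"n{i}": 1.0 for i in range(5)}]
        m = pd.DataFrame(rows)
        pd.testing.assert_frame_equal(
            en.impute(m, "sicap_protein", self.GROUPS5, control_group="control"), m)

    def test_spacemap_all_missing_fraction_gets_minima(self):
        groups = {"x1": "crosslinked", "x2": "crosslinked",
                  "r1": "released", "r2": "released"}
        m = pd.DataFrame([
            {"x1": 5.0, "x2": 6.0, "r1": 7.0, "r2": 9.0},
            {"x1": np.nan, "x2": np.nan, "r1": 8.0, "r2": 10.0},
        ])
        out = en.impute(m, "spacemap_peptide", groups)
        assert out.loc[1, "x1"] == 5.0 and out.loc[1, "x2"] == 6.0
        # partial missingness is left alone
        m2 = pd.DataFrame([{"x1": np.nan, "x2": 2.0, "r1": 1.0, "r2": 1.0}])
        out2 = en.impute(m2, "spacemap_peptide", groups)
        assert np.isnan(out2.loc[0, "x1"])

    def test_entirely_missing_column_is_error(self):
        groups = {"x1": "a", "r1": "b"}
        m = pd.DataFrame({"x1": [np.nan, np.nan], "r1": [1.0, 2.0]})
        with pytest.raises(DataError, match="minimum"):
            en.impute(m, "spacemap_peptide", groups)


class TestFitEBHyperparams:
    def test_identical_variances_give_infinite_d0(self):
        h = en.fit_eb_hyperparams(np.full(100, 0.5), 4.0)
        assert math.isinf(h.d0)
        assert h.s0sq == pytest.approx(0.5)

    def test_recovers_prior_df_within_tolerance(self):
        rng = np.random.default_rng(7)
        sigma2 = 4.0 * 1.0 / rng.chisquare(4.0, 2000)
        s2 = sigma2 * rng.chisquare(2, 2000) / 2
        h = en.fit_eb_hyperparams(s2, 2.0)
        assert 3.2 <= h.d0 <= 4.8
        assert 0.8 <= h.s0sq <= 1.2

    def test_single_feature_is_error(self):
        with pytest.raises(DataError, match="fixed"):
            en.fit_eb_hyperparams(np.array([0.5]), 2.0)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in (0.1, 0.5, 2.0, 10.0, 200.0):
            y = float(polygamma(1, x))
            assert en.trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestModeratedT:
    def test_worked_one_sample_example(self):
        # x=(1.0, 1.2, 0.8): s2=0.04, d=2; with prior d0=4, s0sq=1 the
        # posterior variance is 0.68 and t = 1/sqrt(0.68/3)
        res = en.moderated_t_test(
            pd.DataFrame([[1.0, 1.2, 0.8]]), "one_sample_ratio",
            hyper=en.EBHyperparams(4.0, 1.0))
        assert res.loc[0, "log2fc"] == pytest.approx(1.0)
        assert res.loc[0, "s2_post"] == pytest.approx(0.68)
        assert res.loc[0, "t_mod"] == pytest.approx(2.100420, rel=1e-5)
        assert res.loc[0, "df_total"] == 6.0
        assert res.loc[0, "p"] == pytest.approx(
            2 * stats.t.sf(2.1004201, 6), rel=1e-6)

    def test_d0_zero_recovers_ordinary_t(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 1.0, (20, 5))
        res = en.moderated_t_test(pd.DataFrame(x), "one_sample_ratio",
                                  hyper=en.EBHyperparams(0.0, 1.0))
        t_ref, p_ref = stats.ttest_1samp(x, 0.0, axis=1)
        np.testing.assert_allclose(res["t_mod"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-10)

    def test_all_zero_observations_give_null_result(self):
        res = en.moderated_t_test(pd.DataFrame([[0.0, 0.0, 0.0]]),
                                  "one_sample_ratio", hyper=en.EBHyperparams(4.0, 1.0))
        assert res.loc[0, "t_mod"] == 0.0
        assert res.loc[0, "p"] == 1.0

    def test_insufficient_observations_reported_untested(self):
        res = en.moderated_t_test(pd.DataFrame([[1.0, np.nan, np.nan]]),
                                  "one_sample_ratio", hyper=en.EBHyperparams(4.0, 1.0))
        assert np.isnan(res.loc[0, "p"])

    def test_two_group_d0_zero_recovers_students_t(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (30, 6))
        groups = {i: ("a" if i < 3 else "b") for i in range(6)}
        res = en.moderated_t_test(pd.DataFrame(x), "two_group", groups=groups,
                                  hyper=en.EBHyperparams(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(x[:, :3], x[:, 3:], axis=1)
        np.testing.assert_allclose(res["t_mod"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-10)

    def test_moderation_shrinks_toward_prior(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.5, (50, 4))
        res = en.moderated_t_test(pd.DataFrame(x), "one_sample_ratio",
                                  hyper=en.EBHyperparams(4.0, 1.0))
        lo = np.minimum(res["s2"], 1.0)
        hi = np.maximum(res["s2"], 1.0)
        assert ((res["s2_post"] >= lo - 1e-12) & (res["s2_post"] <= hi + 1e-12)).all()

    def test_matches_limma_on_frozen_dataset(self):
        # independent oracle: limma 3.58.1 lmFit+eBayes on the identical
        # matrix (seeded below, written to TSV, run once via Rscript);
        # d0/s0sq and the first five t/p values are frozen here
        rng = np.random.default_rng(123)
        var = 4 * 0.09 / rng.chisquare(4.0, 20)
        x = rng.normal(0, 1, (20, 4)) * np.sqrt(var)[:, None]
        x[:3] += 1.0
        res = en.moderated_t_test(pd.DataFrame(x), "one_sample_ratio")
        h = en.fit_eb_hyperparams(res["s2"].to_numpy(), 3.0)
        assert h.d0 == pytest.approx(1.729002935, rel=1e-6)
        assert h.s0sq == pytest.approx(0.03512484404, rel=1e-6)
        limma_t = [4.495934412, 14.71186536, 8.055918111, -1.309938767, -0.6189541957]
        limma_p = [0.007338458879, 3.948616998e-05, 0.0006175394157,
                   0.250233458, 0.5645353131]
        np.testing.assert_allclose(res["t_mod"].iloc[:5], limma_t, rtol=1e-6)
        np.testing.assert_allclose(res["p"].iloc[:5], limma_p, rtol=1e-6)


class TestAdjustBH:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            en.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(en.adjust_bh([0.3]), [0.3])

    def test_equal_ps_are_fixed_point(self):
        np.testing.assert_allclose(en.adjust_bh([0.2] * 5), [0.2] * 5)

    def test_na_excluded_from_ranking(self):
        out = en.adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], en.adjust_bh([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            en.adjust_bh([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(en.adjust_bh(p), expected, rtol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_order_invariant_and_monotone(self, ps, rnd):
        p = np.array(ps)
        adj = en.adjust_bh(p)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        adj_perm = en.adjust_bh(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm])
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1 + 1e-12).all()


class TestClassifyTiers:
    def frame(self, fc, adj):
        return pd.DataFrame({"log2fc": fc, "adj_p": adj})

    def test_thresholds_as_printed(self):
        res = self.frame([1.5, 1.5, 1.0, 0.5], [0.005, 0.05, 0.0001, 0.0001])
        tiers = en.classify_tiers(res)
        assert list(tiers) == [en.TIER_HIGH, en.TIER_SIG, en.TIER_NS, en.TIER_NS]

    def test_strict_inequality_on_fold_change(self):
        tiers = en.classify_tiers(self.frame([1.0], [0.001]))
        assert list(tiers) == [en.TIER_NS]

    def test_tier2_only_mode(self):
        tiers = en.classify_tiers(self.frame([2.0], [0.005]), tier2_only=True)
        assert list(tiers) == [en.TIER_SIG]


def fisher_oracle(table):
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    from math import comb

    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher2x2:
    def test_small_table_exact_value(self):
        assert en.fisher_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70)

    def test_symmetric_table_gives_one(self):
        assert en.fisher_2x2([[5, 5], [5, 5]]) == 1.0

    def test_degenerate_margin_gives_one_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert en.fisher_2x2([[0, 0], [1, 1]]) == 1.0
        assert "degenerate" in caplog.text

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            en.fisher_2x2([[-1, 2], [3, 4]])

    def test_matches_hypergeometric_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = rng.integers(1, 15, size=(2, 2)).tolist()
            assert en.fisher_2x2(t) == pytest.approx(fisher_oracle(t), rel=1e-9)
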