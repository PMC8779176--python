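import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trichamber import (
    assumption_checks,
    boxcox_metric,
    cohens_d,
    oneway_anova,
    run_full_analysis,
    sex_difference_tests,
    treatment_anova,
    tukey_posthoc,
)


class TestAssumptionChecks:
    def test_normal_samples_usually_pass(self):
        rng = np.random.default_rng(11)
        ok_norm = ok_var = 0
        reps = 100
        for _ in range(reps):
            groups = {g: rng.normal(0, 1, 50) for g in "abc"}
            norm_p, bart_p = assumption_checks(groups)
            ok_norm += all(p > 0.05 for p in norm_p.values())
            ok_var += bart_p > 0.05
        assert ok_norm / reps >= 0.80  # (0.95)^3 of replicates expected clean
        assert ok_var / reps >= 0.90

    def test_lognormal_samples_fail_normality(self):
        rng = np.random.default_rng(12)
        reject = 0
        reps = 100
        for _ in range(reps):
            norm_p, _ = assumption_checks({"a": rng.lognormal(0, 1, 50)})
            reject += norm_p["a"] < 0.05
        assert reject / reps >= 0.90

    def test_identical_groups_have_zero_bartlett_statistic(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        _, bart_p = assumption_checks({"a": g, "b": g.copy()})
        assert bart_p == pytest.approx(1.0)

    def test_constant_group_normality_is_missing(self):
        norm_p, _ = assumption_checks({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]})
        assert np.isnan(norm_p["a"])


class TestSexDifferences:
    def _cohort(self, f_vals, m_vals):
        rows = [{"sex": "F", "phase": "sociability", "distance_traveled_m": v}
                for v in f_vals]
        rows += [{"sex": "M", "phase": "sociability", "distance_traveled_m": v}
                 for v in m_vals]
        return pd.DataFrame(rows)

    def test_hand_computed_rank_statistic(self):
        """Two-group Kruskal-Wallis H on six distinct values equals the
        textbook rank formula H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)."""
        f, m = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        res = sex_difference_tests(self._cohort(f, m))
        n = 6
        r_f, r_m = 1 + 3 + 5, 2 + 4 + 6  # ranks of the pooled sample
        h_manual = 12.0 / (n * (n + 1)) * (r_f**2 / 3 + r_m**2 / 3) - 3 * (n + 1)
        assert res.loc[0, "H"] == pytest.approx(h_manual)

    def test_identical_distributions_have_null_effect(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(50, 5, 200)
        res = sex_difference_tests(self._cohort(vals[:100], vals[100:]))
        assert abs(res.loc[0, "cohens_d"]) < 0.3
        assert res.loc[0, "p"] > 0.01

    def test_cohens_d_sign_convention_and_swap(self):
        rng = np.random.default_rng(22)
        a = rng.normal(10, 2, 50)
        b = rng.normal(8, 2, 50)
        d = cohens_d(a, b)
        assert d > 0  # first argument (females) larger
        assert cohens_d(b, a) == pytest.approx(-d)


class TestBoxCox:
    def test_lambda_recovery_cube_root(self):
        """If y = x^(1/3) for near-normal x, the MLE lambda is about 3 (the
        transform that undoes the cube root).  The spread needs to be wide
        enough (CV ~0.3) for the power parameter to be identifiable."""
        rng = np.random.default_rng(31)
        x = np.abs(rng.normal(50, 15, 2000)) + 1
        y = np.cbrt(x)
        _, lam, _ = boxcox_metric(y)
        assert lam == pytest.approx(3.0, abs=0.3)

    def test_normal_data_lambda_near_one(self):
        rng = np.random.default_rng(32)
        _, lam, _ = boxcox_metric(rng.normal(100, 10, 1000))
        assert lam == pytest.approx(1.0, abs=0.3)

    def test_constant_metric_is_identity(self):
        vals = np.full(20, 7.0)
        out, lam, offset = boxcox_metric(vals)
        assert np.allclose(out, vals)
        assert np.isnan(lam)

    def test_zeros_handled_by_offset(self):
        rng = np.random.default_rng(33)
        vals = np.concatenate([[0.0, 0.0], rng.gamma(2, 5, 200)])
        out, lam, offset = boxcox_metric(vals)
        assert offset > 0
        assert np.all(np.isfinite(out))


class TestAnova:
    def test_hand_computed_sums_of_squares(self):
        """3 groups of 4 integers; F and partial eta squared match the
        explicit SS arithmetic."""
        groups = {"a": [1, 2, 3, 4], "b": [3, 4, 5, 6], "c": [5, 6, 7, 8]}
        F, df1, df2, p, eta = oneway_anova(groups)
        grand = np.mean([v for g in groups.values() for v in g])  # 4.5
        ss_between = sum(
            4 * (np.mean(v) - grand) ** 2 for v in groups.values()
        )  # 4*(2^2+0+2^2)=32
        ss_within = sum(
            np.sum((np.array(v) - np.mean(v)) ** 2) for v in groups.values()
        )  # 3*5=15
        assert (df1, df2) == (2, 9)
        assert F == pytest.approx((ss_between / 2) / (ss_within / 9))
        assert eta == pytest.approx(ss_between / (ss_between + ss_within))

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(41)
        groups = {g: rng.normal(i, 1, 15) for i, g in enumerate("abcd")}
        F, _, _, p, _ = oneway_anova(groups)
        ref = sps.f_oneway(*groups.values())
        assert F == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_identical_groups_zero_effect(self):
        cell = pd.DataFrame(
            {"treatment": ["a"] * 3 + ["b"] * 3, "m": [2.0, 2.0, 2.0] * 2}
        )
        res = treatment_anova(cell, "m")
        assert res.partial_eta_sq == 0.0
        assert res.posthoc == []

    def test_small_groups_dropped_with_warning(self):
        cell = pd.DataFrame(
            {
                "treatment": ["a", "a", "a", "b", "c", "c", "c"],
                "m": [1.0, 2.0, 3.0, 9.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.warns(UserWarning, match="dropping"):
            res = treatment_anova(cell, "m")
        assert set(res.group_ns) == {"a", "c"}

    def test_type_i_error_calibrated(self):
        """Under the null (3 equal groups of 20) the 0.05-level ANOVA rejects
        at its nominal rate."""
        rng = np.random.default_rng(42)
        reps = 1000
        hits = 0
        for _ in range(reps):
            groups = {g: rng.normal(0, 1, 20) for g in "abc"}
            *_, p, _ = oneway_anova(groups)
            hits += p < 0.05
        assert 0.035 <= hits / reps <= 0.065


class TestTukey:
    def test_two_identical_groups_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        pairs = tukey_posthoc({"a": g, "b": list(g)})
        assert pairs[0][2] == pytest.approx(1.0, abs=1e-9)

    def test_two_groups_equal_omnibus_anova(self):
        rng = np.random.default_rng(51)
        groups = {"a": rng.normal(0, 1, 12), "b": rng.normal(1, 1, 12)}
        *_, p_anova, _ = oneway_anova(groups)
        p_tukey = tukey_posthoc(groups)[0][2]
        assert p_tukey == pytest.approx(p_anova, abs=1e-9)

    def test_shifted_group_drives_significance(self):
        rng = np.random.default_rng(52)
        groups = {
            "a": rng.normal(0, 1, 20),
            "b": rng.normal(0, 1, 20),
            "c": rng.normal(3, 1, 20),
        }
        pairs = {frozenset((x, y)): p for x, y, p in tukey_posthoc(groups)}
        assert pairs[frozenset(("a", "c"))] < 0.05
        assert pairs[frozenset(("b", "c"))] < 0.05
        assert pairs[frozenset(("a", "b"))] > 0.05

    def test_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(53)
        groups = {g: rng.normal(i * 0.8, 1, 15) for i, g in enumerate("abc")}
        ours = {frozenset((a, b)): p for a, b, p in tukey_posthoc(groups)}
        vals = np.concatenate(list(groups.values()))
        labs = np.repeat(list(groups), [len(v) for v in groups.values()])
        ref = pairwise_tukeyhsd(vals, labs)
        for row, p_ref in zip(np.array(ref._results_table.data[1:]), ref.pvalues):
            key = frozenset((row[0], row[1]))
            assert ours[key] == pytest.approx(p_ref, abs=5e-3)

    def test_adjusted_at_least_unadjusted(self):
        """Tukey-adjusted p >= the pooled-MSE pairwise t-test p, every pair."""
        rng = np.random.default_rng(54)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = {
                f"g{i}": rng.normal(rng.normal(0, 1), 1, int(rng.integers(5, 12)))
                for i in range(k)
            }
            arrays = list(groups.values())
            ns = [len(a) for a in arrays]
            df = sum(ns) - k
            mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / df
            adjusted = tukey_posthoc(groups)
            labels = list(groups)
            for a, b, p_adj in adjusted:
                va, vb = groups[a], groups[b]
                se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
                t = abs(va.mean() - vb.mean()) / se
                p_t = 2 * sps.t.sf(t, df)
                assert p_adj >= p_t - 1e-9


class TestFullAnalysis:
    def _cohort(self, rng, n=12, sexes=("F", "M")):
        rows = []
        for sex in sexes:
            for t in ("DMSO", "A1221", "VIN"):
                for i in range(n):
                    rows.append(
                        {
                            "animal_id": f"{sex}{t}{i}",
                            "sex": sex,
                            "generation": "F3",
                            "lineage": "paternal",
                            "treatment": t,
                            "phase": "sociability",
                            "distance_traveled_m": rng.normal(45, 8),
                            "social_preference_score": float(
                                np.clip(rng.normal(0.63, 0.2), 0.02, 0.98)
                            ),
                        }
                    )
        return pd.DataFrame(rows)

    def test_single_sex_cohort_skips_sex_table(self):
        rng = np.random.default_rng(61)
        bundle = run_full_analysis(self._cohort(rng, sexes=("F",)))
        assert bundle.sex_differences.empty
        assert not bundle.treatment_effects.empty

    def test_boxcox_lambda_shared_across_cells(self):
        rng = np.random.default_rng(62)
        bundle = run_full_analysis(self._cohort(rng))
        te = bundle.treatment_effects
        for metric, sub in te.groupby("metric"):
            assert sub["boxcox_lambda"].nunique() == 1

    def test_posthoc_only_for_significant_cells(self):
        rng = np.random.default_rng(63)
        bundle = run_full_analysis(self._cohort(rng))
        if not bundle.posthoc.empty:
            sig = bundle.treatment_effects.query("p < 0.05")
            keys_sig = set(map(tuple, sig[["metric", "sex"]].to_numpy()))
            keys_post = set(map(tuple, bundle.posthoc[["metric", "sex"]].to_numpy()))
            assert keys_post <= keys_sig
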