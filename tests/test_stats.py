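"""Statistical layer against closed-form and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qthf import (delong_compare, fit_logistic, group_comparison_table,
                  incremental_value_analysis, roc_auc)
from qthf.stats import StatsError, comparison_rows_to_frame, univariate_logistic


def brute_force_auc(scores, labels):
    """O(n^2) Mann-Whitney pair counting."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_placements(scores, labels):
    """Placement values from their defining double sum."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


class TestGroupTable:
    def test_two_group_continuous_uses_student_t(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"group": ["A"] * 40 + ["B"] * 40,
                           "x": np.r_[rng.normal(0, 1, 40), rng.normal(1, 1, 40)]})
        rows = group_comparison_table(df, ["x"], "group")
        assert rows[0].test == "t"
        expected = sps.ttest_ind(df.x[:40], df.x[40:], equal_var=True).pvalue
        assert rows[0].p_value == pytest.approx(expected)

    def test_three_group_continuous_uses_anova(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"group": ["A"] * 30 + ["B"] * 30 + ["C"] * 30,
                           "x": rng.normal(0, 1, 90)})
        rows = group_comparison_table(df, ["x"], "group")
        assert rows[0].test == "ANOVA"

    def test_chi_square_on_event_counts(self):
        # 14 arrests/therapies among 155 BrS vs 1 among 182 NR: association
        # must be significant
        df = pd.DataFrame({
            "group": ["BrS"] * 155 + ["NR"] * 182,
            "event": [1] * 14 + [0] * 141 + [1] * 1 + [0] * 181,
        })
        rows = group_comparison_table(df, ["event"], "group")
        assert rows[0].test == "chi-square"
        assert rows[0].p_value < 0.05

    def test_constant_variable_gives_missing_p(self):
        df = pd.DataFrame({"group": ["A"] * 5 + ["B"] * 5, "x": 1.0})
        rows = group_comparison_table(df, ["x"], "group")
        assert math.isnan(rows[0].p_value)

    def test_empty_group_skips_variable(self, caplog):
        df = pd.DataFrame({"group": ["A"] * 5 + ["B"] * 5,
                           "x": [1.0] * 5 + [float("nan")] * 5})
        rows = group_comparison_table(df, ["x"], "group")
        assert rows == []

    def test_frame_export(self):
        df = pd.DataFrame({"group": ["A"] * 10 + ["B"] * 10,
                           "male": [1] * 6 + [0] * 4 + [1] * 3 + [0] * 7})
        frame = comparison_rows_to_frame(group_comparison_table(df, ["male"], "group"))
        assert {"variable", "p_value", "A", "B"} <= set(frame.columns)


class TestLogistic:
    def test_binary_covariate_or_equals_cross_product(self):
        # 2x2 table (14, 141 / 1, 181): OR = 14*181 / (141*1)
        df = pd.DataFrame({"event": [1] * 14 + [0] * 141 + [1] * 1 + [0] * 181,
                           "brs": [1] * 155 + [0] * 182})
        fit = fit_logistic(df, "event", ["brs"])
        expected = (14 * 181) / (141 * 1)
        assert fit.odds_ratio("brs") == pytest.approx(expected, rel=1e-4)

    def test_ci_coverage_under_null(self):
        # true beta = 0: the Wald 95% CI covers 0 in 95% +/- 2% of replicates
        rng = np.random.default_rng(7)
        n, reps, covered = 1000, 500, 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = (rng.random(n) < 0.4).astype(int)
            fit = fit_logistic(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
            lo, hi = fit.table.loc["x", ["ci_low", "ci_high"]]
            covered += lo <= 1.0 <= hi
        assert covered / reps == pytest.approx(0.95, abs=0.02)

    def test_effect_sign_recovery_at_configured_or(self):
        # OR 1.25 per unit of the metric, n=300: sign recovered in >95% of reps
        rng = np.random.default_rng(8)
        beta = math.log(1.25)
        hits = 0
        reps = 200
        for _ in range(reps):
            st = rng.normal(20, 10, 300)
            lp = -0.3 + beta * (st - 20)
            y = (rng.random(300) < 1 / (1 + np.exp(-lp))).astype(int)
            fit = fit_logistic(pd.DataFrame({"y": y, "st": st}), "y", ["st"])
            hits += fit.table.loc["st", "estimate"] > 0
        assert hits / reps > 0.95

    def test_separation_flagged_not_divergent(self):
        df = pd.DataFrame({"y": [0] * 20 + [1] * 20,
                           "x": list(range(20)) + list(range(100, 120))})
        fit = fit_logistic(df, "y", ["x"])
        assert fit.separation
        assert np.isfinite(fit.table["estimate"]).all()

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        df = pd.DataFrame({"y": (rng.random(50) < 0.5).astype(int),
                           "a": x, "b": 2 * x})
        with pytest.raises(StatsError, match="collinear"):
            fit_logistic(df, "y", ["a", "b"])

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"y": [1] * 10, "x": range(10)})
        with pytest.raises(StatsError, match="both classes"):
            fit_logistic(df, "y", ["x"])

    def test_univariate_table_has_row_per_covariate(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"y": (rng.random(200) < 0.5).astype(int),
                           "a": rng.normal(size=200),
                           "b": (rng.random(200) < 0.5).astype(int)})
        uni = univariate_logistic(df, "y", ["a", "b"])
        assert list(uni.index) == ["a", "b"]
        assert (uni["odds_ratio"] > 0).all()


class TestRoc:
    def test_perfect_separation_auc_one(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_all_ties_auc_half(self):
        r = roc_auc([5.0] * 10, [0, 1] * 5)
        assert r.auc == 0.5

    def test_auc_equals_pair_count_oracle_with_ties(self):
        rng = np.random.default_rng(11)
        scores = np.round(rng.normal(size=30), 1)  # rounding forces ties
        labels = (rng.random(30) < 0.5).astype(int)
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(StatsError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_curve_monotone(self):
        rng = np.random.default_rng(12)
        r = roc_auc(rng.normal(size=50), (rng.random(50) < 0.4).astype(int))
        assert np.all(np.diff(r.sensitivity) >= 0)
        assert np.all(np.diff(1 - r.specificity) >= 0)


class TestDeLong:
    def test_identical_scores_give_zero_difference_p_one(self):
        rng = np.random.default_rng(13)
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        cmp = delong_compare(roc_auc(s, y), roc_auc(s.copy(), y))
        assert cmp.auc_difference == 0.0 and cmp.p_value == 1.0

    def test_placement_values_match_defining_double_sum(self):
        scores = np.array([3.0, 5.0, 7.0, 1.0, 5.0, 6.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        r = roc_auc(scores, labels)
        v10, v01 = brute_force_placements(scores, labels)
        np.testing.assert_allclose(r.placements_pos, v10)
        np.testing.assert_allclose(r.placements_neg, v01)
        # and the variance entering the test statistic matches a hand build
        r2 = roc_auc(scores + np.array([0, 0, 0, 0.5, 0, -2.0]), labels)
        cmp = delong_compare(r, r2)
        w10, w01 = brute_force_placements(scores + np.array([0, 0, 0, 0.5, 0, -2.0]),
                                          labels)
        s10 = np.cov(np.vstack([v10, w10]))
        s01 = np.cov(np.vstack([v01, w01]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 3 \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / 3
        assert cmp.variance == pytest.approx(var, rel=1e-12)

    def test_symmetry_under_model_swap(self):
        rng = np.random.default_rng(14)
        y = (rng.random(60) < 0.5).astype(int)
        a = roc_auc(y + rng.normal(0, 1, 60), y)
        b = roc_auc(y + rng.normal(0, 2, 60), y)
        ab, ba = delong_compare(a, b), delong_compare(b, a)
        assert ab.auc_difference == pytest.approx(-ba.auc_difference)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_mismatched_subjects_rejected(self):
        rng = np.random.default_rng(15)
        y1 = np.array([0, 1] * 10)
        y2 = np.array([1, 0] * 10)
        with pytest.raises(StatsError, match="paired"):
            delong_compare(roc_auc(rng.normal(size=20), y1),
                           roc_auc(rng.normal(size=20), y2))

    def test_variance_agrees_with_bootstrap(self):
        # bootstrap comparator: resample subjects, recompute dAUC
        rng = np.random.default_rng(16)
        n = 400
        y = (rng.random(n) < 0.5).astype(int)
        base = y + rng.normal(0, 1.5, n)
        s1, s2 = base + rng.normal(0, 0.8, n), base + rng.normal(0, 0.8, n)
        cmp = delong_compare(roc_auc(s1, y), roc_auc(s2, y))
        deltas = []
        for _ in range(300):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            deltas.append(roc_auc(s1[idx], y[idx]).auc - roc_auc(s2[idx], y[idx]).auc)
        boot_var = float(np.var(deltas, ddof=1))
        assert cmp.variance == pytest.approx(boot_var, rel=0.35)


class TestIncrementalValue:
    def test_intercept_only_reduced_model_has_auc_half(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame({"y": (rng.random(100) < 0.4).astype(int),
                           "m": rng.normal(size=100)})
        res = incremental_value_analysis(df, [], "m", "y")
        assert res.roc_reduced.auc == 0.5

    def test_independent_metric_adds_no_auc_on_average(self):
        rng = np.random.default_rng(18)
        deltas = []
        for _ in range(200):
            n = 150
            x = rng.normal(size=n)
            y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
            m = rng.normal(size=n)  # independent of outcome
            res = incremental_value_analysis(
                pd.DataFrame({"y": y, "x": x, "m": m}), ["x"], "m", "y")
            deltas.append(res.comparison.auc_difference)
        assert abs(float(np.mean(deltas))) < 0.01

    def test_informative_metric_detected(self):
        rng = np.random.default_rng(19)
        hits = 0
        reps = 40
        for _ in range(reps):
            n = 300
            x = rng.normal(size=n)
            m = rng.normal(20, 10, n)
            lp = -0.3 + 0.5 * x + math.log(1.25) * (m - 20)
            y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
            res = incremental_value_analysis(
                pd.DataFrame({"y": y, "x": x, "m": m}), ["x"], "m", "y")
            hits += (res.comparison.auc_difference > 0
                     and res.comparison.p_value < 0.05)
        assert hits / reps > 0.5
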