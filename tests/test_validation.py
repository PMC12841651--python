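"""Validation statistics against independent oracles and closed forms."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from dropscore import (
    DiscriminationUndefinedError,
    SeparationError,
    ValidationError,
    brier_score,
    calibration_line,
    decision_curve,
    delong_auc,
    events_per_variable,
    fisher_or,
    fit_logistic,
    hosmer_lemeshow,
    likelihood_ratio_test,
    pearson_correlation,
    stratified_outcome_table,
    treat_all_net_benefit,
)


def brute_force_auc(scores, outcomes):
    """Exhaustive concordant-pair counting; ties count one half."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestDelongAuc:
    def test_perfect_separation_gives_one(self):
        r = delong_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = delong_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_hand_listed_scores_match_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.62, 0.21, 0.55, 0.3, 0.9, 0.44]
        y = [0, 0, 1, 1, 0, 0, 1, 0, 1, 0]
        r = delong_auc(scores, y)
        assert r.auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_random_instances_match_pair_counting(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 200))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n) + y, 1)  # rounding induces ties
            r = delong_auc(s, y)
            assert r.auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)
            assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0

    def test_single_class_outcome_raises(self):
        with pytest.raises(DiscriminationUndefinedError):
            delong_auc([1, 2, 3], [1, 1, 1])

    def test_ci_shrinks_with_sample_size(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (50, 500):
            y = rng.integers(0, 2, n)
            s = rng.normal(size=n) + 0.8 * y
            r = delong_auc(s, y)
            widths.append(r.ci_high - r.ci_low)
        assert widths[1] < widths[0]


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups_give_zero_statistic(self):
        # outcomes exactly matching group expectations
        p = np.repeat([0.2, 0.5, 0.8], 10)
        y = np.concatenate([[1] * 2 + [0] * 8, [1] * 5 + [0] * 5, [1] * 8 + [0] * 2])
        rep = hosmer_lemeshow(p, y, groups=3)
        assert rep.hl_chi2 == pytest.approx(0.0, abs=1e-12)
        assert rep.hl_p == pytest.approx(1.0)

    def test_hand_built_three_group_statistic(self):
        p = np.repeat([0.1, 0.4, 0.7], 10)
        y = np.concatenate([[1] * 2 + [0] * 8, [1] * 3 + [0] * 7, [1] * 9 + [0] * 1])
        rep = hosmer_lemeshow(p, y, groups=3)
        chi2 = 0.0
        for pr, obs in ((0.1, 2), (0.4, 3), (0.7, 9)):
            e = 10 * pr
            chi2 += (obs - e) ** 2 / (e * (1 - pr))
        assert rep.hl_chi2 == pytest.approx(chi2)
        assert rep.hl_df == 1

    def test_p_value_agrees_with_odd_df_closed_form(self):
        # chi-square upper tail, df=3: erfc(sqrt(x/2)) + sqrt(2x/pi) exp(-x/2)
        for x in (0.5, 0.72, 2.0, 7.53, 15.0):
            closed = special.erfc(math.sqrt(x / 2)) + math.sqrt(
                2 * x / math.pi
            ) * math.exp(-x / 2)
            assert stats.chi2.sf(x, 3) == pytest.approx(closed, abs=1e-10)

    def test_published_calibration_statistic_rounds_consistently(self):
        # chi2 = 0.72 on 3 df -> p = 0.8685; a statistic rounding to 0.72
        # can print p = 0.869
        p = float(stats.chi2.sf(0.72, 3))
        assert p == pytest.approx(0.8685, abs=5e-5)
        assert float(stats.chi2.sf(0.715, 3)) > 0.8690

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValidationError):
            hosmer_lemeshow([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1], groups=2)


class TestCalibrationLine:
    def test_self_generated_outcomes_are_calibrated(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.9, 4000)
        y = (rng.uniform(size=4000) < p).astype(int)
        slope, citl = calibration_line(p, y)
        assert slope == pytest.approx(1.0, abs=0.1)
        assert citl == pytest.approx(0.0, abs=0.1)

    def test_overconfident_predictions_give_negative_intercept(self):
        rng = np.random.default_rng(6)
        true_p = rng.uniform(0.05, 0.5, 3000)
        y = (rng.uniform(size=3000) < true_p).astype(int)
        slope, citl = calibration_line(np.clip(true_p + 0.25, 0.01, 0.99), y)
        assert citl < 0

    def test_slope_matches_independent_refit(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, 2000)
        y = (rng.uniform(size=2000) < p**1.3).astype(int)
        slope, _ = calibration_line(p, y)
        lp = np.log(p / (1 - p)).reshape(-1, 1)
        sk = LogisticRegression(C=1e12, tol=1e-12, max_iter=2000).fit(lp, y)
        assert slope == pytest.approx(float(sk.coef_[0][0]), abs=1e-5)

    def test_degenerate_predictions_rejected(self):
        with pytest.raises(ValidationError):
            calibration_line([0.0, 0.5, 1.0], [0, 1, 1])


class TestDecisionCurves:
    def test_treat_all_published_value(self):
        # prevalence 27/72 at threshold 0.30 -> 0.375 - 0.625*(3/7) = 0.1071
        assert treat_all_net_benefit(27 / 72, 0.30) == pytest.approx(0.1071, abs=5e-5)

    def test_treat_all_limits(self):
        assert treat_all_net_benefit(0.42, 0.0) == pytest.approx(0.42)
        assert treat_all_net_benefit(0.5, 0.5) == pytest.approx(0.0)
        with pytest.raises(ValidationError):
            treat_all_net_benefit(0.5, 1.0)

    def test_hand_built_confusion_matrix_oracle(self):
        p = np.array([0.1, 0.2, 0.25, 0.35, 0.4, 0.45, 0.6, 0.7, 0.8, 0.9])
        y = np.array([0, 0, 1, 0, 0, 1, 1, 0, 1, 1])
        dc = decision_curve(p, y, thresholds=[0.3])
        # at t=0.3: positives are p>=0.3 -> indices 3..9; TP=4, FP=3
        expected = 4 / 10 - 3 / 10 * (0.3 / 0.7)
        assert dc["net_benefit_model"].iloc[0] == pytest.approx(expected)
        assert dc["net_benefit_treat_none"].iloc[0] == 0.0

    def test_threshold_zero_equals_treat_all(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.01, 0.99, 200)
        y = rng.integers(0, 2, 200)
        dc = decision_curve(p, y, thresholds=[0.0])
        assert dc["net_benefit_model"].iloc[0] == pytest.approx(
            dc["net_benefit_treat_all"].iloc[0]
        )

    def test_perfect_model_attains_prevalence(self):
        y = np.array([0] * 70 + [1] * 30)
        p = np.where(y == 1, 0.95, 0.02)
        dc = decision_curve(p, y, thresholds=[0.1, 0.5, 0.9])
        np.testing.assert_allclose(dc["net_benefit_model"], 0.30)

    def test_model_never_beats_prevalence(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.01, 0.99, 500)
        y = (rng.uniform(size=500) < p).astype(int)
        dc = decision_curve(p, y)
        assert (dc["net_benefit_model"] <= y.mean() + 1e-12).all()


class TestFisherOr:
    def test_balanced_table_gives_unity(self):
        assert fisher_or(10, 10, 10, 10).odds_ratio == pytest.approx(1.0)

    def test_hand_computed_cross_product(self):
        r = fisher_or(12, 8, 5, 15)
        assert r.odds_ratio == pytest.approx(4.5)
        assert not r.continuity_corrected

    def test_row_swap_inverts_odds_ratio(self):
        r1 = fisher_or(12, 8, 5, 10)  # OR = 3.0
        r2 = fisher_or(5, 10, 12, 8)
        assert r1.odds_ratio == pytest.approx(3.0)
        assert r2.odds_ratio == pytest.approx(1.0 / 3.0)
        assert r2.odds_ratio == pytest.approx(round(1 / r1.odds_ratio, 2), abs=5e-3)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_transpose_preserves_odds_ratio(self):
        r1, r2 = fisher_or(7, 3, 4, 11), fisher_or(7, 4, 3, 11)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio)

    def test_p_matches_hypergeometric_enumeration(self):
        a, b, c, d = 6, 4, 2, 9
        r = fisher_or(a, b, c, d)
        # enumerate all tables with the same margins
        row1, col1, n = a + b, a + c, a + b + c + d
        p_obs = stats.hypergeom.pmf(a, n, row1, col1)
        total = sum(
            stats.hypergeom.pmf(k, n, row1, col1)
            for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
            if stats.hypergeom.pmf(k, n, row1, col1) <= p_obs * (1 + 1e-9)
        )
        assert r.p_value == pytest.approx(total, abs=1e-9)

    def test_zero_cell_flags_continuity_correction(self):
        r = fisher_or(0, 10, 5, 5)
        assert r.continuity_corrected
        assert np.isfinite(r.odds_ratio) and r.odds_ratio > 0

    def test_empty_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_or(0, 0, 5, 5)


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.params["const"] == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)
        pi = 0.3
        ll = 100 * (pi * math.log(pi) + (1 - pi) * math.log(1 - pi))
        assert fit.llf == pytest.approx(ll, abs=1e-8)
        assert fit.aic == pytest.approx(2 - 2 * ll, abs=1e-8)

    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=5000)
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
        y = (rng.uniform(size=5000) < p).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        lo, hi = fit.conf_int.loc["x"]
        assert lo <= 0.8 <= hi

    def test_score_equations_hold_at_convergence(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"x1": rng.normal(size=400), "x2": rng.integers(0, 2, 400)})
        lp = -0.5 + 0.6 * X.x1 + 0.9 * X.x2
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-lp))).astype(int)
        fit = fit_logistic(X, y)
        Xd = np.column_stack([np.ones(400), X.to_numpy()])
        resid = y - 1 / (1 + np.exp(-(Xd @ fit.params.to_numpy())))
        assert np.all(np.abs(Xd.T @ resid) < 1e-6)

    def test_perfect_separation_raises(self):
        x = np.concatenate([np.arange(20), np.arange(30, 50)])
        y = np.array([0] * 20 + [1] * 20)
        with pytest.raises(SeparationError):
            fit_logistic(pd.DataFrame({"x": x}), y)


class TestLikelihoodRatio:
    def test_identical_likelihoods_give_null_result(self):
        lr, p = likelihood_ratio_test(-50.0, -50.0, 2)
        assert lr == 0.0 and p == 1.0

    def test_published_model_comparison(self):
        # LR = 7.53 on 3 df -> p = 0.057
        _, p = likelihood_ratio_test(-45.305, -49.07, 3)
        assert 2 * (-45.305 + 49.07) == pytest.approx(7.53)
        assert p == pytest.approx(0.057, abs=5e-4)

    def test_non_nested_models_rejected(self):
        with pytest.raises(ValidationError):
            likelihood_ratio_test(-60.0, -50.0, 1)


class TestSimpleMetrics:
    def test_brier_extremes_and_hand_value(self):
        assert brier_score([1e-9, 1 - 1e-9], [0, 1]) == pytest.approx(0.0, abs=1e-12)
        assert brier_score([0.5] * 4, [0, 1, 0, 1]) == 0.25
        p = [0.1, 0.7, 0.4, 0.95, 0.2]
        y = [0, 1, 1, 1, 0]
        hand = np.mean([(0.1) ** 2, (0.3) ** 2, (0.6) ** 2, (0.05) ** 2, (0.2) ** 2])
        assert brier_score(p, y) == pytest.approx(hand)

    @pytest.mark.parametrize("e,k,r", [(27, 4, 6.75), (10, 1, 10.0), (0, 4, 0.0)])
    def test_events_per_variable(self, e, k, r):
        assert events_per_variable(e, k) == r

    def test_events_per_variable_needs_predictors(self):
        with pytest.raises(ValidationError):
            events_per_variable(5, 0)

    def test_pearson_exact_lines_and_hand_value(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = pearson_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, _ = pearson_correlation(x, [-v for v in x])
        assert r == pytest.approx(-1.0)
        xs = np.array([1, 2, 3, 4, 5], float)
        ys = np.array([2, 1, 4, 3, 7], float)
        hand = np.sum((xs - 3) * (ys - ys.mean())) / np.sqrt(
            np.sum((xs - 3) ** 2) * np.sum((ys - ys.mean()) ** 2)
        )
        r, p = pearson_correlation(xs, ys)
        assert r == pytest.approx(hand)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestStratifiedTable:
    def _clinical_style_cohort(self):
        # 70 Moderate (12 rebubbling) and 6 High (0 rebubbling)
        return pd.DataFrame(
            {
                "risk_category": ["Moderate"] * 70 + ["High"] * 6,
                "rebubbling": [1] * 12 + [0] * 58 + [0] * 6,
                "bcva_12m": [0.31] * 70 + [0.50] * 6,
            }
        )

    def test_published_pooled_rebubbling_rate(self):
        out = stratified_outcome_table(
            self._clinical_style_cohort(), binary_outcomes=["rebubbling"],
            continuous_outcomes=["bcva_12m"],
        )
        row = out["binary"].loc["rebubbling"]
        assert row["pooled_rate_pct"] == pytest.approx(100 * 12 / 76)
        assert round(row["pooled_rate_pct"], 1) == 15.8
        assert row["Moderate_rate_pct"] == pytest.approx(100 * 12 / 70)
        assert row["High_rate_pct"] == 0.0

    def test_single_category_pooled_equals_category(self):
        df = pd.DataFrame({"risk_category": ["Moderate"] * 10,
                           "rebubbling": [1, 0] * 5})
        out = stratified_outcome_table(df, binary_outcomes=["rebubbling"])
        row = out["binary"].loc["rebubbling"]
        assert row["pooled_rate_pct"] == row["Moderate_rate_pct"]

    def test_hand_built_two_category_rates(self):
        df = pd.DataFrame(
            {
                "risk_category": ["Low"] * 4 + ["High"] * 4,
                "rejection": [0, 0, 0, 1, 1, 1, 0, 1],
            }
        )
        out = stratified_outcome_table(df, binary_outcomes=["rejection"])
        row = out["binary"].loc["rejection"]
        assert row["Low_rate_pct"] == pytest.approx(25.0)
        assert row["High_rate_pct"] == pytest.approx(75.0)
        assert 0 <= row["p_value"] <= 1
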