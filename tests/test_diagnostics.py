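"""Evaluation statistics: metrics, odds ratios, tests, ROC, logistic fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lymphovte import (
    ConfusionTable,
    chi_square_test,
    confusion,
    fit_logistic,
    metrics,
    odds_ratio,
    roc,
    two_sample_t,
)


class TestConfusion:
    def test_counts_partition_cohort(self):
        preds = [True, True, False, False, True]
        outs = [True, False, True, False, False]
        ct = confusion(preds, outs)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (1, 2, 1, 1)
        assert ct.n == 5
        assert ct.tp + ct.fn == sum(outs)

    def test_all_negative_no_events(self):
        ct = confusion([False] * 4, [False] * 4)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (0, 0, 0, 4)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([True], [True, False])


class TestMetrics:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            # (tp, fp, fn, tn) -> display-scale percentages
            ((3, 25, 18, 279),
             {"sensitivity": 14.3, "ppv": 10.7, "specificity": 91.8,
              "npv": 93.9, "youden_index": 6.1}),
            ((8, 31, 13, 273),
             {"sensitivity": 38.1, "ppv": 20.5, "specificity": 89.8,
              "npv": 95.5, "youden_index": 27.9}),
        ],
    )
    def test_clinical_metric_sets(self, cells, expected):
        ct = ConfusionTable(*cells)
        assert metrics(ct).as_percentages() == expected

    def test_perfect_classifier(self):
        m = metrics(ConfusionTable(tp=7, fp=0, fn=0, tn=13)).as_percentages()
        assert all(v == 100.0 for v in m.values())

    def test_zero_denominator_flags_undefined(self):
        m = metrics(ConfusionTable(tp=0, fp=0, fn=0, tn=5))
        assert m.sensitivity is None and m.ppv is None
        assert "sensitivity" in m.undefined and "youden_index" in m.undefined
        assert m.specificity == 1.0

    def test_youden_identity(self):
        m = metrics(ConfusionTable(5, 10, 2, 30))
        assert m.youden_index == pytest.approx(m.sensitivity + m.specificity - 1)


class TestOddsRatio:
    def test_history_of_vte_table(self):
        res = odds_ratio(6, 15, 4, 300)
        assert res.or_value == pytest.approx(30.0)
        assert round(res.ci_low, 3) == 7.644
        assert round(res.ci_high, 3) == 117.742

    def test_balanced_table_is_null(self):
        res = odds_ratio(10, 10, 10, 10)
        assert res.or_value == 1.0
        assert res.ci_low < 1.0 < res.ci_high

    def test_mediastinal_involvement_table(self):
        assert odds_ratio(10, 11, 41, 263).or_value == pytest.approx(5.831, abs=5e-4)

    def test_zero_cell_requires_haldane(self):
        with pytest.raises(ValueError, match="zero cell"):
            odds_ratio(0, 5, 3, 10)
        res = odds_ratio(0, 5, 3, 10, method="woolf-haldane")
        assert res.or_value == pytest.approx((0.5 * 10.5) / (5.5 * 3.5))
        assert res.ci_low <= res.or_value <= res.ci_high

    def test_ci_always_brackets_estimate(self):
        for cells in [(1, 2, 3, 4), (20, 5, 7, 100), (2, 2, 50, 50)]:
            res = odds_ratio(*cells)
            assert res.ci_low <= res.or_value <= res.ci_high


class TestChiSquare:
    def test_validation_risk_table_yates(self):
        stat, p = chi_square_test([[6, 15], [3, 74]], correction="yates")
        assert p == pytest.approx(0.002, abs=5e-4)

    def test_identical_row_proportions_give_zero(self):
        stat, p = chi_square_test([[10, 20], [30, 60]], correction="none")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        """Independent oracle: Pearson and Yates sums written out by hand."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(1, 30, size=(2, 2)).astype(float)
            n = t.sum()
            e = np.outer(t.sum(1), t.sum(0)) / n
            pearson = ((t - e) ** 2 / e).sum()
            yates = ((np.maximum(np.abs(t - e) - 0.5, 0.0)) ** 2 / e).sum()
            stat_n, _ = chi_square_test(t, correction="none")
            stat_y, _ = chi_square_test(t, correction="yates")
            assert stat_n == pytest.approx(pearson)
            assert stat_y == pytest.approx(yates)

    @given(
        cells=st.tuples(*[st.integers(min_value=1, max_value=40)] * 4)
    )
    @settings(deadline=None, max_examples=100)
    def test_yates_p_never_below_uncorrected(self, cells):
        t = [[cells[0], cells[1]], [cells[2], cells[3]]]
        _, p_none = chi_square_test(t, correction="none")
        _, p_yates = chi_square_test(t, correction="yates")
        assert p_yates >= p_none - 1e-12

    def test_degenerate_margins_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_test([[0, 0], [3, 4]])


class TestTwoSampleT:
    def test_identical_groups_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        stat, p = two_sample_t(g, g)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_type_i_error_near_nominal(self):
        """Null simulation: rejection rate at alpha=0.05 stays near 5%."""
        rng = np.random.default_rng(12)
        reps, n = 4000, 30
        a = rng.normal(0, 1, (reps, n))
        b = rng.normal(0, 1, (reps, n))
        p = stats.ttest_ind(a, b, axis=1).pvalue
        rate = (p < 0.05).mean()
        assert 0.035 < rate < 0.065

    def test_power_at_published_d_dimer_moments(self):
        """Groups at the published D-dimer means/SDs reject in most replicates."""
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(1171.15, 1025.55, 304)
            b = rng.normal(3196.19, 3348.32, 21)
            _, p = two_sample_t(a, b)
            rejections += p < 0.05
        assert rejections / reps > 0.5

    def test_zero_variance_both_groups_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


def _auc_pair_oracle(values, outcomes):
    """Brute-force concordant-pair count (+0.5 per tie) / (n1 * n0)."""
    pos = [v for v, o in zip(values, outcomes) if o]
    neg = [v for v, o in zip(values, outcomes) if not o]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfectly_separated_marker(self):
        curve = roc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert curve.auc == 1.0
        # optimal cutoff separates the classes
        assert 3 < curve.optimal_cutoff < 10

    def test_all_tied_marker_gives_half(self):
        curve = roc([5.0] * 10, [True] * 4 + [False] * 6)
        assert curve.auc == 0.5

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(6, 25))
            values = rng.integers(0, 8, n).astype(float)  # many ties
            outcomes = rng.random(n) < 0.4
            if outcomes.all() or not outcomes.any():
                continue
            curve = roc(values, outcomes)
            assert curve.auc == pytest.approx(_auc_pair_oracle(values, outcomes))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=40)
        outcomes = rng.random(40) < 0.3
        outcomes[0] = True
        outcomes[1] = False
        base = roc(values, outcomes).auc
        assert roc(np.exp(values), outcomes).auc == pytest.approx(base)
        assert roc(3 * values + 7, outcomes).auc == pytest.approx(base)

    def test_curve_sweeps_corner_to_corner(self):
        rng = np.random.default_rng(10)
        values = rng.normal(size=30)
        outcomes = rng.random(30) < 0.5
        outcomes[0], outcomes[1] = True, False
        curve = roc(values, outcomes)
        assert curve.tpr[0] == 0.0 and curve.fpr[0] == 0.0
        assert curve.tpr[-1] == 1.0 and curve.fpr[-1] == 1.0
        assert (np.diff(curve.tpr) >= 0).all() and (np.diff(curve.fpr) >= 0).all()

    def test_optimal_cutoff_maximises_youden(self):
        values = [1, 2, 3, 4, 5, 6]
        outcomes = [False, False, True, False, True, True]
        curve = roc(values, outcomes)
        best = curve.youden.max()
        chosen = np.where(curve.thresholds == curve.optimal_cutoff)[0][0]
        assert curve.youden[chosen] == pytest.approx(best)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            roc([1, 2, 3], [True, True, True])


class TestLogistic:
    def test_intercept_only_recovers_log_odds(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_logistic(np.empty((100, 0)), y)
        assert fit.coef[0] == pytest.approx(math.log(0.3 / 0.7), rel=1e-6)

    def test_single_binary_covariate_matches_odds_ratio(self):
        rng = np.random.default_rng(21)
        x = rng.random(400) < 0.4
        p = np.where(x, 0.55, 0.25)
        y = rng.random(400) < p
        a = int((x & y).sum()); b = int((~x & y).sum())
        c = int((x & ~y).sum()); d = int((~x & ~y).sum())
        table_or = odds_ratio(a, b, c, d).or_value
        fit = fit_logistic(x.astype(float)[:, None], y)
        assert fit.odds_ratios[1] == pytest.approx(table_or, rel=1e-8)

    def test_parameter_recovery_on_simulated_design(self):
        rng = np.random.default_rng(31)
        n = 5000
        x1 = (rng.random(n) < 0.3).astype(float)
        x2 = rng.normal(size=n)
        beta = np.array([-2.0, 0.8, 0.5])
        eta = beta[0] + beta[1] * x1 + beta[2] * x2
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        fit = fit_logistic(np.column_stack([x1, x2]), y)
        for est, se, true in zip(fit.coef, fit.se, beta):
            assert abs(est - true) <= 3 * se

    def test_wald_and_or_columns(self):
        rng = np.random.default_rng(41)
        x = rng.normal(size=300)
        y = rng.random(300) < 1 / (1 + np.exp(-(0.5 + x)))
        fit = fit_logistic(x[:, None], y)
        assert fit.wald == pytest.approx((fit.coef / fit.se) ** 2)
        assert fit.odds_ratios == pytest.approx(np.exp(fit.coef))
        frame = fit.to_frame()
        assert list(frame.columns) == ["B", "SE", "Wald", "p", "OR"]

    def test_perfect_separation_is_diagnosed(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = x.astype(bool)
        with pytest.raises(RuntimeError):
            fit_logistic(x[:, None], y)

    def test_non_binary_outcomes_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(np.ones((10, 1)), np.arange(10))
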