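"""Metric oracles: printed-table recomputation, Clopper-Pearson vs beta
quantiles, AUC vs brute-force concordance, regression error summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wakemark.evaluation import (
    ConfusionCounts,
    confusion_rates,
    exact_binomial_ci,
    percentile_abs_error,
    r2_score_signed,
    rates_pct,
    rmse,
    roc_auc,
    sp_targeted_sensitivity,
)


class TestConfusionRates:
    def test_study_within_participant_counts(self):
        # 79/85 WR and 81/84 SD correct
        r = rates_pct(confusion_rates(ConfusionCounts(tn=79, fp=6, fn=3, tp=81)), 1)
        assert r["accuracy"] == 94.7
        assert r["true_wr_rate"] == 92.9
        assert r["true_sd_rate"] == 96.4
        # exact arithmetic before rounding
        exact = confusion_rates(ConfusionCounts(79, 6, 3, 81))
        from fractions import Fraction
        assert exact["accuracy"] == Fraction(160, 169)

    def test_study_between_participant_counts(self):
        # 73/85 WR and 61/84 SD correct
        r = rates_pct(confusion_rates(ConfusionCounts(tn=73, fp=12, fn=23, tp=61)), 1)
        assert r["accuracy"] == 79.3

    def test_all_correct(self):
        r = rates_pct(confusion_rates(ConfusionCounts(10, 0, 0, 10)))
        assert all(v == 100.0 for v in r.values())

    def test_undefined_rate_reported_absent(self):
        # degenerate: every sample predicted WR -> predicted-SD rate undefined
        r = confusion_rates(ConfusionCounts(tn=8, fp=0, fn=8, tp=0))
        assert r["predicted_sd_rate"] is None
        assert r["true_sd_rate"] == 0


class TestExactBinomialCI:
    def test_printed_interval_identification(self):
        # the printed bounds uniquely identify the Clopper-Pearson method
        lo, hi = exact_binomial_ci(160, 169)
        assert round(lo * 100, 1) == 90.1 and round(hi * 100, 1) == 97.5
        lo, _ = exact_binomial_ci(134, 169)
        assert round(lo * 100, 1) == 72.4
        lo, hi = exact_binomial_ci(16, 16)
        assert round(lo * 100, 1) == 79.4 and hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 16), abs=1e-12)

    def test_zero_successes_closed_form(self):
        lo, hi = exact_binomial_ci(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** 0.1, abs=1e-9)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(n=st.integers(1, 200), data=st.data())
    def test_matches_beta_quantile_oracle(self, n, data):
        s = data.draw(st.integers(0, n))
        lo, hi = exact_binomial_ci(s, n)
        oracle_lo = stats.beta.ppf(0.025, s, n - s + 1) if s > 0 else 0.0
        oracle_hi = stats.beta.ppf(0.975, s + 1, n - s) if s < n else 1.0
        assert abs(lo - oracle_lo) < 1e-6 and abs(hi - oracle_hi) < 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(1, 0)
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)


class TestRocAuc:
    def test_perfect_separator(self):
        curve = roc_auc([0, 0, 1, 1], [0, 0, 1, 1])
        assert curve.auc_pct == 100.0

    def test_hand_example_mann_whitney(self):
        # 3 of 4 discordant/concordant pairs -> AUC 75%
        curve = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert curve.auc_pct == pytest.approx(75.0)

    def test_brute_force_concordance_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        curve = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = np.mean([
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        ])
        assert curve.auc_pct == pytest.approx(conc * 100, abs=1e-9)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        assert abs(roc_auc(scores, labels).auc_pct - 50) < 3

    def test_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0.01, 0.99, size=60)
        labels = rng.integers(0, 2, size=60)
        a = roc_auc(scores, labels).auc_pct
        b = roc_auc(np.log(scores / (1 - scores)), labels).auc_pct
        assert a == pytest.approx(b)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        labels = np.repeat([0, 1], 50)
        curve = roc_auc(scores, labels)
        assert curve.ci95[0] <= curve.auc_pct <= curve.ci95[1]
        boot = roc_auc(scores, labels, ci_method="bootstrap")
        assert boot.ci95[0] <= boot.auc_pct <= boot.ci95[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestSpTargetedSensitivity:
    def test_perfect_separator_keeps_full_sensitivity(self):
        curve = roc_auc([0, 0, 1, 1], [0, 0, 1, 1])
        thr, sn, sp = sp_targeted_sensitivity(curve, 0.99)
        assert sn == 1.0 and sp == 1.0

    def test_zero_target_gives_max_tpr(self):
        rng = np.random.default_rng(4)
        curve = roc_auc(rng.normal(size=50), rng.integers(0, 2, size=50))
        _, sn, _ = sp_targeted_sensitivity(curve, 0.0)
        assert sn == 1.0

    def test_gaussian_closed_form(self):
        # equal-variance Gaussian scores with separation d': at specificity
        # target a, SN = Phi(d' - Phi^-1(a))
        rng = np.random.default_rng(5)
        d = 1.5
        n = 4000
        scores = np.concatenate([rng.normal(0, 1, n), rng.normal(d, 1, n)])
        labels = np.repeat([0, 1], n)
        curve = roc_auc(scores, labels)
        _, sn, _ = sp_targeted_sensitivity(curve, 0.85)
        expected = stats.norm.cdf(d - stats.norm.ppf(0.85))
        assert abs(sn - expected) < 0.05

    def test_unreachable_target_reported(self):
        curve = roc_auc([1, 1, 1, 1.0], [0, 0, 1, 1])
        # ties everywhere: only the all-positive point, spec 0 or 1 via inf thr
        out = sp_targeted_sensitivity(curve, 1.1)
        assert out is None


class TestRegressionMetrics:
    def test_rmse_closed_form(self):
        # errors (0, 2) -> sqrt((0+4)/2) = sqrt(2)
        assert rmse([1, 4], [1, 2]) == pytest.approx(np.sqrt(2))
        assert rmse([1, 5], [1, 2]) == pytest.approx(np.sqrt(9 / 2))

    def test_r2_sign_behavior(self):
        y = np.array([1.0, 2, 3, 4])
        assert r2_score_signed(y, y) == 1.0
        assert r2_score_signed(y, np.full(4, y.mean())) == 0.0
        assert r2_score_signed(y, y[::-1]) < 0

    def test_percentile_errors(self):
        assert percentile_abs_error([1, 2, 3], [1, 2, 3], q=(50, 90)) == {
            50.0: 0.0, 90.0: 0.0
        }
        got = percentile_abs_error([2, 4, 6, 8], [1, 2, 3, 4], q=50)
        assert got[50.0] == pytest.approx(2.5)

    def test_half_normal_median_oracle(self):
        rng = np.random.default_rng(6)
        actual = rng.uniform(0, 38, size=2000)
        pred = actual + rng.normal(0, 3, size=2000)
        med = percentile_abs_error(pred, actual, q=50)[50.0]
        assert abs(med - 3 * stats.norm.ppf(0.75)) < 0.2
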