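"""Metric primitives: confusion rates, exact binomial CIs, ROC/AUC, and
regression error summaries.

Conventions: the positive class is the sleep-deprived (SD) condition;
accuracies, AUCs and rates are reported as percentages.  Confusion-matrix
rates use exact rational arithmetic, with rounding applied only when
reports are serialized.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats


@dataclass
class ConfusionCounts:
    """tn/fp/fn/tp with SD as the positive class."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


def confusion_rates(c: ConfusionCounts) -> dict:
    """The four conditional correct-classification rates plus accuracy.

    Rates are named by their conditioning event (numerator/denominator
    explicit) rather than by clinical labels:
    true_wr_rate = tn/(tn+fp), true_sd_rate = tp/(tp+fn),
    predicted_wr_rate = tn/(tn+fn), predicted_sd_rate = tp/(tp+fp).
    Undefined rates (zero denominator) are returned as None.
    """

    def rate(num, den):
        return None if den == 0 else Fraction(num, den)

    out = {
        "accuracy": Fraction(c.tn + c.tp, c.total),
        "true_wr_rate": rate(c.tn, c.tn + c.fp),
        "true_sd_rate": rate(c.tp, c.tp + c.fn),
        "predicted_wr_rate": rate(c.tn, c.tn + c.fn),
        "predicted_sd_rate": rate(c.tp, c.tp + c.fp),
    }
    return out


def rates_pct(rates: dict, ndigits: int | None = None) -> dict:
    """Convert exact rates to float percentages (optionally rounded)."""
    out = {}
    for k, v in rates.items():
        if v is None:
            out[k] = None
        else:
            pct = float(v) * 100
            out[k] = round(pct, ndigits) if ndigits is not None else pct
    return out


def exact_binomial_ci(successes: int, n: int, conf: float = 0.95):
    """Clopper-Pearson exact interval from beta quantiles.

    At successes = n the lower bound is (alpha/2)**(1/n) and the upper is 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    alpha = 1 - conf
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc_pct: float
    ci95: tuple


def _delong_variance(scores, labels):
    """DeLong variance of the AUC estimator (midrank formulation)."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_scores)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # placement values of positives
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # placement values of negatives
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_auc(scores, labels, conf: float = 0.95, ci_method: str = "delong") -> RocCurve:
    """Empirical ROC curve with trapezoid AUC and a 95% CI.

    AUC equals the Mann-Whitney concordance probability.  The default CI is
    the DeLong asymptotic interval; ``ci_method='bootstrap'`` resamples
    (seeded) instead.
    """
    from sklearn.metrics import roc_curve as _sk_roc

    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, thr = _sk_roc(labels, scores)
    auc, var = _delong_variance(scores, labels)
    if ci_method == "delong":
        z = stats.norm.ppf(1 - (1 - conf) / 2)
        half = z * np.sqrt(var)
        ci = (max(0.0, auc - half) * 100, min(1.0, auc + half) * 100)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(0)
        reps = []
        idx = np.arange(len(labels))
        for _ in range(2000):
            b = rng.choice(idx, size=len(idx), replace=True)
            if len(np.unique(labels[b])) < 2:
                continue
            a, _v = _delong_variance(scores[b], labels[b])
            reps.append(a)
        lo, hi = np.percentile(reps, [(1 - conf) / 2 * 100, (1 + conf) / 2 * 100])
        ci = (lo * 100, hi * 100)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocCurve(thr, tpr, fpr, auc * 100, ci)


def sp_targeted_sensitivity(curve: RocCurve, sp_target: float = 0.85):
    """Sensitivity at the operating point with minimal sensitivity loss
    subject to specificity >= sp_target.

    Returns (threshold, sensitivity, achieved_specificity) as fractions, or
    None when no threshold reaches the target specificity.
    """
    spec = 1.0 - curve.fpr
    ok = spec >= sp_target
    if not ok.any():
        return None
    i = int(np.flatnonzero(ok)[np.argmax(curve.tpr[ok])])
    return float(curve.thresholds[i]), float(curve.tpr[i]), float(spec[i])


def percentile_abs_error(pred_h, actual_h, q=(50, 75, 90)):
    """Empirical percentiles (linear interpolation) of |pred - actual|."""
    pred = np.asarray(pred_h, dtype=float)
    actual = np.asarray(actual_h, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual must have equal length")
    err = np.abs(pred - actual)
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    return dict(zip([float(x) for x in qs], np.percentile(err, qs, method="linear")))


def r2_score_signed(actual, pred) -> float:
    """Test-set R^2 = 1 - SSE/SST (SST about the test mean); may be negative."""
    actual = np.asarray(actual, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sst = np.sum((actual - actual.mean()) ** 2)
    sse = np.sum((actual - pred) ** 2)
    return 1.0 - sse / sst if sst > 0 else np.nan


def rmse(actual, pred) -> float:
    actual = np.asarray(actual, dtype=float)
    pred = np.asarray(pred, dtype=float)
    return float(np.sqrt(np.mean((actual - pred) ** 2)))
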