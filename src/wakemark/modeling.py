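"""Hold-out random-forest classification and regression.

Classifiers separate well-rested (WR) from sleep-deprived (SD) samples
under configurable time-since-wake bin definitions; regressors predict
time-since-wake in hours.  Models are trained on one experiment and tested
on the other, with per-participant sub-reports, a threshold-scan over
narrowed WR/SD definitions, and an exhaustive candidate-combination scan
with Bonferroni-adjusted exact binomial significance against the
no-information rate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import evaluation as ev
from .forest import OobRandomForest

log = logging.getLogger(__name__)

WR, SD = "WR", "SD"


@dataclass
class ConditionDef:
    """Closed TSW intervals defining the WR and SD classes."""

    wr_range_h: tuple = (0.0, 16.0)
    sd_range_h: tuple = (24.0, 38.0)
    label: str = "0-16 vs. 24-38"

    def __post_init__(self) -> None:
        if not (self.wr_range_h[1] < self.sd_range_h[0] or self.sd_range_h[1] < self.wr_range_h[0]):
            raise ValueError("WR and SD ranges must not overlap")


#: the six stepwise-narrowed comparisons, ordered widest to narrowest WR/SD gap
TABLE3_CONDITIONS = [
    ConditionDef((0, 16), (22, 38), "0-16 vs. 22-38"),
    ConditionDef((0, 18), (24, 38), "0-18 vs. 24-38"),
    ConditionDef((0, 16), (20, 38), "0-16 vs. 20-38"),
    ConditionDef((0, 20), (24, 38), "0-20 vs. 24-38"),
    ConditionDef((0, 16), (18, 38), "0-16 vs. 18-38"),
    ConditionDef((0, 23), (24, 38), "0-23 vs. 24-38"),
]


@dataclass
class RfConfig:
    seed: int = 123
    mtry: int = 3
    ntree: int = 500
    nodesize_classification: int = 1
    nodesize_regression: int = 5


@dataclass
class ModelReport:
    role: str  # training | testing
    task: str  # classification | regression
    n: int = 0
    confusion: ev.ConfusionCounts | None = None
    accuracy_pct: float | None = None
    accuracy_ci_pct: tuple | None = None
    class_rates_pct: dict | None = None
    auc_pct: float | None = None
    auc_ci_pct: tuple | None = None
    r2_pct: float | None = None
    rmse_h: float | None = None
    percentile_error_h: dict | None = None
    importance: dict | None = None
    per_participant: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "role": self.role, "task": self.task, "n": self.n,
            "accuracy_pct": self.accuracy_pct,
            "accuracy_ci_pct": self.accuracy_ci_pct,
            "class_rates_pct": self.class_rates_pct,
            "auc_pct": self.auc_pct, "auc_ci_pct": self.auc_ci_pct,
            "r2_pct": self.r2_pct, "rmse_h": self.rmse_h,
            "percentile_error_h": self.percentile_error_h,
            "importance": self.importance,
        }
        if self.confusion is not None:
            c = self.confusion
            d["confusion"] = {"tn": c.tn, "fp": c.fp, "fn": c.fn, "tp": c.tp}
        if self.per_participant:
            d["per_participant"] = {k: v.to_dict() for k, v in self.per_participant.items()}
        return d


def assign_conditions(view, cond: ConditionDef, candidates=None):
    """Label samples WR/SD by closed-interval membership of TSW.

    Returns (X DataFrame over candidate features, y label array, sample
    metadata of the retained samples).  Out-of-range samples are dropped.
    """
    table = view.table if hasattr(view, "table") else view
    tsw = table.sample_meta["tsw_hours"]
    wr = (tsw >= cond.wr_range_h[0]) & (tsw <= cond.wr_range_h[1])
    sd = (tsw >= cond.sd_range_h[0]) & (tsw <= cond.sd_range_h[1])
    keep = wr | sd
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("%s: excluded %d samples outside both ranges", cond.label, n_dropped)
    y = np.where(wr[keep], WR, SD)
    if (y == WR).sum() == 0 or (y == SD).sum() == 0:
        raise ValueError(f"condition {cond.label!r} leaves an empty class")
    cols = list(candidates) if candidates is not None else list(table.intensities.columns)
    X = table.intensities.loc[keep.to_numpy(), cols]
    return X, y, table.sample_meta.loc[keep.to_numpy()]


def _confusion_from(y_true, y_pred) -> ev.ConfusionCounts:
    return ev.ConfusionCounts(
        tn=int(((y_true == WR) & (y_pred == WR)).sum()),
        fp=int(((y_true == WR) & (y_pred == SD)).sum()),
        fn=int(((y_true == SD) & (y_pred == WR)).sum()),
        tp=int(((y_true == SD) & (y_pred == SD)).sum()),
    )


def train_classifier(X, y, rf: RfConfig | None = None):
    """Train a classification forest; training accuracy = 1 - OOB error with
    an exact binomial CI on the OOB-correct counts; MDA importance."""
    rf = rf or RfConfig()
    model = OobRandomForest(
        task="classification", n_trees=rf.ntree, mtry=min(rf.mtry, X.shape[1]),
        min_samples_leaf=rf.nodesize_classification, seed=rf.seed,
    ).fit(np.asarray(X, dtype=float), np.asarray(y))
    ci = ev.exact_binomial_ci(model.oob_n_correct_, model.oob_n_)
    covered = model.oob_covered_
    y_arr = np.asarray(y)
    pred = model.classes_[np.maximum(model.oob_pred_, 0)]
    conf = _confusion_from(y_arr[covered], pred[covered])
    pos = int(np.flatnonzero(model.classes_ == SD)[0])
    oob_scores = model.oob_votes_[covered, pos] / model.oob_votes_[covered].sum(axis=1)
    curve = ev.roc_auc(oob_scores, (y_arr[covered] == SD).astype(int))
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"v{j}" for j in range(X.shape[1])]
    imp = dict(zip(names, model.permutation_importance() * 100))
    report = ModelReport(
        role="training", task="classification", n=model.oob_n_,
        confusion=conf,
        accuracy_pct=100 * model.oob_n_correct_ / model.oob_n_,
        accuracy_ci_pct=(ci[0] * 100, ci[1] * 100),
        class_rates_pct=ev.rates_pct(ev.confusion_rates(conf)),
        auc_pct=curve.auc_pct, auc_ci_pct=curve.ci95,
        importance=imp,
    )
    model.feature_names_ = names
    return model, report


def train_regressor(X, y_tsw, rf: RfConfig | None = None):
    """Train a regression forest; OOB R^2 / RMSE and %IncMSE importance."""
    rf = rf or RfConfig()
    model = OobRandomForest(
        task="regression", n_trees=rf.ntree, mtry=min(rf.mtry, X.shape[1]),
        min_samples_leaf=rf.nodesize_regression, seed=rf.seed,
    ).fit(np.asarray(X, dtype=float), np.asarray(y_tsw, dtype=float))
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"v{j}" for j in range(X.shape[1])]
    imp = dict(zip(names, model.permutation_importance()))
    report = ModelReport(
        role="training", task="regression", n=model.oob_n_,
        r2_pct=model.oob_r2_ * 100, rmse_h=float(np.sqrt(model.oob_mse_)),
        importance=imp,
    )
    model.feature_names_ = names
    return model, report


def _classification_report(model, X, y, meta, per_participant=True) -> ModelReport:
    pred = model.predict(np.asarray(X, dtype=float))
    scores = model.predict_score(np.asarray(X, dtype=float), positive_class=SD)
    conf = _confusion_from(np.asarray(y), pred)
    n_correct = conf.tn + conf.tp
    ci = ev.exact_binomial_ci(n_correct, conf.total)
    labels01 = (np.asarray(y) == SD).astype(int)
    auc_pct = auc_ci = None
    if len(np.unique(labels01)) == 2:
        curve = ev.roc_auc(scores, labels01)
        auc_pct, auc_ci = curve.auc_pct, curve.ci95
    rep = ModelReport(
        role="testing", task="classification", n=conf.total, confusion=conf,
        accuracy_pct=100 * n_correct / conf.total,
        accuracy_ci_pct=(ci[0] * 100, ci[1] * 100),
        class_rates_pct=ev.rates_pct(ev.confusion_rates(conf)),
        auc_pct=auc_pct, auc_ci_pct=auc_ci,
    )
    if per_participant:
        for pid, idx in meta.groupby("participant_id", sort=False).groups.items():
            loc = meta.index.get_indexer(idx)
            sub_y = np.asarray(y)[loc]
            if len(set(sub_y)) < 1 or len(sub_y) == 0:
                continue
            rep.per_participant[pid] = _classification_report(
                model, np.asarray(X)[loc], sub_y, meta.loc[idx], per_participant=False
            )
    return rep


def _regression_report(model, X, y, meta, per_participant=True) -> ModelReport:
    pred = model.predict(np.asarray(X, dtype=float))
    rep = ModelReport(
        role="testing", task="regression", n=len(pred),
        r2_pct=ev.r2_score_signed(y, pred) * 100,
        rmse_h=ev.rmse(y, pred),
        percentile_error_h=ev.percentile_abs_error(pred, y),
    )
    if per_participant:
        for pid, idx in meta.groupby("participant_id", sort=False).groups.items():
            loc = meta.index.get_indexer(idx)
            rep.per_participant[pid] = _regression_report(
                model, np.asarray(X)[loc], np.asarray(y)[loc], meta.loc[idx],
                per_participant=False,
            )
    return rep


def evaluate_holdout(model, test_view, cond: ConditionDef | None = None,
                     candidates=None, per_participant=True) -> ModelReport:
    """Evaluate a trained model on the held-out experiment.

    Classification models require a ConditionDef to label the test samples;
    regression models are scored against TSW.  Feature columns must match
    the training features.
    """
    table = test_view.table if hasattr(test_view, "table") else test_view
    cols = candidates if candidates is not None else getattr(model, "feature_names_", None)
    if cols is not None:
        missing = [c for c in cols if c not in table.intensities.columns]
        if missing:
            raise ValueError(f"test table lacks trained features: {missing[:5]}")
    if model.task == "classification":
        if cond is None:
            raise ValueError("classification evaluation requires a ConditionDef")
        X, y, meta = assign_conditions(table, cond, cols)
        return _classification_report(model, X, y, meta, per_participant)
    X = table.intensities.loc[:, cols] if cols is not None else table.intensities
    y = table.sample_meta["tsw_hours"].to_numpy(dtype=float)
    return _regression_report(model, X, y, table.sample_meta, per_participant)


def train_and_test(train_view, test_view, candidates, cond: ConditionDef,
                   rf: RfConfig | None = None):
    """One full train/test cycle for a WR/SD condition definition."""
    Xtr, ytr, _ = assign_conditions(train_view, cond, candidates)
    model, train_rep = train_classifier(Xtr, ytr, rf)
    test_rep = evaluate_holdout(model, test_view, cond, candidates)
    return model, train_rep, test_rep


def threshold_scan(train_view, test_view, candidates,
                   conditions=None, rf: RfConfig | None = None) -> pd.DataFrame:
    """Re-train and re-test under each WR/SD definition; one row each.

    Failures (e.g. an empty class) are flagged in the ``error`` column and
    do not abort the scan.
    """
    conditions = conditions if conditions is not None else TABLE3_CONDITIONS
    rows = []
    for cond in conditions:
        row = {"label": cond.label, "wr_range": cond.wr_range_h, "sd_range": cond.sd_range_h,
               "error": None}
        try:
            _, train_rep, test_rep = train_and_test(train_view, test_view, candidates, cond, rf)
            row.update(
                n_test=test_rep.n,
                accuracy_pct=test_rep.accuracy_pct,
                accuracy_ci_pct=test_rep.accuracy_ci_pct,
                auc_pct=test_rep.auc_pct,
                train_accuracy_pct=train_rep.accuracy_pct,
            )
            n_wr = test_rep.confusion.tn + test_rep.confusion.fp
            n_sd = test_rep.confusion.tp + test_rep.confusion.fn
            row["balanced"] = abs(n_wr - n_sd) <= 0.2 * (n_wr + n_sd)
        except (ValueError, KeyError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def no_information_rate(y) -> float:
    """Majority-class proportion of the evaluated subset."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    return counts.max() / counts.sum()


def combo_scan(train_view, test_view, candidates, cond: ConditionDef | None = None,
               rf: RfConfig | None = None, k_min: int = 2) -> pd.DataFrame:
    """Train/test every candidate subset of size >= k_min.

    Significance per combination is a one-sided exact binomial test of the
    test accuracy against the no-information rate, Bonferroni-corrected
    across the number of combinations; mtry is capped at the subset size.
    """
    if len(candidates) < 2:
        raise ValueError("combo_scan requires >= 2 candidates")
    cond = cond or ConditionDef()
    rf = rf or RfConfig()
    combos = [
        c for k in range(k_min, len(candidates) + 1)
        for c in itertools.combinations(candidates, k)
    ]
    n_combos = len(combos)
    rows = []
    for combo in combos:
        _, train_rep, test_rep = train_and_test(train_view, test_view, list(combo), cond, rf)
        conf = test_rep.confusion
        _, ytest, _ = assign_conditions(test_view, cond, list(combo))
        nir = no_information_rate(ytest)
        p = stats.binomtest(conf.tn + conf.tp, conf.total, nir, alternative="greater").pvalue
        rows.append(
            {
                "combo": "+".join(combo), "size": len(combo),
                "accuracy_pct": test_rep.accuracy_pct,
                "auc_pct": test_rep.auc_pct,
                "nir_pct": nir * 100,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * n_combos),
            }
        )
    return pd.DataFrame(rows)
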