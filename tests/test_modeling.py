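"""Hold-out modeling: condition assignment boundaries, training = 1-OOB,
combination counts, determinism, and per-participant reports."""

import numpy as np
import pandas as pd
import pytest

from wakemark.modeling import (
    ConditionDef,
    RfConfig,
    assign_conditions,
    combo_scan,
    evaluate_holdout,
    no_information_rate,
    threshold_scan,
    train_and_test,
    train_classifier,
    train_regressor,
)
from wakemark.preprocess import PreprocessConfig, prepare_views

from conftest import make_table

FAST_RF = RfConfig(ntree=100)


class TestAssignConditions:
    def test_closed_interval_boundaries(self):
        t = make_table(
            np.ones((4, 2)), participants=["A"] * 4, tsw=[16.0, 18.0, 24.0, 38.0]
        )
        X, y, meta = assign_conditions(t, ConditionDef())
        # 16 -> WR (closed), 18 -> excluded, 24 and 38 -> SD
        assert list(meta["tsw_hours"]) == [16.0, 24.0, 38.0]
        assert list(y) == ["WR", "SD", "SD"]

    def test_complete_participant_has_8_per_class(self):
        tsw = list(np.arange(2.0, 40.0, 2.0))
        t = make_table(np.ones((19, 1)), participants=["A"] * 19, tsw=tsw)
        _, y, _ = assign_conditions(t, ConditionDef())
        assert (y == "WR").sum() == 8 and (y == "SD").sum() == 8

    def test_empty_class_rejected(self):
        t = make_table(np.ones((3, 1)), participants=["A"] * 3, tsw=[2, 4, 6])
        with pytest.raises(ValueError):
            assign_conditions(t, ConditionDef())

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            ConditionDef((0, 24), (24, 38))


class TestTraining:
    def _sep_data(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n),
                          "c": rng.normal(size=n)})
        y = np.where(X["a"] > 0, "SD", "WR")
        X["a"] += np.where(y == "SD", 2.0, -2.0)  # fully separated
        return X, y

    def test_separated_classes_high_oob_accuracy(self):
        X, y = self._sep_data()
        _, rep = train_classifier(X, y, FAST_RF)
        assert rep.accuracy_pct >= 99.0
        assert rep.accuracy_ci_pct[0] <= rep.accuracy_pct <= rep.accuracy_ci_pct[1]
        assert rep.confusion.total == rep.n

    def test_permuted_labels_near_chance(self):
        X, y = self._sep_data()
        rng = np.random.default_rng(1)
        yp = rng.permutation(y)
        _, rep = train_classifier(X, yp, FAST_RF)
        nir = no_information_rate(yp) * 100
        lo, hi = rep.accuracy_ci_pct
        assert lo <= nir + 10  # chance-level within/near the CI

    def test_same_seed_identical_predictions(self):
        X, y = self._sep_data()
        m1, _ = train_classifier(X, y, RfConfig(ntree=50, seed=123))
        m2, _ = train_classifier(X, y, RfConfig(ntree=50, seed=123))
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_regressor_noiseless_monotone_signal(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 300), "b": rng.normal(size=300)})
        y = 38 * X["a"].to_numpy()
        _, rep = train_regressor(X, y, FAST_RF)
        assert rep.r2_pct >= 95.0

    def test_regressor_null_signal_nonpositive_r2(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
        y = rng.normal(size=150)
        _, rep = train_regressor(X, y, FAST_RF)
        assert rep.r2_pct <= 5.0


class TestHoldout:
    def test_holdout_on_strong_synthetic_signal(self, candidate_study):
        exp1, exp2, _ = candidate_study
        v1 = prepare_views(exp1, PreprocessConfig(imputation_seed=5))
        v2 = prepare_views(exp2, PreprocessConfig(imputation_seed=6),
                           feature_subset=v1["within"].table.feature_ids)
        cands = [f for f in exp1.feature_ids
                 if exp1.feature_meta.loc[f, "true_class"] == "linear"]
        model, train_rep, test_rep = train_and_test(
            v1["within"], v2["within"], cands, ConditionDef(), FAST_RF
        )
        assert test_rep.accuracy_pct >= 90.0
        assert test_rep.auc_pct >= 95.0
        # per-participant reports cover every test participant
        assert set(test_rep.per_participant) == set(
            v2["within"].table.sample_meta["participant_id"]
        )
        # confusion trace equals accuracy exactly
        c = test_rep.confusion
        assert test_rep.accuracy_pct == pytest.approx(100 * (c.tn + c.tp) / c.total)

    def test_feature_mismatch_rejected(self, candidate_study):
        exp1, exp2, _ = candidate_study
        v1 = prepare_views(exp1, PreprocessConfig(imputation_seed=5))
        v2 = prepare_views(exp2, PreprocessConfig(imputation_seed=6),
                           feature_subset=v1["within"].table.feature_ids)
        X, y, _ = assign_conditions(v1["within"], ConditionDef(), ["F0001"])
        model, _ = train_classifier(X, y, FAST_RF)
        model.feature_names_ = ["not_a_feature"]
        with pytest.raises(ValueError, match="lacks"):
            evaluate_holdout(model, v2["within"], ConditionDef())


class TestScans:
    def test_threshold_scan_row_per_condition(self, candidate_study):
        exp1, exp2, _ = candidate_study
        v1 = prepare_views(exp1, PreprocessConfig(imputation_seed=5))
        v2 = prepare_views(exp2, PreprocessConfig(imputation_seed=6),
                           feature_subset=v1["within"].table.feature_ids)
        cands = [f for f in exp1.feature_ids
                 if exp1.feature_meta.loc[f, "true_class"] == "linear"][:3]
        conds = [ConditionDef((0, 16), (24, 38), "wide"),
                 ConditionDef((0, 23), (24, 38), "narrow"),
                 ConditionDef((0, 1), (39, 40), "degenerate")]
        scan = threshold_scan(v1["within"], v2["within"], cands, conds, FAST_RF)
        assert list(scan["label"]) == ["wide", "narrow", "degenerate"]
        assert scan.loc[2, "error"] is not None  # degenerate flagged
        assert scan.loc[[0, 1], "accuracy_pct"].notna().all()  # others unaffected

    def test_combo_counts(self):
        # C(5,2..5) = 26 and C(3,2..3) = 4
        from itertools import combinations
        assert sum(len(list(combinations(range(5), k))) for k in range(2, 6)) == 26
        rng = np.random.default_rng(4)
        n = 80
        z = np.repeat([0, 1], n // 2)
        t_train = make_table(
            np.column_stack([z * 3 + rng.normal(size=n) for _ in range(3)]),
            participants=["A"] * n, tsw=np.where(z == 1, 30.0, 10.0),
            feature_ids=["x", "y", "w"],
        )
        t_test = make_table(
            np.column_stack([z * 3 + rng.normal(size=n) for _ in range(3)]),
            participants=["B"] * n, tsw=np.where(z == 1, 30.0, 10.0),
            feature_ids=["x", "y", "w"],
        )
        scan = combo_scan(t_train, t_test, ["x", "y", "w"], rf=RfConfig(ntree=50))
        assert len(scan) == 4
        assert (scan["p_bonferroni"] >= scan["p_raw"] - 1e-12).all()
        assert (scan["p_bonferroni"] <= 1.0).all()

    def test_no_information_rate_majority_class(self):
        assert no_information_rate(["a", "a", "b"]) == pytest.approx(2 / 3)
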