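"""End-to-end discovery and recovery orchestration.

``run_discovery`` executes preprocess -> characterize -> a priori filter ->
three-stage selection (classification & regression on the within and
between views) -> consensus -> hold-out modeling, and returns a manifest
(counts after every stage, all reports, resolved configuration, seeds, and
a checksum) sufficient to reproduce the run.  Hold-out hygiene: the test
experiment is preprocessed independently and contributes nothing to
filtering, selection, or training.  ``run_recovery`` produces the pre/post
sleep contrast tables for both block designs plus the meal-timing
comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import recovery as rec
from .apriori import FilterConfig, apply_filter, passed_features
from .modeling import (
    TABLE3_CONDITIONS, ConditionDef, RfConfig, assign_conditions,
    evaluate_holdout, threshold_scan, train_classifier, train_regressor,
)
from .preprocess import PreprocessConfig, prepare_views
from .trends import characterize
from .vsurf import VsurfConfig, consensus_candidates, run_vsurf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    train_experiment_id: str = "exp1"
    test_experiment_id: str = "exp2"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    vsurf: VsurfConfig = field(default_factory=VsurfConfig)
    rf: RfConfig = field(default_factory=RfConfig)
    condition: ConditionDef = field(default_factory=ConditionDef)
    scan_conditions: list = field(default_factory=lambda: list(TABLE3_CONDITIONS))
    n_candidates: int = 5
    run_threshold_scan: bool = False

    def __post_init__(self) -> None:
        if self.train_experiment_id == self.test_experiment_id:
            raise ValueError("train and test experiments must differ")


def _checksum(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_discovery(train_table, test_table, config: RunConfig | None = None) -> dict:
    """Full biomarker-discovery pipeline on a train/test experiment pair."""
    config = config or RunConfig()
    manifest = {
        "train_experiment": config.train_experiment_id,
        "test_experiment": config.test_experiment_id,
        "counts": {"features_initial": train_table.n_features,
                   "train_samples": train_table.n_samples,
                   "test_samples": test_table.n_samples},
        "config": {
            "preprocess": asdict(config.preprocess),
            "filter": asdict(config.filter),
            "vsurf": asdict(config.vsurf),
            "rf": asdict(config.rf),
        },
    }

    views_train = prepare_views(train_table, config.preprocess)
    # the test experiment adopts the training side's feature universe
    # (train->test direction only; no test statistic feeds back)
    views_test = prepare_views(
        test_table, config.preprocess,
        feature_subset=views_train["within"].table.feature_ids,
    )
    manifest["counts"]["features_after_zero_filter"] = views_train["within"].table.n_features
    log.info("zero filter: %d -> %d features", train_table.n_features,
             views_train["within"].table.n_features)

    ind = characterize(views_train["within"], level="individual")
    grp = characterize(views_train["within"], level="group")
    filter_report = apply_filter(ind, grp, config.filter)
    filtered = passed_features(filter_report)
    manifest["counts"]["features_after_apriori_filter"] = len(filtered)
    log.info("a priori filter: %d candidates", len(filtered))
    if not filtered:
        raise RuntimeError("a priori filter left no candidate features")

    # common feature universe for both views (test may lack features dropped
    # by its own zero filter; selection/training use train-side features only)
    selection_results = {}
    for view_kind in ("within", "between"):
        view = views_train[view_kind]
        Xc, yc, _ = assign_conditions(view, config.condition, filtered)
        vs_cfg_c = _vsurf_for(config.vsurf, "classification")
        selection_results[f"classification_{view_kind}"] = run_vsurf(Xc, yc, vs_cfg_c)
        Xr = view.table.intensities.loc[:, filtered]
        yr = view.table.sample_meta["tsw_hours"].to_numpy(dtype=float)
        vs_cfg_r = _vsurf_for(config.vsurf, "regression")
        selection_results[f"regression_{view_kind}"] = run_vsurf(Xr, yr, vs_cfg_r)
    candidates = consensus_candidates(
        list(selection_results.values()), target_size=config.n_candidates
    )
    manifest["counts"]["final_candidates"] = len(candidates)
    manifest["candidates"] = candidates
    manifest["selection"] = {k: v.to_dict() for k, v in selection_results.items()}
    log.info("consensus candidates: %s", candidates)

    model_reports = {}
    for view_kind in ("within", "between"):
        tr_view, te_view = views_train[view_kind], views_test[view_kind]
        Xc, yc, _ = assign_conditions(tr_view, config.condition, candidates)
        clf, clf_train = train_classifier(Xc, yc, config.rf)
        clf_test = evaluate_holdout(clf, te_view, config.condition, candidates)
        Xr = tr_view.table.intensities.loc[:, candidates]
        yr = tr_view.table.sample_meta["tsw_hours"].to_numpy(dtype=float)
        reg, reg_train = train_regressor(Xr, yr, config.rf)
        reg_test = evaluate_holdout(reg, te_view, candidates=candidates)
        model_reports[f"classification_{view_kind}"] = {
            "training": clf_train.to_dict(), "testing": clf_test.to_dict()}
        model_reports[f"regression_{view_kind}"] = {
            "training": reg_train.to_dict(), "testing": reg_test.to_dict()}
    manifest["models"] = model_reports

    if config.run_threshold_scan:
        scan = threshold_scan(views_train["within"], views_test["within"],
                              candidates, config.scan_conditions, config.rf)
        manifest["threshold_scan"] = scan.to_dict(orient="records")

    manifest["filter_report_summary"] = {
        "passed": int(filter_report["passed"].sum()),
        "failed": int((~filter_report["passed"].astype(bool)).sum()),
    }
    manifest["checksum"] = _checksum(manifest)
    manifest["_filter_report"] = filter_report
    manifest["_views_train"] = views_train
    manifest["_views_test"] = views_test
    return manifest


def _vsurf_for(cfg: VsurfConfig, task: str) -> VsurfConfig:
    from dataclasses import replace

    return replace(cfg, task=task)


def run_recovery(sleepdep_tables: dict, control_table, candidates,
                 preprocess_cfg: PreprocessConfig | None = None) -> dict:
    """Pre/post-sleep contrasts for both block designs plus meal comparison.

    *sleepdep_tables* maps protocol labels to raw sleep-deprivation
    FeatureTables; *control_table* is the raw matched-control table.  All
    tables are preprocessed to the within (z-scored) view here.
    """
    if not candidates:
        raise ValueError("candidates list must not be empty")
    preprocess_cfg = preprocess_cfg or PreprocessConfig(max_zero_fraction=0.999)
    z_tables = {}
    for label, tab in {**sleepdep_tables, "matched_control": control_table}.items():
        views = prepare_views(tab, preprocess_cfg)
        z = views["within"].table
        missing = [c for c in candidates if c not in z.intensities.columns]
        if missing:
            raise ValueError(f"candidates missing from {label!r}: {missing}")
        z_tables[label] = z
    out = {}
    for design in (rec.PrePostDesign.clock_matched(), rec.PrePostDesign.evening_morning()):
        stacked = rec.build_pre_post(z_tables, design, candidates)
        out[design.design_kind] = rec.fit_prepost_model(stacked)

    # meal-timing: control sampling day vs the clock-matched WR span of one
    # sleep-deprivation experiment (first listed).  Both subsets are
    # z-scored across the compared day only — z-scores taken over the full
    # 38-h wake span would mechanically compress the sleep-deprivation
    # slope and manufacture a spurious protocol interaction.
    sd_label = next(iter(sleepdep_tables))
    sd_raw = sleepdep_tables[sd_label]
    wr_mask = sd_raw.sample_meta["tsw_hours"] <= 16
    ctrl_mask = control_table.sample_meta["day_index"] == 3
    sd_day = prepare_views(sd_raw.select_samples(wr_mask.to_numpy()), preprocess_cfg)
    ctrl_day = prepare_views(control_table.select_samples(ctrl_mask.to_numpy()), preprocess_cfg)
    out["meal_timing"] = rec.meal_timing_comparison(
        ctrl_day["within"].table, sd_day["within"].table, candidates
    )
    return out
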