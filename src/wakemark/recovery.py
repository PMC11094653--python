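"""Recovery-after-sleep validation of biomarker candidates.

Compares candidate z-scores in a 4-h block before vs after the habitual
sleep interval: in the sleep-deprivation experiments (no sleep occurs) a
homeostatic biomarker keeps drifting, while in the matched control the
nightly sleep resets it, so the pre/post contrast should be opposite or
null.  Contrasts are fit per (metabolite, protocol) with a linear mixed
model (random participant intercept) and FDR-adjusted within each design.
A meal-timing comparison tests whether candidate trends across a
well-rested day differ between the hourly-snack (constant routine) and
three-meal (constant posture) protocols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests


@dataclass
class PrePostDesign:
    design_kind: str
    sd_pre: tuple
    sd_post: tuple
    ctrl_pre: tuple  # (day_index, (lo, hi))
    ctrl_post: tuple

    @classmethod
    def clock_matched(cls) -> "PrePostDesign":
        return cls("clock_matched", (2, 6), (26, 30), (2, (2, 6)), (3, (2, 6)))

    @classmethod
    def evening_morning(cls) -> "PrePostDesign":
        return cls("evening_morning", (12, 16), (26, 30), (2, (12, 16)), (3, (2, 6)))


def _block_mask(meta, tsw_range, day=None):
    tsw = meta["tsw_hours"]
    mask = (tsw >= tsw_range[0]) & (tsw <= tsw_range[1])
    if day is not None:
        mask &= meta["day_index"] == day
    return mask


def build_pre_post(tables: dict, design: PrePostDesign, candidates) -> pd.DataFrame:
    """Stack pre/post block samples into a long table.

    *tables* maps protocol label -> z-scored FeatureTable.  Sleep-deprivation
    protocols use the TSW intervals directly; matched-control protocols use
    (day, TSW) blocks.  Columns of the result: metabolite, protocol,
    participant, period (pre|post), value_z.
    """
    rows = []
    for proto, table in tables.items():
        meta = table.sample_meta
        is_control = (meta["protocol_kind"] == "matched_control").all()
        if is_control:
            masks = {
                "pre": _block_mask(meta, design.ctrl_pre[1], design.ctrl_pre[0]),
                "post": _block_mask(meta, design.ctrl_post[1], design.ctrl_post[0]),
            }
        else:
            masks = {
                "pre": _block_mask(meta, design.sd_pre),
                "post": _block_mask(meta, design.sd_post),
            }
        for period, mask in masks.items():
            if not mask.any():
                raise ValueError(f"empty {period!r} block for protocol {proto!r}")
            sub = table.intensities.loc[mask.to_numpy(), list(candidates)]
            for met in candidates:
                rows.append(
                    pd.DataFrame(
                        {
                            "metabolite": met,
                            "protocol": proto,
                            "participant": meta.loc[mask.to_numpy(), "participant_id"].to_numpy(),
                            "period": period,
                            "value_z": sub[met].to_numpy(),
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def _fit_one(sub: pd.DataFrame):
    """Mixed model value_z ~ period (random participant intercept).

    Returns (estimate post-pre, df, t_ratio, p).  Falls back to a paired
    t-test on participant means when the mixed fit is singular.
    """
    post = (sub["period"] == "post").astype(float).to_numpy()
    exog = np.column_stack([np.ones(len(sub)), post])
    n_groups = sub["participant"].nunique()
    df = len(sub) - n_groups - 1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM(sub["value_z"].to_numpy(), exog, groups=sub["participant"]).fit(reml=True)
        est = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(se) or se == 0:
            raise ValueError("singular mixed fit")
        t_ratio = est / se
        p = 2 * stats.t.sf(abs(t_ratio), df)
        return est, float(df), t_ratio, float(p)
    except (ValueError, np.linalg.LinAlgError):
        means = sub.pivot_table(index="participant", columns="period", values="value_z")
        res = stats.ttest_rel(means["post"], means["pre"])
        est = float((means["post"] - means["pre"]).mean())
        return est, float(len(means) - 1), float(res.statistic), float(res.pvalue)


def fit_prepost_model(stacked: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per (metabolite, protocol) post-pre contrast with FDR across all
    tests of the design.  Columns: estimate, df, t_ratio, p_raw, p_fdr,
    trend in {increasing, decreasing, not_significant}."""
    if stacked["participant"].nunique() < 2:
        raise ValueError("pre/post contrasts require >= 2 participants")
    rows = []
    for (met, proto), sub in stacked.groupby(["metabolite", "protocol"], sort=False):
        est, df, t_ratio, p = _fit_one(sub)
        rows.append(
            {"metabolite": met, "protocol": proto, "estimate": est,
             "df": df, "t_ratio": t_ratio, "p_raw": p}
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    out["trend"] = np.where(
        out["p_fdr"] >= alpha, "not_significant",
        np.where(out["estimate"] > 0, "increasing", "decreasing"),
    )
    return out


def meal_timing_comparison(control_day: "FeatureTable", sleepdep_day: "FeatureTable",
                           candidates) -> pd.DataFrame:
    """Interaction test of TSW slope x protocol (meal schedule).

    Both tables must be z-scored across the compared well-rested day.
    Fits value_z ~ tsw * protocol with a random participant intercept; a
    large interaction p means the wake trend is not protocol-dependent.
    """
    frames = []
    for label, table in (("control", control_day), ("sleep_deprivation", sleepdep_day)):
        meta = table.sample_meta
        for met in candidates:
            frames.append(
                pd.DataFrame(
                    {
                        "metabolite": met,
                        "protocol_flag": 1.0 if label == "control" else 0.0,
                        "participant": meta["participant_id"].to_numpy(),
                        "tsw": meta["tsw_hours"].to_numpy(dtype=float),
                        "value_z": table.intensities[met].to_numpy(),
                    }
                )
            )
    data = pd.concat(frames, ignore_index=True)
    rows = []
    for met, sub in data.groupby("metabolite", sort=False):
        exog = np.column_stack(
            [np.ones(len(sub)), sub["tsw"], sub["protocol_flag"],
             sub["tsw"] * sub["protocol_flag"]]
        )
        df = len(sub) - sub["participant"].nunique() - 3
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = MixedLM(sub["value_z"].to_numpy(), exog, groups=sub["participant"]).fit(reml=True)
            est = float(fit.params[3])
            se = float(fit.bse[3])
            t_ratio = est / se if se > 0 else 0.0
            p = 2 * stats.t.sf(abs(t_ratio), df) if se > 0 else 1.0
        except (ValueError, np.linalg.LinAlgError):
            est, t_ratio, p = 0.0, 0.0, 1.0
        rows.append(
            {"metabolite": met, "interaction_estimate": est,
             "t_ratio": t_ratio, "p_interaction": p}
        )
    return pd.DataFrame(rows)
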