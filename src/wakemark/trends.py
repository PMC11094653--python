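"""Linear and 24-h cosinor trend screening.

Every feature is fit, per participant and at the group level, with

* an ordinary least squares line in time-since-wake (homeostatic trend), and
* a cosinor model ``y ~ 1 + cos(2*pi*t/24) + sin(2*pi*t/24)`` (circadian
  trend), amplitude = norm of the two harmonic coefficients, acrophase =
  peak clock time, significance = joint F-test of both coefficients.

Benjamini-Hochberg adjustment is applied across features separately for the
linear and cosinor families, and features are categorized as increasing,
decreasing, and/or cycling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUP = "group"


@dataclass
class LinearFit:
    slope: float
    intercept: float
    p_value: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.slope))


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_h: float
    p_value: float
    period_h: float = 24.0


@dataclass
class TrendCatalog:
    """Per-feature (x per-participant) fit results and category flags.

    ``entries`` is tidy: one row per (feature, participant-or-'group') with
    slope, p_lin, q_lin, mesor, amplitude, acrophase, p_cos, q_cos.
    ``categories`` is one row per feature with boolean flags
    increasing / decreasing / cycling.
    """

    level: str
    entries: pd.DataFrame
    categories: pd.DataFrame
    alpha: float = 0.05


def _ols_multi(X, Y):
    """OLS of every column of Y on design X; returns beta, rss, XtX_inv, tss."""
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    tss = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))
    return beta, rss, XtX_inv, tss


def _linear_multi(times, Y):
    """Vectorized line fits: slope, intercept, two-sided t-test p per column."""
    n = len(times)
    X = np.column_stack([np.ones(n), times])
    beta, rss, XtX_inv, tss = _ols_multi(X, Y)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / df
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        t = beta[1] / se
        p = 2 * stats.t.sf(np.abs(t), df)
    slope = beta[1]
    # degenerate cases: constant series carry no trend; an exact nonzero
    # line is maximally significant
    constant = tss == 0
    slope = np.where(constant, 0.0, slope)
    p = np.where(constant, 1.0, p)
    exact = ~np.isfinite(p) & ~constant
    p = np.where(exact, np.where(np.abs(slope) > 0, 0.0, 1.0), p)
    return slope, beta[0], p


def _cosinor_multi(times, Y, period=24.0):
    """Vectorized cosinor fits: mesor, amplitude, acrophase, joint-F p."""
    n = len(times)
    w = 2 * np.pi / period
    X = np.column_stack([np.ones(n), np.cos(w * times), np.sin(w * times)])
    beta, rss, _, tss = _ols_multi(X, Y)
    df = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((tss - rss) / 2) / (rss / df)
        p = stats.f.sf(F, 2, df)
    amplitude = np.hypot(beta[1], beta[2])
    acrophase = (np.arctan2(beta[2], beta[1]) / w) % period
    constant = tss == 0
    amplitude = np.where(constant, 0.0, amplitude)
    p = np.where(constant, 1.0, p)
    exact = ~np.isfinite(p) & ~constant
    p = np.where(exact, np.where(amplitude > 1e-12, 0.0, 1.0), p)
    return beta[0], amplitude, acrophase, p


def fit_linear(values, times_h) -> LinearFit:
    """OLS of value on time with exact t-test for the slope."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times_h, dtype=float)
    if len(np.unique(times)) < 3:
        raise ValueError("fit_linear requires >= 3 distinct times")
    slope, intercept, p = _linear_multi(times, values[:, None])
    return LinearFit(float(slope[0]), float(intercept[0]), float(p[0]))


def fit_cosinor(values, times_h, period_h: float = 24.0) -> CosinorFit:
    """Fixed-period cosinor fit; p-value from the joint F-test of both
    harmonic coefficients."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times_h, dtype=float)
    uniq = np.unique(times)
    if len(uniq) < 4 or (uniq.max() - uniq.min()) <= period_h / 2:
        raise ValueError(
            "fit_cosinor requires >= 4 distinct times spanning more than half a period"
        )
    mesor, amp, acro, p = _cosinor_multi(times, values[:, None], period_h)
    return CosinorFit(float(mesor[0]), float(amp[0]), float(acro[0]), float(p[0]), period_h)


def _bh(p):
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def characterize(view, level: str = GROUP, alpha: float = 0.05) -> TrendCatalog:
    """Fit both trend models for every feature of a prepared data view.

    level='group' pools all samples; level='individual' fits each
    participant separately.  FDR (Benjamini-Hochberg) is applied across
    features, separately for the linear and cosinor families (and, at the
    individual level, separately within each participant).

    Group categories use FDR-adjusted q < alpha.  Individual-level
    categories follow the majority rule: a feature is flagged when more
    than half the participants show a raw-significant trend with a
    consistent direction (linear) or a raw-significant amplitude (cycling).
    """
    table = view.table if hasattr(view, "table") else view
    inten = table.intensities
    meta = table.sample_meta
    feats = list(inten.columns)

    def fit_block(sub_inten, sub_times, who):
        Y = sub_inten.to_numpy(dtype=float)
        slope, intercept, p_lin = _linear_multi(sub_times, Y)
        mesor, amp, acro, p_cos = _cosinor_multi(sub_times, Y)
        return pd.DataFrame(
            {
                "feature_id": feats,
                "participant_id": who,
                "slope": slope,
                "intercept": intercept,
                "p_lin": p_lin,
                "q_lin": _bh(p_lin),
                "mesor": mesor,
                "amplitude": amp,
                "acrophase_h": acro,
                "p_cos": p_cos,
                "q_cos": _bh(p_cos),
            }
        )

    times_all = meta["tsw_hours"].to_numpy(dtype=float)
    if level == GROUP:
        entries = fit_block(inten, times_all, GROUP)
        sig_lin = entries["q_lin"] < alpha
        categories = pd.DataFrame(
            {
                "increasing": (sig_lin & (entries["slope"] > 0)).to_numpy(),
                "decreasing": (sig_lin & (entries["slope"] < 0)).to_numpy(),
                "cycling": (entries["q_cos"] < alpha).to_numpy(),
            },
            index=pd.Index(feats, name="feature_id"),
        )
    elif level == "individual":
        blocks = []
        for pid, idx in meta.groupby("participant_id", sort=False).groups.items():
            sub = inten.loc[idx]
            blocks.append(fit_block(sub, meta.loc[idx, "tsw_hours"].to_numpy(float), pid))
        entries = pd.concat(blocks, ignore_index=True)
        n_part = entries["participant_id"].nunique()
        by_feat = entries.groupby("feature_id", sort=False)
        frac_up = by_feat.apply(
            lambda g: ((g["p_lin"] < alpha) & (g["slope"] > 0)).sum() / n_part,
            include_groups=False,
        )
        frac_dn = by_feat.apply(
            lambda g: ((g["p_lin"] < alpha) & (g["slope"] < 0)).sum() / n_part,
            include_groups=False,
        )
        frac_cyc = by_feat.apply(
            lambda g: (g["p_cos"] < alpha).sum() / n_part, include_groups=False
        )
        categories = pd.DataFrame(
            {
                "increasing": (frac_up > 0.5).reindex(feats).to_numpy(),
                "decreasing": (frac_dn > 0.5).reindex(feats).to_numpy(),
                "cycling": (frac_cyc > 0.5).reindex(feats).to_numpy(),
            },
            index=pd.Index(feats, name="feature_id"),
        )
    else:
        raise ValueError(f"unknown level {level!r}")
    return TrendCatalog(level, entries, categories, alpha)


CATEGORY_BINS = [
    "linear_only_increasing",
    "linear_only_decreasing",
    "cycling_only",
    "cycling_and_linear",
    "neither",
]


def category_counts(catalog: TrendCatalog) -> pd.Series:
    """Mutually exclusive category bins used for between-experiment comparison."""
    c = catalog.categories
    lin = c["increasing"] | c["decreasing"]
    bins = pd.Series(0, index=CATEGORY_BINS, dtype=int)
    bins["linear_only_increasing"] = int((c["increasing"] & ~c["cycling"]).sum())
    bins["linear_only_decreasing"] = int((c["decreasing"] & ~c["cycling"]).sum())
    bins["cycling_only"] = int((c["cycling"] & ~lin).sum())
    bins["cycling_and_linear"] = int((c["cycling"] & lin).sum())
    bins["neither"] = int((~c["cycling"] & ~lin).sum())
    return bins


def compare_experiments(catalog_a: TrendCatalog, catalog_b: TrendCatalog):
    """Pearson chi-square on the 2 x bins contingency table of category
    counts from two experiments.  Returns (statistic, df, p)."""
    if set(catalog_a.categories.index) != set(catalog_b.categories.index):
        raise ValueError("catalogs must categorize the same feature universe")
    obs = np.vstack([category_counts(catalog_a).to_numpy(), category_counts(catalog_b).to_numpy()])
    nonzero = obs.sum(axis=0) > 0
    obs = obs[:, nonzero]
    if obs.shape[1] < 2:
        return 0.0, 0, 1.0
    stat, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if (expected < 1).any():
        warnings.warn("chi-square expected cell count < 1; statistic may be unstable")
    if stat == 0:
        p = 1.0
    return float(stat), int(df), float(p)
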