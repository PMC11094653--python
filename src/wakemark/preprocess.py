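"""Feature-table cleaning and normalization.

Produces the two data views used downstream:

* **between** view - zero-value feature filtering, left-censored imputation,
  and within-sample median normalization; intensities stay on the raw
  (nonnegative) relative-peak-area scale.
* **within** view - the between view followed by per-participant z-scoring
  of every feature across that participant's time points, removing
  between-participant location/scale differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .table import FeatureTable

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    max_zero_fraction: float = 0.20
    imputation: str = "truncated_normal_qr"  # or "half_min"
    imputation_seed: int = 0
    views: tuple = ("between", "within")

    def __post_init__(self) -> None:
        if not 0 <= self.max_zero_fraction < 1:
            raise ValueError("max_zero_fraction must be in [0, 1)")
        if self.imputation not in ("truncated_normal_qr", "half_min"):
            raise ValueError(f"unknown imputation {self.imputation!r}")


@dataclass
class DataView:
    view_kind: str
    table: FeatureTable
    provenance: list = field(default_factory=list)


def filter_zero_features(table: FeatureTable, max_zero_fraction: float = 0.20):
    """Drop features whose zero fraction strictly exceeds *max_zero_fraction*.

    Returns (filtered table, list of dropped feature ids).  Feature order is
    preserved.  A feature at exactly the threshold is retained (the rule is
    strict ``>``).
    """
    if table.n_samples == 0 or table.n_features == 0:
        raise ValueError("cannot filter an empty table")
    zero_frac = (table.intensities == 0).mean(axis=0)
    dropped = list(zero_frac.index[zero_frac > max_zero_fraction])
    kept = [f for f in table.feature_ids if f not in set(dropped)]
    if not kept:
        raise ValueError("no features survive the zero-value filter")
    return table.select_features(kept), dropped


def _qr_truncnorm_params(obs, censored_fraction):
    """Quantile-match a normal to observed (left-truncated) values.

    Treats observed nonzero values as the upper (1 - c) tail of a normal and
    matches the censoring point and the observed median:
    ``min_obs = mu + sigma * z(c)``, ``median_obs = mu + sigma * z(c + (1-c)/2)``.
    """
    c = censored_fraction
    m = float(np.min(obs))
    q50 = float(np.median(obs))
    z_lo = stats.norm.ppf(max(c, 1e-6))
    z_mid = stats.norm.ppf(c + (1 - c) / 2)
    denom = z_mid - z_lo
    if denom <= 0 or q50 <= m:
        return None
    sigma = (q50 - m) / denom
    mu = m - sigma * z_lo
    return mu, sigma


def impute_left_censored(table: FeatureTable, config: PreprocessConfig) -> FeatureTable:
    """Replace zeros (left-censored values) with draws below the feature's
    observed minimum.

    Default mode draws from a per-feature normal truncated to
    (0, min observed nonzero), with location/scale estimated by quantile
    matching against the censored-normal model; ``half_min`` deterministically
    uses half the observed minimum.  Nonzero entries are untouched.
    """
    inten = table.intensities.copy()
    rng = np.random.default_rng(config.imputation_seed)
    global_min = inten.to_numpy()[inten.to_numpy() > 0].min() if (inten.to_numpy() > 0).any() else 1.0
    for fid in inten.columns:
        col = inten[fid].to_numpy(dtype=float)
        mask = col == 0
        n_zero = int(mask.sum())
        if n_zero == 0:
            continue
        obs = col[~mask]
        if obs.size == 0:
            warnings.warn(
                f"feature {fid} is entirely censored; imputing half the global minimum"
            )
            col[mask] = global_min / 2
            inten[fid] = col
            continue
        m = obs.min()
        if config.imputation == "half_min":
            col[mask] = m / 2
        else:
            params = _qr_truncnorm_params(obs, n_zero / col.size)
            if params is None:
                col[mask] = m / 2
            else:
                mu, sigma = params
                a, b = (0.0 - mu) / sigma, (m - mu) / sigma
                if not a < b:
                    col[mask] = m / 2
                else:
                    draws = stats.truncnorm.rvs(
                        a, b, loc=mu, scale=sigma, size=n_zero, random_state=rng
                    )
                    # numerical guard: strictly inside (0, min_obs)
                    col[mask] = np.clip(draws, np.nextafter(0, 1), np.nextafter(m, 0))
        inten[fid] = col
    return FeatureTable(inten, table.sample_meta, table.feature_meta)


def median_normalize(table: FeatureTable) -> FeatureTable:
    """Scale each sample so its across-feature median equals the reference
    median (the median of per-sample medians)."""
    inten = table.intensities
    sample_medians = inten.median(axis=1)
    if (sample_medians == 0).any():
        bad = list(sample_medians.index[sample_medians == 0])
        raise ValueError(f"samples with zero median cannot be normalized: {bad[:5]}")
    reference = float(sample_medians.median())
    scaled = inten.mul(reference / sample_medians, axis=0)
    return FeatureTable(scaled, table.sample_meta, table.feature_meta)


def zscore_within_participant(table: FeatureTable) -> FeatureTable:
    """Per participant, per feature: center and scale (sample sd, ddof=1)
    across that participant's samples.  Zero-variance features are set to 0."""
    inten = table.intensities
    parts = table.sample_meta["participant_id"]
    counts = parts.value_counts()
    singles = counts[counts < 2]
    if len(singles):
        raise ValueError(
            f"participants with a single sample cannot be z-scored: {list(singles.index)}"
        )
    grouped = inten.groupby(parts, sort=False)
    mean = grouped.transform("mean")
    sd = grouped.transform("std")  # ddof=1
    zero_var = sd == 0
    if zero_var.to_numpy().any():
        log.warning(
            "%d participant/feature cells had zero variance; z-scores set to 0",
            int(zero_var.to_numpy().sum()),
        )
    z = (inten - mean) / sd.where(~zero_var, np.inf)
    z = z.fillna(0.0)
    return FeatureTable(z, table.sample_meta, table.feature_meta)


def prepare_views(table: FeatureTable, config: PreprocessConfig | None = None,
                  feature_subset=None):
    """Run the full cleaning chain and return the requested views.

    between = filter -> impute -> median-normalize;
    within  = between followed by per-participant z-scoring.

    When *feature_subset* is given (e.g. the training experiment's retained
    features, for hold-out evaluation) the zero-value filter is replaced by
    selection of exactly those features.
    """
    config = config or PreprocessConfig()
    steps = []
    if feature_subset is not None:
        missing = [f for f in feature_subset if f not in table.intensities.columns]
        if missing:
            raise ValueError(f"table lacks requested features: {missing[:5]}")
        filtered = table.select_features(feature_subset)
        steps.append(f"select_features({len(list(feature_subset))} externally defined)")
    else:
        filtered, dropped = filter_zero_features(table, config.max_zero_fraction)
        steps.append(
            f"filter_zero_features(>{config.max_zero_fraction:.0%}): dropped {len(dropped)}"
        )
    imputed = impute_left_censored(filtered, config)
    steps.append(f"impute_left_censored({config.imputation}, seed={config.imputation_seed})")
    between = median_normalize(imputed)
    steps.append("median_normalize(reference=median of per-sample medians)")
    views = {}
    if "between" in config.views:
        views["between"] = DataView("between", between, list(steps))
    if "within" in config.views:
        within = zscore_within_participant(between)
        views["within"] = DataView(
            "within", within, list(steps) + ["zscore_within_participant(ddof=1)"]
        )
    return views
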