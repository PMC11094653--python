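"""Knowledge-based a priori feature filter.

A feature becomes a biomarker candidate for modeling only if, in the
training experiment, it shows a significant linear (homeostatic) trend with
a consistent direction in more than half the participants AND at the group
level, while NOT showing a significant 24-h cosinor amplitude in more than
a quarter of participants (a likely circadian confound).  Raw per-test
p-values at alpha are used inside the filter, mirroring screening practice;
FDR belongs to the characterization stage, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trends import GROUP, TrendCatalog


@dataclass
class FilterConfig:
    min_linear_fraction: float = 0.50  # pass requires fraction strictly greater
    max_cyclic_fraction: float = 0.25  # exclusion triggers strictly above
    alpha: float = 0.05
    require_group_significant: bool = True
    require_direction_consensus: bool = True

    def __post_init__(self) -> None:
        for f in (self.min_linear_fraction, self.max_cyclic_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def apply_filter(
    individual_catalog: TrendCatalog,
    group_catalog: TrendCatalog,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Apply the a priori filter; returns the per-feature FilterReport.

    Columns: frac_linear_significant, majority_direction,
    frac_consistent_direction, group_linear_p, group_slope,
    frac_cosinor_significant, passed, fail_reasons.
    """
    config = config or FilterConfig()
    ind = individual_catalog.entries
    grp = group_catalog.entries.set_index("feature_id")
    feats = list(individual_catalog.categories.index)
    if set(feats) != set(grp.index):
        raise ValueError("individual and group catalogs cover different feature universes")

    n_part = ind["participant_id"].nunique()
    a = config.alpha
    rows = []
    for fid, g in ind.groupby("feature_id", sort=False):
        sig = g["p_lin"] < a
        n_sig = int(sig.sum())
        n_up = int((sig & (g["slope"] > 0)).sum())
        n_dn = int((sig & (g["slope"] < 0)).sum())
        majority = 0 if n_up == n_dn else (1 if n_up > n_dn else -1)
        n_consistent = max(n_up, n_dn)
        frac_lin = n_sig / n_part
        frac_consistent = n_consistent / n_part
        frac_cyc = float((g["p_cos"] < a).sum()) / n_part
        gp = float(grp.loc[fid, "p_lin"])
        gslope = float(grp.loc[fid, "slope"])

        reasons = []
        if config.require_direction_consensus:
            if frac_consistent <= config.min_linear_fraction:
                if frac_lin > config.min_linear_fraction and majority != 0 and n_consistent < n_sig:
                    reasons.append("no direction consensus")
                else:
                    reasons.append("insufficient linear fraction")
        else:
            if frac_lin <= config.min_linear_fraction:
                reasons.append("insufficient linear fraction")
        if config.require_group_significant:
            if not gp < a:
                reasons.append("group not significant")
            elif config.require_direction_consensus and majority != 0 and np.sign(gslope) != majority:
                reasons.append("group direction mismatch")
        if frac_cyc > config.max_cyclic_fraction:
            reasons.append("cyclic")

        rows.append(
            {
                "feature_id": fid,
                "frac_linear_significant": frac_lin,
                "majority_direction": majority,
                "frac_consistent_direction": frac_consistent,
                "group_linear_p": gp,
                "group_slope": gslope,
                "frac_cosinor_significant": frac_cyc,
                "passed": not reasons,
                "fail_reasons": reasons,
            }
        )
    report = pd.DataFrame(rows).set_index("feature_id").reindex(feats)
    return report


def passed_features(report: pd.DataFrame) -> list[str]:
    return list(report.index[report["passed"].astype(bool)])
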