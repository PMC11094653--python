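"""Sample x feature intensity table joined to per-sample metadata.

The :class:`FeatureTable` is the universal currency of the pipeline: every
stage consumes and produces one.  Intensities are nonnegative relative peak
areas; a value of exactly 0 encodes a left-censored (below detection limit)
measurement, never a true zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_META_COLUMNS = [
    "participant_id",
    "experiment_id",
    "tsw_hours",
    "day_index",
    "protocol_kind",
    "clock_offset_h",
]


@dataclass
class FeatureTable:
    """Intensity matrix plus aligned sample and feature metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample_id, one column per feature, nonnegative.
    sample_meta
        DataFrame indexed by sample_id with columns participant_id,
        experiment_id, tsw_hours, day_index, protocol_kind, clock_offset_h.
    feature_meta
        DataFrame indexed by feature_id; for synthetic data carries
        ``true_class`` and the generating parameters.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.intensities.columns)
        self.validate()

    def validate(self) -> None:
        if not self.intensities.index.equals(self.sample_meta.index):
            raise ValueError("sample_meta rows must correspond 1:1 with intensity rows")
        if not self.intensities.columns.equals(self.feature_meta.index):
            raise ValueError("feature_meta rows must correspond 1:1 with intensity columns")
        if (self.sample_meta["participant_id"].astype(str) == "").any():
            raise ValueError("participant IDs must be non-empty")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def participants(self) -> list[str]:
        return list(pd.unique(self.sample_meta["participant_id"]))

    def assert_nonnegative(self) -> None:
        vals = self.intensities.to_numpy()
        if np.any(vals < 0):
            raise ValueError("negative intensities are not allowed")

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(),
            self.sample_meta.copy(),
            self.feature_meta.copy(),
        )

    def select_features(self, feature_ids) -> "FeatureTable":
        feature_ids = list(feature_ids)
        return FeatureTable(
            self.intensities.loc[:, feature_ids],
            self.sample_meta,
            self.feature_meta.loc[feature_ids],
        )

    def select_samples(self, mask) -> "FeatureTable":
        return FeatureTable(
            self.intensities.loc[mask],
            self.sample_meta.loc[mask],
            self.feature_meta,
        )

    # ---- CSV round trip (the dialect shared by all pipeline stages) ----

    def to_csv(self, out_dir, name: str) -> None:
        """Write ``<name>_intensities.csv``, ``<name>_samples.csv`` and, when
        feature metadata is present, ``<name>_truth.csv`` under *out_dir*."""
        import pathlib

        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        inten = self.intensities.copy()
        inten.index.name = "sample_id"
        inten.to_csv(out_dir / f"{name}_intensities.csv")
        meta = self.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(out_dir / f"{name}_samples.csv")
        if len(self.feature_meta.columns):
            truth = self.feature_meta.copy()
            truth.index.name = "feature_id"
            truth.to_csv(out_dir / f"{name}_truth.csv")

    @classmethod
    def from_csv(cls, in_dir, name: str) -> "FeatureTable":
        import pathlib

        in_dir = pathlib.Path(in_dir)
        inten = pd.read_csv(in_dir / f"{name}_intensities.csv", index_col="sample_id")
        meta = pd.read_csv(in_dir / f"{name}_samples.csv", index_col="sample_id")
        truth_path = in_dir / f"{name}_truth.csv"
        feature_meta = None
        if truth_path.exists():
            feature_meta = pd.read_csv(truth_path, index_col="feature_id")
            feature_meta.index = feature_meta.index.astype(str)
        inten.columns = inten.columns.astype(str)
        return cls(inten, meta, feature_meta)
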