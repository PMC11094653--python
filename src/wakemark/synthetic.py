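"""Synthetic plasma LC-MS study generator.

Emulates bi-hourly constant-routine sleep-deprivation experiments (extended
wake, 2-38 h time-since-wake) and a matched-control protocol with a nightly
8-h sleep interval, with features drawn from four temporal classes:

* ``linear``    - homeostatic drift: monotone change with accumulated wake,
                  resetting to baseline after sleep;
* ``circadian`` - 24-h cosinor cycling in clock time, unaffected by sleep;
* ``mixed``     - both components;
* ``null``      - baseline plus noise only.

Intensities are relative peak areas on a log-normal scale with
participant-level multiplicative offsets, left-censored zeros produced by
per-feature quantile censoring, and sporadic missing samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .table import FeatureTable

FEATURE_CLASSES = ("linear", "circadian", "mixed", "null")

#: the homeostatic (linear) term is expressed relative to mid-protocol so a
#: decreasing feature starts above its baseline and decays through it rather
#: than crashing into the detection floor: relative peak areas cannot go
#: negative, and a slope of 0.03/h over 38 h would otherwise exceed the
#: baseline itself
HOMEOSTATIC_CENTER_H = 20.0

#: default bi-hourly sampling grid: 2, 4, ..., 38 h time-since-wake
DEFAULT_SD_TIMES = tuple(range(2, 40, 2))
#: matched control: bi-hourly sampling 2-16 h TSW on each in-laboratory day
DEFAULT_CONTROL_DAY_TIMES = {2: tuple(range(2, 18, 2)), 3: tuple(range(2, 18, 2))}


@dataclass
class ProtocolSpec:
    """Sampling design of one in-laboratory experiment."""

    protocol_kind: str = "sleep_deprivation"
    n_participants: int = 12
    sample_times_tsw: tuple = DEFAULT_SD_TIMES
    control_day_times: dict = field(default_factory=lambda: dict(DEFAULT_CONTROL_DAY_TIMES))
    missing_sample_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol_kind not in ("sleep_deprivation", "matched_control"):
            raise ValueError(f"unknown protocol_kind {self.protocol_kind!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        times = np.asarray(self.sample_times_tsw, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample_times_tsw must be strictly increasing")
        if np.any(times < 0):
            raise ValueError("sample times must be >= 0")
        if not 0 <= self.missing_sample_rate < 1:
            raise ValueError("missing_sample_rate must be in [0, 1)")


@dataclass
class FeatureProfileSpec:
    """Generative parameters of a single mass feature.

    ``slope_per_hour`` and ``amplitude`` are on the intensity scale of the
    feature's baseline ``exp(baseline_log_mean)``; the acrophase is the clock
    time (hours after habitual wake) of peak abundance.
    """

    feature_class: str = "null"
    slope_per_hour: float = 0.0
    amplitude: float = 0.0
    acrophase_h: float = 0.0
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 0.5
    noise_sd: float = 1.0
    lod_quantile: float = 0.0

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class {self.feature_class!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if self.feature_class == "null" and (self.slope_per_hour != 0 or self.amplitude != 0):
            raise ValueError("null features must have zero slope and amplitude")


@dataclass
class ProfileDefaults:
    """Population-level effect-size distributions used when drawing a panel.

    Effects are relative to each feature's baseline intensity: a linear slope
    of 0.02/h changes abundance by ~72% over a 36-h constant routine; a
    circadian amplitude of 0.2 cycles by +/-20% around the mesor.
    """

    linear_slope_rel: tuple = (0.010, 0.030)  # |slope| per hour, sign random
    circadian_amp_rel: tuple = (0.10, 0.30)
    noise_rel: float = 0.08
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 0.5
    participant_log_sd: float = 0.30
    censor_high_fraction: float = 0.10  # fraction of features censored beyond 20%
    censor_low_range: tuple = (0.0, 0.08)
    censor_high_range: tuple = (0.25, 0.45)
    class_proportions: dict = field(
        default_factory=lambda: {"linear": 0.02, "circadian": 0.25, "mixed": 0.05, "null": 0.68}
    )


def simulate_feature_profile(spec, times, participant_offset=0.0, rng=None, clock_times=None):
    """Simulate one feature's intensity series for one participant.

    Returns ``baseline * exp(participant_offset) + slope * t_tsw
    + A * cos(2*pi*(t_clock - acrophase)/24) + noise``, floored at 0.
    The linear (homeostatic) term runs on time-since-wake *times*; the
    cosine runs on *clock_times* (defaults to *times*, appropriate for a
    constant routine where no sleep intervenes).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if clock_times is None:
        clock_times = times
    clock_times = np.asarray(clock_times, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    baseline = math.exp(spec.baseline_log_mean) * math.exp(participant_offset)
    y = np.full(times.shape, baseline, dtype=float)
    if spec.feature_class in ("linear", "mixed"):
        y = y + spec.slope_per_hour * (times - HOMEOSTATIC_CENTER_H)
    if spec.feature_class in ("circadian", "mixed"):
        y = y + spec.amplitude * np.cos(2 * np.pi * (clock_times - spec.acrophase_h) / 24.0)
    y = y + rng.normal(0.0, spec.noise_sd, size=times.shape)
    return np.maximum(y, 0.0)


def draw_feature_panel(class_counts, defaults=None, seed=0):
    """Draw a reusable panel of feature profiles.

    The panel (list of :class:`FeatureProfileSpec` plus feature ids) fixes
    the true classes and effect sizes; generating two experiments from the
    same panel with different seeds yields independent realizations with
    shared ground truth, mirroring two independent studies of one cohort
    biology.
    """
    defaults = defaults or ProfileDefaults()
    rng = np.random.default_rng(seed)
    specs, ids = [], []
    idx = 0
    for cls in FEATURE_CLASSES:
        for _ in range(int(class_counts.get(cls, 0))):
            idx += 1
            log_base = rng.normal(defaults.baseline_log_mean, defaults.baseline_log_sd)
            base = math.exp(log_base)
            slope = 0.0
            amp = 0.0
            if cls in ("linear", "mixed"):
                mag = rng.uniform(*defaults.linear_slope_rel)
                slope = base * mag * rng.choice([-1.0, 1.0])
            if cls in ("circadian", "mixed"):
                amp = base * rng.uniform(*defaults.circadian_amp_rel)
            if rng.uniform() < defaults.censor_high_fraction:
                lod = rng.uniform(*defaults.censor_high_range)
            else:
                lod = rng.uniform(*defaults.censor_low_range)
            specs.append(
                FeatureProfileSpec(
                    feature_class=cls,
                    slope_per_hour=slope,
                    amplitude=amp,
                    acrophase_h=rng.uniform(0, 24),
                    baseline_log_mean=log_base,
                    baseline_log_sd=0.0,
                    noise_sd=base * defaults.noise_rel,
                    lod_quantile=lod,
                )
            )
            ids.append(f"F{idx:04d}")
    if not specs:
        raise ValueError("class_counts must request at least one feature")
    return ids, specs


def _panel_meta(ids, specs):
    return pd.DataFrame(
        {
            "true_class": [s.feature_class for s in specs],
            "slope": [s.slope_per_hour for s in specs],
            "amplitude": [s.amplitude for s in specs],
            "acrophase": [s.acrophase_h for s in specs],
        },
        index=pd.Index(ids, name="feature_id"),
    )


def _censor(values, lod_quantile):
    """Left-censor a feature column at its empirical lod quantile."""
    if lod_quantile <= 0:
        return values
    threshold = np.quantile(values, lod_quantile)
    out = values.copy()
    out[out < threshold] = 0.0
    return out


def _drop_missing(meta_rows, rate, rng):
    """Drop exactly round(rate * n) scheduled samples, completely at random."""
    n = len(meta_rows)
    n_drop = int(round(rate * n))
    if n_drop == 0:
        return np.ones(n, dtype=bool)
    drop = rng.choice(n, size=n_drop, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    return keep


def _assemble(protocol, ids, specs, schedule, experiment_id, experiment_scale=1.0):
    """Common experiment assembly: offsets, signal, noise, censoring, dropout.

    *schedule* is a list of (participant_index, tsw, clock, day) tuples.
    """
    rng = np.random.default_rng(protocol.seed)
    offsets = rng.normal(0.0, _participant_log_sd(specs), size=protocol.n_participants)

    tsw = np.array([s[1] for s in schedule], dtype=float)
    clock = np.array([s[2] for s in schedule], dtype=float)
    pidx = np.array([s[0] for s in schedule], dtype=int)
    day = np.array([s[3] for s in schedule], dtype=int)

    cols = {}
    for fid, spec in zip(ids, specs):
        base = math.exp(spec.baseline_log_mean) * np.exp(offsets[pidx])
        y = base.copy()
        if spec.feature_class in ("linear", "mixed"):
            y = y + spec.slope_per_hour * (tsw - HOMEOSTATIC_CENTER_H)
        if spec.feature_class in ("circadian", "mixed"):
            y = y + spec.amplitude * np.cos(2 * np.pi * (clock - spec.acrophase_h) / 24.0)
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
        y = np.maximum(y * experiment_scale, 0.0)
        cols[fid] = _censor(y, spec.lod_quantile)

    participants = [f"{experiment_id}_P{k + 1:02d}" for k in range(protocol.n_participants)]
    sample_ids = [
        f"{experiment_id}_P{p + 1:02d}_d{d}_t{t:04.1f}" for p, t, _c, d in schedule
    ]
    inten = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    meta = pd.DataFrame(
        {
            "participant_id": [participants[p] for p in pidx],
            "experiment_id": experiment_id,
            "tsw_hours": tsw,
            "day_index": day,
            "protocol_kind": protocol.protocol_kind,
            "clock_offset_h": 0.0,
        },
        index=inten.index,
    )
    keep = _drop_missing(sample_ids, protocol.missing_sample_rate, rng)
    return FeatureTable(inten.loc[keep], meta.loc[keep], _panel_meta(ids, specs))


def _participant_log_sd(specs):
    # panel specs carry per-feature baselines; the participant offset scale is
    # a study-level constant (multiplicative, on the natural-log scale)
    return ProfileDefaults().participant_log_sd


def generate_sleep_dep_experiment(
    protocol, class_counts=None, profile_defaults=None, panel=None,
    experiment_id="exp1", experiment_scale=1.0,
):
    """Generate one constant-routine sleep-deprivation experiment.

    One row per scheduled (participant, time-since-wake) sample, minus
    missing samples dropped completely at random.  Pass the same *panel*
    (from :func:`draw_feature_panel`) with different protocol seeds to
    obtain biologically comparable but technically independent experiments.
    """
    if protocol.protocol_kind != "sleep_deprivation":
        raise ValueError("protocol_kind must be sleep_deprivation")
    if panel is None:
        if class_counts is None:
            raise ValueError("provide either a feature panel or class_counts")
        panel = draw_feature_panel(class_counts, profile_defaults, seed=protocol.seed + 7919)
    ids, specs = panel
    schedule = [
        (p, t, t, 1)
        for p in range(protocol.n_participants)
        for t in protocol.sample_times_tsw
    ]
    return _assemble(protocol, ids, specs, schedule, experiment_id, experiment_scale)


def generate_matched_control(
    protocol, class_counts=None, profile_defaults=None, panel=None,
    experiment_id="ctrl", experiment_scale=1.0,
):
    """Generate the matched-control (constant posture) experiment.

    Time-since-wake restarts at 0 after each nightly sleep interval, so the
    homeostatic (linear) term of every feature resets daily; circadian
    features continue uninterrupted in clock time (clock = 24*(day-1) + TSW
    relative to habitual wake).
    """
    if protocol.protocol_kind != "matched_control":
        raise ValueError("protocol_kind must be matched_control")
    if panel is None:
        if class_counts is None:
            raise ValueError("provide either a feature panel or class_counts")
        panel = draw_feature_panel(class_counts, profile_defaults, seed=protocol.seed + 7919)
    ids, specs = panel
    schedule = [
        (p, t, 24.0 * (day - 1) + t, day)
        for p in range(protocol.n_participants)
        for day in sorted(protocol.control_day_times)
        for t in protocol.control_day_times[day]
    ]
    return _assemble(protocol, ids, specs, schedule, experiment_id, experiment_scale)


def generate_study(
    class_counts,
    profile_defaults=None,
    seed=0,
    n_participants=(12, 11, 5),
    missing=(10, 11, 0),
):
    """Generate the full three-experiment study from one shared feature panel.

    Returns (exp1, exp2, control) FeatureTables: two sleep-deprivation
    experiments with 12 and 11 participants (218 and 198 samples at the
    default missing counts of 10 and 11) and a 5-participant matched control.
    """
    panel = draw_feature_panel(class_counts, profile_defaults, seed=seed)
    n1, n2, nc = n_participants
    rate1 = missing[0] / (n1 * len(DEFAULT_SD_TIMES))
    rate2 = missing[1] / (n2 * len(DEFAULT_SD_TIMES))
    exp1 = generate_sleep_dep_experiment(
        ProtocolSpec(n_participants=n1, missing_sample_rate=rate1, seed=seed + 1),
        panel=panel, experiment_id="exp1",
    )
    exp2 = generate_sleep_dep_experiment(
        ProtocolSpec(n_participants=n2, missing_sample_rate=rate2, seed=seed + 2),
        panel=panel, experiment_id="exp2",
    )
    nc_rate = missing[2] / (nc * 16) if nc else 0.0
    control = generate_matched_control(
        ProtocolSpec(
            protocol_kind="matched_control", n_participants=nc,
            missing_sample_rate=nc_rate, seed=seed + 3,
        ),
        panel=panel, experiment_id="ctrl",
    )
    return exp1, exp2, control
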