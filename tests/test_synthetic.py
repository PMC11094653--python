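"""Generator contracts: closed-form profiles, sample bookkeeping,
censoring, determinism, and the sleep-reset construction."""

import numpy as np
import pandas as pd
import pytest

from wakemark.synthetic import (
    DEFAULT_SD_TIMES,
    FeatureProfileSpec,
    ProfileDefaults,
    ProtocolSpec,
    draw_feature_panel,
    generate_matched_control,
    generate_sleep_dep_experiment,
    generate_study,
    simulate_feature_profile,
)
from wakemark.trends import fit_cosinor, fit_linear


def test_default_sampling_grid_is_19_bihourly_times():
    assert len(DEFAULT_SD_TIMES) == 19
    assert DEFAULT_SD_TIMES[0] == 2 and DEFAULT_SD_TIMES[-1] == 38


class TestSimulateProfile:
    def test_noiseless_linear_profile_increments(self):
        spec = FeatureProfileSpec(
            feature_class="linear", slope_per_hour=5.0, noise_sd=1e-12,
            baseline_log_mean=10.0,
        )
        t = np.arange(0, 40, 2.0)
        y = simulate_feature_profile(spec, t, rng=0)
        assert np.all(np.diff(y) > 0)
        np.testing.assert_allclose(np.diff(y), 10.0, atol=1e-6)

    def test_noiseless_cosine_extrema(self):
        spec = FeatureProfileSpec(
            feature_class="circadian", amplitude=3.0, acrophase_h=0.0,
            noise_sd=1e-12,
        )
        t = np.arange(0, 48, 1.0)
        y = simulate_feature_profile(spec, t, rng=0)
        assert {int(t[i]) % 24 for i in np.flatnonzero(y == y.max())} == {0}
        assert {int(t[i]) % 24 for i in np.flatnonzero(y == y.min())} == {12}

    def test_mixed_profile_recovered_by_downstream_fits(self):
        # fit-recovery oracle: cosinor and line fits on one simulated draw
        # baseline well above the drift range so the nonnegativity floor
        # never censors the series
        spec = FeatureProfileSpec(
            feature_class="mixed", slope_per_hour=2.0, amplitude=5.0,
            acrophase_h=8.0, baseline_log_mean=5.0, noise_sd=1.0,
        )
        t = np.asarray(DEFAULT_SD_TIMES, dtype=float)
        # joint linear+cosinor least-squares oracle (the two components are
        # not orthogonal over 1.5 cycles, so they must be fit together);
        # averaged over independent draws to beat the single-draw SE (~0.4)
        X = np.column_stack([np.ones_like(t), t,
                             np.cos(2 * np.pi * t / 24), np.sin(2 * np.pi * t / 24)])
        rng = np.random.default_rng(42)
        betas = [
            np.linalg.lstsq(X, simulate_feature_profile(spec, t, rng=rng), rcond=None)[0]
            for _ in range(8)
        ]
        amp = np.mean([np.hypot(b[2], b[3]) for b in betas])
        slope = np.mean([b[1] for b in betas])
        assert abs(amp - 5.0) < 0.5
        assert abs(slope - 2.0) < 0.2

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            FeatureProfileSpec(feature_class="circadian", amplitude=-1.0)
        with pytest.raises(ValueError):
            FeatureProfileSpec(noise_sd=0.0)
        with pytest.raises(ValueError):
            FeatureProfileSpec(feature_class="null", slope_per_hour=1.0)
        with pytest.raises(ValueError):
            simulate_feature_profile(FeatureProfileSpec(), np.array([]))


class TestSleepDepExperiment:
    def test_full_schedule_sample_count(self):
        panel = draw_feature_panel({"null": 3}, seed=0)
        t = generate_sleep_dep_experiment(
            ProtocolSpec(n_participants=12, seed=1), panel=panel
        )
        assert t.n_samples == 12 * 19 == 228

    def test_missing_rate_reproduces_study_counts(self):
        # 10 of 228 scheduled samples missing -> 218, 10-12 per time point
        panel = draw_feature_panel({"null": 3}, seed=0)
        t = generate_sleep_dep_experiment(
            ProtocolSpec(n_participants=12, missing_sample_rate=10 / 228, seed=1),
            panel=panel,
        )
        assert t.n_samples == 218
        per_time = t.sample_meta.groupby("tsw_hours").size()
        assert per_time.min() >= 10 and per_time.max() <= 12

    def test_class_tallies_match_request(self):
        counts = {"linear": 20, "circadian": 50, "mixed": 30, "null": 900}
        panel = draw_feature_panel(counts, seed=0)
        t = generate_sleep_dep_experiment(
            ProtocolSpec(n_participants=2, seed=1), panel=panel
        )
        assert t.feature_meta["true_class"].value_counts().to_dict() == counts

    def test_determinism_and_seed_independence(self):
        panel = draw_feature_panel({"linear": 2, "null": 3}, seed=5)
        a = generate_sleep_dep_experiment(ProtocolSpec(n_participants=3, seed=9), panel=panel)
        b = generate_sleep_dep_experiment(ProtocolSpec(n_participants=3, seed=9), panel=panel)
        c = generate_sleep_dep_experiment(ProtocolSpec(n_participants=3, seed=10), panel=panel)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)
        assert not a.intensities.equals(c.intensities)
        # shared panel => identical ground truth across experiments
        pd.testing.assert_frame_equal(a.feature_meta, c.feature_meta)

    def test_censoring_yields_zeros_at_configured_rate(self):
        spec = [FeatureProfileSpec(lod_quantile=0.30)]
        t = generate_sleep_dep_experiment(
            ProtocolSpec(n_participants=12, seed=2), panel=(["F1"], spec)
        )
        frac = float((t.intensities["F1"] == 0).mean())
        assert 0.25 < frac < 0.35
        t.assert_nonnegative()

    def test_zero_participants_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(n_participants=0)


class TestMatchedControl:
    def test_linear_feature_resets_after_sleep(self):
        # evening of day 2 must exceed the post-sleep morning of day 3
        spec = FeatureProfileSpec(
            feature_class="linear", slope_per_hour=200.0, noise_sd=1e-6,
            baseline_log_mean=10.0,
        )
        t = generate_matched_control(
            ProtocolSpec(protocol_kind="matched_control", n_participants=5, seed=3),
            panel=(["F1"], [spec]),
        )
        m = t.sample_meta
        evening_d2 = t.intensities.loc[
            ((m.day_index == 2) & m.tsw_hours.between(12, 16)).to_numpy(), "F1"
        ].mean()
        morning_d3 = t.intensities.loc[
            ((m.day_index == 3) & m.tsw_hours.between(2, 6)).to_numpy(), "F1"
        ].mean()
        assert evening_d2 > morning_d3

    def test_circadian_feature_is_clock_matched_across_days(self):
        spec = FeatureProfileSpec(
            feature_class="circadian", amplitude=500.0, acrophase_h=4.0,
            noise_sd=1e-6, baseline_log_mean=10.0,
        )
        t = generate_matched_control(
            ProtocolSpec(protocol_kind="matched_control", n_participants=1, seed=3),
            panel=(["F1"], [spec]),
        )
        m = t.sample_meta
        d2 = t.intensities.loc[(m.day_index == 2).to_numpy(), "F1"].to_numpy()
        d3 = t.intensities.loc[(m.day_index == 3).to_numpy(), "F1"].to_numpy()
        np.testing.assert_allclose(d2, d3, atol=1e-3)

    def test_pre_post_block_counts(self):
        # 5 participants x 3 bi-hourly samples per 4-h block = 15 per condition
        panel = draw_feature_panel({"null": 2}, seed=0)
        t = generate_matched_control(
            ProtocolSpec(protocol_kind="matched_control", n_participants=5, seed=3),
            panel=panel,
        )
        m = t.sample_meta
        block = ((m.day_index == 2) & m.tsw_hours.between(2, 6)).sum()
        assert block == 15


def test_generate_study_shapes():
    exp1, exp2, ctrl = generate_study(
        {"linear": 2, "null": 8}, seed=4, n_participants=(12, 11, 5), missing=(10, 11, 0)
    )
    assert exp1.n_samples == 218 and exp2.n_samples == 198
    assert ctrl.n_samples == 5 * 16
    assert exp1.feature_ids == exp2.feature_ids == ctrl.feature_ids
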