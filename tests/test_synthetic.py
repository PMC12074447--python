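"""Simulator contracts: perception, event statistics, rigid-body structure,
locality, calibration geometry, determinism."""

import dataclasses

import numpy as np
import pytest

from conftest import noiseless_config
from fetalmotion.synthetic import (
    G_GLOBAL,
    GRAVITY,
    SimConfig,
    _axis_angle,
    _sample_events,
    make_cohort,
    random_rotation,
    simulate_calibration,
    simulate_trial,
)


class TestPerception:
    def test_no_perception_no_presses(self):
        cfg = SimConfig(trial_duration=60.0, p_perceive=0.0)
        _, truth = simulate_trial(cfg, seed=1)
        assert truth.press_times.size == 0

    def test_perfect_instant_perception_presses_equal_onsets(self):
        cfg = SimConfig(
            trial_duration=60.0,
            p_perceive=1.0,
            reaction_delay_mean=0.0,
            reaction_delay_sd=0.0,
        )
        _, truth = simulate_trial(cfg, seed=2)
        assert truth.event_onsets.size > 0
        np.testing.assert_allclose(truth.press_times, truth.event_onsets)

    def test_press_fraction_matches_p_perceive(self):
        """Over many trials the perceived fraction converges to p_perceive."""
        cfg = noiseless_config(trial_duration=100.0)
        n_events = n_press = 0
        for seed in range(40):
            _, truth = simulate_trial(cfg, seed=seed)
            n_events += truth.event_onsets.size
            n_press += truth.press_times.size
        frac = n_press / n_events
        se = np.sqrt(0.4 * 0.6 / n_events)
        # presses can be lost at the trial edge, so allow the band downward too
        assert abs(frac - cfg.p_perceive) < 3 * se + 0.02

    def test_presses_within_trial_and_after_onset(self, small_trial):
        trial, truth = small_trial
        assert np.all(truth.press_times <= trial.duration)
        # every press is some onset plus a nonnegative delay <= 3.5 s
        for p in truth.press_times:
            deltas = p - truth.event_onsets
            assert np.any((deltas >= 0) & (deltas <= 3.5))


class TestEventProcess:
    def test_poisson_mean_event_count(self):
        """Cluster thinning preserves the marginal Poisson mean (Monte Carlo
        oracle: 1000 realizations of a 600 s trial at 1 event/min)."""
        cfg = SimConfig(trial_duration=600.0, event_rate=1.0 / 60.0)
        rng = np.random.default_rng(123)
        counts = [
            _sample_events(cfg, np.random.default_rng(rng.integers(2**31)))[0].size
            for _ in range(1000)
        ]
        counts = np.asarray(counts)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 10.0) < 3 * se

    def test_event_sensors_exclude_reference(self, small_trial):
        _, truth = small_trial
        for sensors in truth.event_sensors:
            assert all(0 <= s <= 3 for s in sensors)
            assert 1 <= len(sensors) <= 2

    def test_durations_in_range(self, small_trial):
        _, truth = small_trial
        assert np.all(truth.event_durations >= 0.3)
        assert np.all(truth.event_durations <= 1.5)


class TestRigidBody:
    def test_global_angular_rate_shared_across_sensors(self):
        """With events, noise and drift disabled, removing the mounting
        rotation recovers one identical global angular-rate signal."""
        rng = np.random.default_rng(5)
        R = np.stack([random_rotation(rng) for _ in range(5)])
        cfg = noiseless_config(event_rate=0.0, mounting_rotations=R)
        trial, _ = simulate_trial(cfg, seed=3)
        glob = np.einsum("sji,sjn->sin", R, trial.gyr)
        assert np.abs(glob - glob[0]).max() < 1e-9
        assert trial.gyr.std() > 0  # maternal motion actually present

    def test_locality_events_leave_outside_samples_untouched(self):
        """Disabling fetal events changes nothing outside their supports
        (independent random streams make this exact, not just statistical)."""
        cfg_on = SimConfig(trial_duration=30.0)
        cfg_off = dataclasses.replace(cfg_on, event_rate=0.0)
        trial_on, truth = simulate_trial(cfg_on, seed=0)
        trial_off, _ = simulate_trial(cfg_off, seed=0)
        assert truth.event_onsets.size > 0
        fs = cfg_on.fs
        mask = np.zeros(trial_on.n_samples, dtype=bool)
        for onset, dur in zip(truth.event_onsets, truth.event_durations):
            i0 = int(round(onset * fs))
            i1 = min(trial_on.n_samples, i0 + int(round(dur * fs)) + 1)
            mask[i0:i1] = True
        np.testing.assert_array_equal(
            trial_on.acc[:, :, ~mask], trial_off.acc[:, :, ~mask]
        )
        np.testing.assert_array_equal(
            trial_on.gyr[:, :, ~mask], trial_off.gyr[:, :, ~mask]
        )
        assert np.any(trial_on.acc[:, :, mask] != trial_off.acc[:, :, mask])


class TestCalibration:
    def test_identity_mounting_static_gravity_on_x(self):
        cfg = noiseless_config(mounting_rotations=np.stack([np.eye(3)] * 5))
        calib = simulate_calibration(cfg, seed=0)
        static = calib.acc[:, :, calib.static_slice].mean(axis=-1)
        np.testing.assert_allclose(static, np.tile(G_GLOBAL, (5, 1)), atol=1e-9)

    def test_rotated_mounting_rotates_gravity(self):
        R = _axis_angle([0.0, 0.0, 1.0], np.deg2rad(30.0))
        cfg = noiseless_config(mounting_rotations=np.stack([R] * 5))
        calib = simulate_calibration(cfg, seed=0)
        static = calib.acc[0, :, calib.static_slice].mean(axis=-1)
        np.testing.assert_allclose(static, R @ G_GLOBAL, atol=1e-9)

    def test_hinge_rotation_about_frontal_axis(self):
        cfg = noiseless_config(mounting_rotations=np.stack([np.eye(3)] * 5))
        calib = simulate_calibration(cfg, seed=0)
        w = np.concatenate(
            [calib.gyr[0][:, calib.hinge_slice(k)] for k in range(3)], axis=-1
        )
        cov = w @ w.T
        _, vecs = np.linalg.eigh(cov)
        cos = abs(vecs[:, -1] @ np.array([0.0, 1.0, 0.0]))
        assert cos > 0.99

    def test_phase_structure(self, small_calibration):
        calib = small_calibration
        assert calib.phase_bounds.size == 5
        assert np.all(np.diff(calib.phase_bounds) > 0)
        # static phase precedes the hinges and is rotation-free
        static_gyr = calib.gyr[:, :, calib.static_slice]
        hinge_gyr = calib.gyr[:, :, calib.hinge_slice(0)]
        assert np.abs(hinge_gyr).max() > 10 * np.abs(static_gyr).std()


class TestCohort:
    def test_default_cohort_size_and_distinctness(self):
        cfg = SimConfig(trial_duration=8.0)
        cohort = make_cohort(49, cfg, seed=0)
        assert len(cohort) == 49
        a, b = cohort[0][0], cohort[1][0]
        assert not np.array_equal(a.acc, b.acc)

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(trial_duration=10.0)
        c1 = make_cohort(3, cfg, seed=42)
        c2 = make_cohort(3, cfg, seed=42)
        for (t1, g1, k1), (t2, g2, k2) in zip(c1, c2):
            np.testing.assert_array_equal(t1.acc, t2.acc)
            np.testing.assert_array_equal(t1.gyr, t2.gyr)
            np.testing.assert_array_equal(g1.event_onsets, g2.event_onsets)
            np.testing.assert_array_equal(k1.acc, k2.acc)

    def test_singleton(self):
        cohort = make_cohort(1, SimConfig(trial_duration=10.0), seed=0)
        assert len(cohort) == 1


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"trial_duration": 5.0},
            {"event_band": (0.0, 10.0)},
            {"event_band": (5.0, 70.0)},
            {"p_perceive": 1.5},
            {"event_footprint": 9},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            simulate_trial(SimConfig(**kw), seed=0)

    def test_mounting_orthonormality_enforced(self):
        bad = np.stack([np.eye(3)] * 5)
        bad[0, 0, 0] = 2.0
        with pytest.raises(ValueError, match="orthonormal"):
            simulate_trial(SimConfig(mounting_rotations=bad), seed=0)
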