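"""Generator correctness: event statistics, waveform construction, determinism."""

import numpy as np
import pytest

from gaitval.config import SyntheticConfig
from gaitval.synthetic import (
    generate_events,
    generate_scenario,
    synthesize_gyro,
    synthesize_keypoints,
    synthesize_phase_series,
)

from conftest import nearest_errors


class TestGenerateEvents:
    def test_zero_variance_forces_exact_stride_time(self):
        cfg = SyntheticConfig(
            cadence_spm=120.0, stride_cv=0.0, duration_s=13.0,
            gyro_noise_sd_dps=0.0, velocity_mps=1.3,
        )
        truth = generate_events(cfg)
        np.testing.assert_allclose(truth.stride_durations["right"], 1.0, atol=1e-12)
        np.testing.assert_allclose(truth.stride_durations["left"], 1.0, atol=1e-12)
        assert len(truth.stride_durations["right"]) >= 10

    def test_deterministic_under_fixed_seed(self):
        cfg = SyntheticConfig(cadence_spm=100.0, stride_cv=0.05, seed=7)
        a, b = generate_events(cfg), generate_events(cfg)
        for side in ("left", "right"):
            np.testing.assert_array_equal(a.foot_contacts[side], b.foot_contacts[side])
            np.testing.assert_array_equal(a.toe_offs[side], b.toe_offs[side])

    def test_mean_stride_time_matches_configured_distribution(self):
        # ~1000 strides at cadence 100 -> stride mean 1.2 s
        cfg = SyntheticConfig(
            cadence_spm=100.0, stride_cv=0.05, duration_s=1205.0, seed=3,
        )
        strides = generate_events(cfg).stride_durations["right"]
        assert len(strides) >= 990
        se = np.std(strides, ddof=1) / np.sqrt(len(strides))
        assert abs(np.mean(strides) - 1.2) < 3 * se

    def test_cadence_from_events_matches_configured_mean(self):
        cfg = SyntheticConfig(cadence_spm=96.0, stride_cv=0.05, duration_s=60.0, seed=5)
        truth = generate_events(cfg)
        fc = truth.foot_contacts["right"]
        cadence = 120.0 * (len(fc) - 1) / (fc[-1] - fc[0])
        assert cadence == pytest.approx(96.0, abs=2.0)

    def test_duration_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            generate_events(SyntheticConfig(cadence_spm=100.0, duration_s=2.0))

    def test_event_ordering_invariants(self, clean_scenario):
        truth = clean_scenario[0]
        for side in ("left", "right"):
            fc, to = truth.foot_contacts[side], truth.toe_offs[side]
            assert np.all(np.diff(fc) > 0)
            n = len(to)
            assert np.all(to > fc[:n]) and np.all(to < fc[1 : n + 1])
            swings = truth.swing_intervals(side)
            strides = np.diff(fc)[: len(swings)]
            assert np.all(swings[:, 1] - swings[:, 0] > 0)
            assert np.all(swings[:, 1] - swings[:, 0] < strides)


class TestSynthesizeGyro:
    def test_sign_changes_only_at_swing_boundaries(self, clean_scenario, clean_config):
        truth, gyro = clean_scenario[0], clean_scenario[1]
        world_t = gyro.t - clean_config.clock_offset_s
        z = gyro.gyro_z
        crossings = world_t[np.flatnonzero(np.sign(z[:-1]) != np.sign(z[1:]))]
        events = np.sort(
            np.concatenate([truth.swing_intervals("right").ravel()])
        )
        dt = 1.0 / clean_config.sensor_rate_hz
        assert np.all(nearest_errors(events, crossings) <= 1.5 * dt)
        assert np.all(nearest_errors(crossings, events) <= 1.5 * dt)

    def test_glitches_add_sign_changes_within_each_swing(self):
        cfg = SyntheticConfig(
            seed=9, stride_cv=0.0, gyro_noise_sd_dps=0.0,
            glitch_probability=1.0, glitch_duration_s=0.2,
        )
        truth = generate_events(cfg)
        gyro = synthesize_gyro(truth, cfg)
        world_t = gyro.t - cfg.clock_offset_s
        for start, end in truth.swing_intervals("right"):
            inside = (world_t > start + 1e-3) & (world_t < end - 1e-3)
            z = gyro.gyro_z[inside]
            n_changes = np.sum(np.diff(np.sign(z)) != 0)
            assert n_changes >= 2  # the toe catch dips below zero and back

    def test_clock_offset_shows_up_as_crosscorrelation_lag(self):
        base = dict(seed=4, stride_cv=0.0, gyro_noise_sd_dps=0.0, duration_s=16.0)
        cfg_off = SyntheticConfig(clock_offset_s=0.17, **base)
        cfg_zero = SyntheticConfig(clock_offset_s=0.0, **base)
        truth = generate_events(cfg_off)
        g_off = synthesize_gyro(truth, cfg_off)
        g_zero = synthesize_gyro(generate_events(cfg_zero), cfg_zero)
        dt = 1.0 / cfg_off.sensor_rate_hz
        grid = np.arange(2.0, 13.0, dt)
        a = np.interp(grid, g_off.t, g_off.gyro_z)  # delayed by 0.17 in absolute time
        b = np.interp(grid, g_zero.t, g_zero.gyro_z)
        # brute-force lag scan over less than one stride, so the peak is unique
        lags = np.arange(-0.4, 0.4, dt)
        corr = [np.dot(a, np.interp(grid - lag, grid, b)) for lag in lags]
        assert abs(lags[int(np.argmax(corr))] - 0.17) <= 1.5 * dt

    def test_sensor_timestamps_carry_the_offset(self, clean_scenario, clean_config):
        gyro = clean_scenario[1]
        assert gyro.t[0] == pytest.approx(clean_config.clock_offset_s, abs=1e-12)

    def test_bit_reproducible(self, clean_config):
        t1 = generate_events(clean_config)
        t2 = generate_events(clean_config)
        np.testing.assert_array_equal(
            synthesize_gyro(t1, clean_config).gyro_z,
            synthesize_gyro(t2, clean_config).gyro_z,
        )


class TestSynthesizePhaseSeries:
    def test_sin_crosses_zero_upward_at_contacts(self, clean_scenario):
        truth, series = clean_scenario[0], clean_scenario[2]
        for side in ("left", "right"):
            q = series.contact_channel(side)
            s, t = q[:, 0], series.frame_times
            up = np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0))
            frac = s[up] / (s[up] - s[up + 1])
            crossings = t[up] + frac * (t[up + 1] - t[up])
            inner = truth.foot_contacts[side][1:-1]
            assert np.all(nearest_errors(crossings, inner) <= 1.0 / 60.0)

    def test_constant_stride_gives_constant_phase_rate(self):
        cfg = SyntheticConfig(cadence_spm=120.0, stride_cv=0.0, duration_s=14.0,
                              velocity_mps=1.2, gyro_noise_sd_dps=0.0)
        series = synthesize_phase_series(generate_events(cfg), cfg)
        np.testing.assert_allclose(series.phase_rate, 2 * np.pi, rtol=1e-9)

    def test_quadrature_identity_before_noise(self, clean_scenario):
        series = clean_scenario[2]
        for q in series.quadrature.values():
            np.testing.assert_allclose(q[:, 0] ** 2 + q[:, 1] ** 2, 1.0, atol=1e-12)

    def test_pelvis_velocity_is_configured_constant(self, clean_scenario, clean_config):
        series = clean_scenario[2]
        np.testing.assert_allclose(series.pelvis_velocity, clean_config.velocity_mps)


class TestSynthesizeKeypoints:
    def test_no_edge_frames_when_flag_off(self, clean_scenario):
        track = clean_scenario[3]
        margin = 10
        near = (
            (track.x < margin) | (track.x > track.width_px - margin)
            | (track.y < margin) | (track.y > track.height_px - margin)
        )
        assert not near.any()

    def test_edge_fraction_close_to_configured(self):
        cfg = SyntheticConfig(seed=21, edge_proximity=True, edge_fraction=0.05,
                              duration_s=40.0)
        truth = generate_events(cfg)
        track = synthesize_keypoints(truth, cfg)
        near = (track.x < 10).any(axis=1)
        n = len(track.frame_times)
        p_hat = near.mean()
        tol = 3 * np.sqrt(0.05 * 0.95 / n)  # binomial 3-sigma
        assert abs(p_hat - 0.05) <= tol

    def test_mean_ankle_confidence_near_configured_level(self, clean_scenario):
        track = clean_scenario[3]
        assert 0.80 <= track.ankle_confidence("right").mean() <= 0.90


def test_scenario_generation_is_fully_deterministic(noisy_config):
    a = generate_scenario(noisy_config)
    b = generate_scenario(noisy_config)
    np.testing.assert_array_equal(a[1].gyro_z, b[1].gyro_z)
    np.testing.assert_array_equal(a[2].phase_rate, b[2].phase_rate)
    np.testing.assert_array_equal(a[3].confidence, b[3].confidence)
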