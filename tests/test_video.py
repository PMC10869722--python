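"""Window stitching, quadrature decoding, cadence/velocity, quality rules."""

import numpy as np
import pytest

from gaitval.config import PipelineParams, SyntheticConfig
from gaitval.synthetic import generate_events, synthesize_phase_series
from gaitval.types import KeypointTrack, LEG_JOINTS, SegmentQuality, TimedSegment
from gaitval.video import (
    assemble_sliding_window,
    compute_segment_velocity,
    compute_video_cadence,
    decode_foot_contacts,
    decode_quadrature_events,
    filter_by_ankle_quality,
    flag_clipping,
)

from conftest import nearest_errors


class TestAssembleSlidingWindow:
    def test_single_window_output_is_verbatim(self):
        frames = np.arange(90)
        out = assemble_sliding_window(lambda w: w * 2.0, frames, window=90)
        np.testing.assert_array_equal(out, frames * 2.0)

    def test_identity_model_preserves_frame_indices(self):
        frames = np.arange(300)
        out = assemble_sliding_window(lambda w: w, frames, window=90)
        np.testing.assert_array_equal(out, frames)

    def test_window_start_model_assembly(self):
        # model reports its window start at every row: expected output is 0 for
        # the first 45 frames, a unit ramp through the middle, and N-90 for the
        # last 45 frames
        n, w = 300, 90
        frames = np.arange(n)
        out = assemble_sliding_window(lambda win: np.full(w, win[0]), frames, window=w)
        expected = np.concatenate([
            np.zeros(45),
            np.arange(0, n - w),  # centre row of window starting at t-45
            np.full(45, n - w),
        ])
        np.testing.assert_array_equal(out, expected)

    def test_short_sequence_raises(self):
        with pytest.raises(ValueError, match="at least 90"):
            assemble_sliding_window(lambda w: w, np.arange(50), window=90)


class TestDecodeFootContacts:
    def test_analytic_unit_cycle(self):
        t = np.arange(-0.1, 5.0, 1 / 30.0)
        events = decode_quadrature_events(np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), t)
        np.testing.assert_allclose(events, [0, 1, 2, 3, 4], atol=1 / 60.0)

    def test_roundtrip_against_generator_truth(self, clean_scenario):
        truth, series = clean_scenario[0], clean_scenario[2]
        for side in ("left", "right"):
            decoded = decode_foot_contacts(series, side)
            errors = nearest_errors(decoded, truth.foot_contacts[side])
            assert np.max(errors) <= 1 / 60.0

    def test_no_crossing_gives_empty_list(self):
        t = np.arange(0, 2, 1 / 30.0)
        assert len(decode_quadrature_events(np.full_like(t, 0.5), np.ones_like(t), t)) == 0

    def test_crossings_with_negative_cos_are_rejected(self):
        # sin upward crossings at integers, but cos = -1 there: the phase-pi
        # crossing of a cycle, not the event
        t = np.arange(-0.1, 3.0, 1 / 30.0)
        events = decode_quadrature_events(np.sin(2 * np.pi * t), -np.cos(2 * np.pi * t), t)
        assert len(events) == 0

    def test_invalid_leg_raises(self, clean_scenario):
        with pytest.raises(ValueError):
            decode_foot_contacts(clean_scenario[2], "prosthetic")


def _flat_series(omega=2 * np.pi, velocity=1.0, duration=10.0):
    cfg = SyntheticConfig(cadence_spm=60.0 * omega / np.pi, stride_cv=0.0,
                          velocity_mps=velocity, duration_s=max(duration, 14.0),
                          gyro_noise_sd_dps=0.0)
    return synthesize_phase_series(generate_events(cfg), cfg)


class TestCadenceAndVelocity:
    @pytest.mark.parametrize("omega, expected", [(2 * np.pi, 120.0), (np.pi, 60.0)])
    def test_constant_phase_rate(self, omega, expected):
        series = _flat_series(omega=omega)
        seg = TimedSegment(t_start=2.0, t_end=7.3)
        assert compute_video_cadence(series, seg) == pytest.approx(expected, abs=1e-9)

    def test_cadence_roundtrip_with_stride_jitter(self):
        cfg = SyntheticConfig(cadence_spm=100.0, stride_cv=0.05, seed=17,
                              gyro_noise_sd_dps=0.0)
        truth = generate_events(cfg)
        series = synthesize_phase_series(truth, cfg)
        seg = TimedSegment(t_start=truth.t_start, t_end=truth.t_end)
        c_v = compute_video_cadence(series, seg)
        c_truth = truth.cadence_in_window(seg.t_start, seg.t_end)
        assert abs(c_v - c_truth) <= 1.0

    def test_cadence_invariant_to_time_translation(self):
        series = _flat_series()
        shifted = _flat_series()
        shifted.frame_times = shifted.frame_times + 37.5
        a = compute_video_cadence(series, TimedSegment(t_start=2.0, t_end=8.0))
        b = compute_video_cadence(shifted, TimedSegment(t_start=39.5, t_end=45.5))
        assert a == pytest.approx(b, abs=1e-9)

    def test_constant_velocity_is_exact(self):
        series = _flat_series(velocity=1.1)
        seg = TimedSegment(t_start=2.0, t_end=9.0)
        assert compute_segment_velocity(series, seg) == pytest.approx(1.1, abs=1e-12)

    def test_annotated_ground_truth_velocity(self):
        assert TimedSegment(t_start=0.0, t_end=8.0).ground_truth_velocity == 1.25

    def test_segment_outside_series_raises(self):
        series = _flat_series()
        with pytest.raises(ValueError, match="outside"):
            compute_video_cadence(series, TimedSegment(t_start=2.0, t_end=1e4))


def _track(n_frames=150, edge_frames=(), ankle_conf=0.85):
    t = np.arange(n_frames) / 30.0
    x = np.full((n_frames, len(LEG_JOINTS)), 540.0)
    y = np.full_like(x, 1500.0)
    conf = np.full_like(x, 0.9)
    conf[:, LEG_JOINTS.index("right_ankle")] = ankle_conf
    for f in edge_frames:
        x[f, LEG_JOINTS.index("right_ankle")] = 5.0
    return KeypointTrack(frame_times=t, x=x, y=y, confidence=conf)


class TestQualityRules:
    def test_keypoint_near_edge_flags_frame(self):
        q = flag_clipping(_track(edge_frames=[3]))
        assert q.clipped_fraction == pytest.approx(1 / 150)

    def test_centre_keypoints_never_clip(self):
        q = flag_clipping(_track())
        assert q.clipped_fraction == 0.0 and not q.clipped

    def test_two_of_150_frames_exceed_one_percent(self):
        q = flag_clipping(_track(edge_frames=[10, 20]))
        assert q.clipped_fraction == pytest.approx(2 / 150)
        assert q.clipped  # 1.33% > 1%

    def test_clipped_decision_monotone_in_clipped_frames(self):
        fractions = [
            flag_clipping(_track(edge_frames=list(range(k)))).clipped
            for k in (0, 1, 2, 5, 20)
        ]
        assert fractions == sorted(fractions)

    def test_quality_threshold_partition(self):
        qualities = [
            SegmentQuality(ankle_confidence=0.65, clipped_fraction=0.0, clipped=False),
            SegmentQuality(ankle_confidence=0.70, clipped_fraction=0.0, clipped=False),
            SegmentQuality(ankle_confidence=0.90, clipped_fraction=0.05, clipped=True),
        ]
        included, excluded = filter_by_ankle_quality(qualities, threshold=0.7)
        assert [q.ankle_confidence for q in included] == [0.70]
        assert [q.ankle_confidence for q in excluded] == [0.65, 0.90]

    def test_segment_restriction_uses_only_inside_frames(self):
        track = _track(edge_frames=[0, 1, 2])
        seg = TimedSegment(t_start=1.0, t_end=4.0)  # excludes the clipped frames
        assert flag_clipping(track, seg).clipped_fraction == 0.0
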