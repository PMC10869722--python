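"""Synthetic paired sensor/video gait recordings with known ground truth.

No public recordings exist for the clinical validation this package
implements, so every downstream stage is exercised against this generator:
it emits a shank-gyro trace, a per-frame video gait-phase series (quadrature
event channels, phase rate, pelvis velocity, hip/knee angles), leg-keypoint
tracks with confidences, and the exact event times that produced them.

The sensor and video sides share one world clock; the sensor trace is
timestamped at world time + the configured clock offset, which is what the
synchronization stage has to recover.

Waveform model
--------------
The shank gyro z-channel is a half-sine lobe of configurable peak (default
300 deg/s) during each prosthetic-limb swing and a shallow negative half-sine
dip (default -20 deg/s) during stance, so the noiseless template is
continuous, positive exactly inside swings, and crosses zero exactly at toe
off (upward) and foot contact (downward).  An optional toe-catch glitch
subtracts a raised-cosine deceleration pulse centred mid-swing, twice the
local lobe amplitude deep, so the signed reversal lasts about half the
configured pulse duration — the brief mid-swing reversal the deglitching
median filter exists to remove.
"""

from __future__ import annotations

import numpy as np

from .config import SyntheticConfig
from .types import (
    GaitGroundTruth,
    GaitPhaseSeries,
    GyroTrace,
    KeypointTrack,
    LEG_JOINTS,
    TimedSegment,
)

__all__ = [
    "generate_events",
    "synthesize_gyro",
    "synthesize_phase_series",
    "synthesize_keypoints",
    "synthesize_packets",
    "make_segment",
    "generate_scenario",
]

_FIRST_CONTACT_S = 1.0  # lead-in before the first prosthetic foot contact
_SEGMENT_LEAD_S = 0.5  # gap between first contact and segment start


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per component
    return np.random.default_rng([config.seed, stream])


def _truncated_normal(rng, mean, sd, n, nsig=3.0):
    """Normal draws re-sampled until within mean ± nsig*sd (vectorised)."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = np.abs(out - mean) > nsig * sd
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = np.abs(out - mean) > nsig * sd
    return out


def generate_events(config: SyntheticConfig) -> GaitGroundTruth:
    """Draw ground-truth foot-contact and toe-off times for both legs.

    The prosthetic leg's stride durations are drawn i.i.d. from a truncated
    normal (mean 120/cadence s, CV as configured, truncated at ±3 SD); the
    sound side steps half a stride later.  Raises ``ValueError`` when the
    recording is too short to hold one full stride.
    """
    stride_s = 120.0 / config.cadence_spm
    if config.duration_s < _FIRST_CONTACT_S + stride_s + 0.2:
        raise ValueError(
            f"duration {config.duration_s} s too short for one full stride of {stride_s} s"
        )
    rng = _rng(config, 0)
    n_max = int(np.ceil(config.duration_s / stride_s)) + 4
    strides = _truncated_normal(rng, stride_s, config.stride_cv * stride_s, n_max)
    pros_fc = _FIRST_CONTACT_S + np.concatenate([[0.0], np.cumsum(strides)])
    keep = pros_fc <= config.duration_s - 0.1
    pros_fc = pros_fc[keep]
    if len(pros_fc) < 2:
        raise ValueError("recording too short: fewer than two prosthetic contacts")
    pros_strides = np.diff(pros_fc)
    # contralateral contacts half a stride later
    other_fc = pros_fc[:-1] + 0.5 * pros_strides
    other_fc = other_fc[other_fc <= config.duration_s - 0.1]
    other_strides = np.diff(other_fc)

    def _toe_offs(fc, strides):
        return fc[: len(strides)] + config.stance_fraction * strides

    pros, other = config.prosthetic_side, ("left" if config.prosthetic_side == "right" else "right")
    foot_contacts = {pros: pros_fc, other: other_fc}
    toe_offs = {pros: _toe_offs(pros_fc, pros_strides), other: _toe_offs(other_fc, other_strides)}
    stride_durations = {pros: pros_strides, other: other_strides}

    t_start = _FIRST_CONTACT_S + _SEGMENT_LEAD_S
    t_end_full = t_start + config.segment_distance_m / config.velocity_mps
    t_end = min(t_end_full, pros_fc[-1] - 0.2)
    if t_end <= t_start + stride_s:
        raise ValueError("recording too short to hold a timed walking segment")
    return GaitGroundTruth(
        foot_contacts=foot_contacts,
        toe_offs=toe_offs,
        stride_durations=stride_durations,
        velocity_mps=config.velocity_mps,
        cadence_spm=config.cadence_spm,
        t_start=t_start,
        t_end=t_end,
        duration_s=config.duration_s,
        prosthetic_side=config.prosthetic_side,
    )


def make_segment(truth: GaitGroundTruth, config: SyntheticConfig) -> TimedSegment:
    """Timed-walk annotation consistent with the generated bout.

    The annotated distance is exactly velocity × elapsed time, mirroring tape
    marks placed on the ground at a known spacing.
    """
    return TimedSegment(
        t_start=truth.t_start,
        t_end=truth.t_end,
        distance_m=truth.velocity_mps * (truth.t_end - truth.t_start),
        view=config.segment_view,
        segment_id=f"seed{config.seed}",
    )


def gyro_template(truth: GaitGroundTruth, config: SyntheticConfig, t: np.ndarray) -> np.ndarray:
    """Noiseless, glitch-free shank gyro z waveform at world times ``t``."""
    t = np.asarray(t, float)
    side = truth.prosthetic_side
    fc = truth.foot_contacts[side]
    to = truth.toe_offs[side]
    stance_mean = float(np.mean(to - fc[: len(to)]))
    g = np.full(t.shape, -0.3 * config.stance_dip_dps)

    def _stance(a, b):
        m = (t >= a) & (t < b)
        g[m] = -config.stance_dip_dps * np.sin(np.pi * (t[m] - a) / (b - a))

    def _swing(a, b):
        m = (t >= a) & (t < b)
        g[m] = config.swing_peak_dps * np.sin(np.pi * (t[m] - a) / (b - a))

    _stance(fc[0] - stance_mean, fc[0])  # virtual lead-in stance
    for k in range(len(fc) - 1):
        _stance(fc[k], to[k])
        _swing(to[k], fc[k + 1])
    _stance(fc[-1], fc[-1] + stance_mean)  # virtual run-out stance
    return g


def synthesize_gyro(truth: GaitGroundTruth, config: SyntheticConfig) -> GyroTrace:
    """Sample the shank gyro, add toe-catch glitches and noise, stamp sensor time."""
    n = int(np.floor(truth.duration_s * config.sensor_rate_hz))
    world_t = np.arange(n) / config.sensor_rate_hz
    g = gyro_template(truth, config, world_t)

    if config.glitch_probability > 0:
        rng = _rng(config, 2)
        d = config.glitch_duration_s
        for start, end in truth.swing_intervals(truth.prosthetic_side):
            if rng.random() >= config.glitch_probability:
                continue
            swing = end - start
            lo, hi = start + d / 2 + 0.01, end - d / 2 - 0.01
            if hi <= lo:
                continue  # glitch does not fit inside this swing
            centre = np.clip(start + swing * rng.uniform(0.45, 0.55), lo, hi)
            m = np.abs(world_t - centre) < d / 2
            # smooth local inversion: the signed reversal lasts d/2 around the
            # centre, and the waveform rejoins the lobe smoothly at +/- d/2
            g[m] *= -np.cos(2 * np.pi * (world_t[m] - centre) / d)

    if config.gyro_noise_sd_dps > 0:
        g = g + _rng(config, 3).normal(0.0, config.gyro_noise_sd_dps, size=n)

    return GyroTrace(
        t=world_t + config.clock_offset_s,
        gyro_z=g,
        nominal_rate_hz=config.sensor_rate_hz,
    )


def _event_phase(event_times: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear phase hitting 2πk exactly at the k-th event.

    Extrapolated at the edge stride rates but capped half a cycle beyond the
    terminal events, so decoding cannot invent events outside the bout.
    """
    e = np.asarray(event_times, float)
    if len(e) < 2:
        raise ValueError("need at least two occurrences to define a phase")
    knots = 2 * np.pi * np.arange(len(e))
    phi = np.interp(t, e, knots)
    left = t < e[0]
    phi[left] = np.maximum((t[left] - e[0]) * 2 * np.pi / (e[1] - e[0]), -np.pi)
    right = t > e[-1]
    phi[right] = np.minimum(
        knots[-1] + (t[right] - e[-1]) * 2 * np.pi / (e[-1] - e[-2]), knots[-1] + np.pi
    )
    return phi


def _stride_rate(event_times: np.ndarray, t: np.ndarray) -> np.ndarray:
    """dφ/dt of the stride cycle: 2π over the current stride duration."""
    e = np.asarray(event_times, float)
    rates = 2 * np.pi / np.diff(e)
    idx = np.clip(np.searchsorted(e, t, side="right") - 1, 0, len(rates) - 1)
    return rates[idx]


def synthesize_phase_series(truth: GaitGroundTruth, config: SyntheticConfig) -> GaitPhaseSeries:
    """Per-frame video-side outputs at the video frame rate.

    Quadrature channels encode each event's cycle phase as (sin φ, cos φ);
    the phase-rate channel is the stride-cycle dφ/dt; hip and knee sagittal
    angles integrate the noiseless shank angular velocity (split between the
    two joints and detrended so they stay bounded), which makes their summed
    time-derivative usable for clock-offset estimation.
    """
    n_frames = int(np.floor(truth.duration_s * config.video_fps))
    ft = np.arange(n_frames) / config.video_fps

    quad = {}
    for side in ("left", "right"):
        for kind, times in (
            ("foot_contact", truth.foot_contacts[side]),
            ("toe_off", truth.toe_offs[side]),
        ):
            phi = _event_phase(times, ft)
            quad[f"{side}_{kind}"] = np.column_stack([np.sin(phi), np.cos(phi)])

    pros_fc = truth.foot_contacts[truth.prosthetic_side]
    phase_rate = _stride_rate(pros_fc, ft)

    pelvis = np.full(n_frames, truth.velocity_mps)
    if config.velocity_modulation_mps > 0:
        pelvis = pelvis + config.velocity_modulation_mps * np.sin(_event_phase(pros_fc, ft))

    # shank angle from the noiseless gyro template, integrated on a dense grid
    dense = np.arange(int(truth.duration_s * 240)) / 240.0
    omega = gyro_template(truth, config, dense)
    theta = np.concatenate([[0.0], np.cumsum((omega[1:] + omega[:-1]) / 2) / 240.0])
    theta -= dense * (theta[-1] - theta[0]) / (dense[-1] - dense[0])  # remove drift
    theta_f = np.interp(ft, dense, theta)
    hip = 20.0 + 0.35 * theta_f
    knee = 10.0 + 0.65 * theta_f

    return GaitPhaseSeries(
        frame_times=ft,
        quadrature=quad,
        phase_rate=phase_rate,
        pelvis_velocity=pelvis,
        hip_angle=hip,
        knee_angle=knee,
    )


def synthesize_keypoints(truth: GaitGroundTruth, config: SyntheticConfig) -> KeypointTrack:
    """Leg keypoints in a 1080 × 1920 portrait frame with confidences.

    Geometry is a simple swinging-leg cartoon (it drives nothing downstream
    but the clipping rule); confidence carries the configured prosthetic-ankle
    level.  With the edge-proximity flag set, a Bernoulli(edge_fraction)
    subset of frames pushes the prosthetic ankle within 10 px of the border.
    """
    n_frames = int(np.floor(truth.duration_s * config.video_fps))
    ft = np.arange(n_frames) / config.video_fps
    rng = _rng(config, 4)
    width, height = 1080, 1920

    x = np.empty((n_frames, len(LEG_JOINTS)))
    y = np.empty_like(x)
    conf = np.empty_like(x)
    phase = {s: _event_phase(truth.foot_contacts[s], ft) for s in ("left", "right")}
    centre_x = width / 2
    for j, joint in enumerate(LEG_JOINTS):
        side, part = joint.split("_")
        amp = {"hip": 25.0, "knee": 60.0, "ankle": 110.0}[part]
        y[:, j] = {"hip": 1150.0, "knee": 1430.0, "ankle": 1700.0}[part]
        lateral = -40.0 if side == "left" else 40.0
        x[:, j] = centre_x + lateral + amp * np.sin(phase[side])
        level = config.ankle_confidence if joint == f"{truth.prosthetic_side}_ankle" else 0.92
        conf[:, j] = np.clip(level + rng.normal(0.0, 0.02, n_frames), 0.0, 1.0)

    if config.edge_proximity and config.edge_fraction > 0:
        near_edge = rng.random(n_frames) < config.edge_fraction
        x[near_edge, LEG_JOINTS.index(f"{truth.prosthetic_side}_ankle")] = 4.0

    return KeypointTrack(
        frame_times=ft,
        x=x,
        y=y,
        confidence=conf,
        width_px=width,
        height_px=height,
        prosthetic_side=truth.prosthetic_side,
    )


def synthesize_packets(
    config: SyntheticConfig,
    true_rate_hz: float | None = None,
    n_packets: int = 200,
    samples_per_packet: int = 18,
    host_jitter_sd_s: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """BLE packet host timestamps and sample indices for timebase calibration.

    The true on-sensor rate may differ from nominal by a couple of Hz; host
    arrival times carry millisecond-scale jitter.
    """
    rate = true_rate_hz if true_rate_hz is not None else config.sensor_rate_hz
    rng = _rng(config, 5)
    indices = np.arange(n_packets) * samples_per_packet
    host = indices / rate + rng.normal(0.0, host_jitter_sd_s, size=n_packets)
    return host, indices


def generate_scenario(config: SyntheticConfig):
    """Convenience bundle: (truth, gyro, phase series, keypoints, segment)."""
    truth = generate_events(config)
    return (
        truth,
        synthesize_gyro(truth, config),
        synthesize_phase_series(truth, config),
        synthesize_keypoints(truth, config),
        make_segment(truth, config),
    )
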