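"""Video-side gait outputs: window stitching, event decoding, cadence,
velocity, and keypoint-quality rules.

The trained sequence model itself is out of scope here; what this module
owns is the computation defined around it — assembling sliding-window model
outputs into a per-frame series, decoding cyclic events from their
quadrature (sin φ, cos φ) encoding, integrating the phase rate into cadence,
time-averaging pelvis velocity over an annotated 10-m segment, and the
keypoint-quality rules that decide which segments enter the validation.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .config import PipelineParams
from .types import GaitPhaseSeries, KeypointTrack, SegmentQuality, TimedSegment

__all__ = [
    "assemble_sliding_window",
    "decode_foot_contacts",
    "decode_quadrature_events",
    "compute_video_cadence",
    "compute_segment_velocity",
    "flag_clipping",
    "filter_by_ankle_quality",
]


def assemble_sliding_window(
    model: Callable[[np.ndarray], np.ndarray],
    frames: np.ndarray | Sequence,
    window: int = 90,
) -> np.ndarray:
    """Stitch per-window model outputs into one per-frame output sequence.

    ``model`` maps a window of ``window`` consecutive frames to one output
    row per frame.  The model is run at every window position; each interior
    output frame takes the centre row of the window centred on it, while the
    first and last half-windows take the corresponding half of the first and
    last window's output.  For a sequence of N frames the result has N rows.
    """
    frames = np.asarray(frames)
    n = len(frames)
    if n < window:
        raise ValueError(f"need at least {window} frames, got {n}")
    half = window // 2
    pieces = []
    last = None
    for start in range(0, n - window + 1):
        out = np.asarray(model(frames[start : start + window]))
        if len(out) != window:
            raise ValueError("model must return one output row per window frame")
        if start == 0:
            pieces.append(out[:half])  # leading half from the first window
        if start < n - window:
            pieces.append(out[half : half + 1])  # centre row -> frame start+half
        else:
            last = out
    pieces.append(last[half:])  # trailing half from the last window
    stitched = np.concatenate(pieces, axis=0)
    if len(stitched) != n:
        raise AssertionError("window stitching produced a wrong-length output")
    return stitched


def decode_quadrature_events(
    sin_ch: np.ndarray, cos_ch: np.ndarray, frame_times: np.ndarray
) -> np.ndarray:
    """Event times at the positively directed zero crossings of sin φ.

    The sin channel of a noisy quadrature pair can cross zero upward twice
    per cycle; the true event sits at φ ≈ 0 where cos ≈ +1, so crossings with
    a negative interpolated cos are rejected.  Crossing times are located by
    linear interpolation between the bracketing frames.
    """
    s = np.asarray(sin_ch, float)
    c = np.asarray(cos_ch, float)
    t = np.asarray(frame_times, float)
    if len(s) < 2:
        raise ValueError("need at least two frames to find a crossing")
    up = np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0))
    if len(up) == 0:
        return np.empty(0)
    frac = s[up] / (s[up] - s[up + 1])
    cos_at = c[up] + frac * (c[up + 1] - c[up])
    up, frac = up[cos_at > 0], frac[cos_at > 0]
    return t[up] + frac * (t[up + 1] - t[up])


def decode_foot_contacts(series: GaitPhaseSeries, leg: str) -> np.ndarray:
    """Foot-contact times (s, video timebase) for ``leg`` ('left'/'right')."""
    if leg not in ("left", "right"):
        raise ValueError("leg must be 'left' or 'right'")
    q = series.contact_channel(leg)
    return decode_quadrature_events(q[:, 0], q[:, 1], series.frame_times)


def _segment_grid(series: GaitPhaseSeries, segment: TimedSegment) -> tuple[np.ndarray, np.ndarray]:
    """Frame times clipped to the segment with interpolated partial ends."""
    t = series.frame_times
    if segment.t_start < t[0] - 1e-9 or segment.t_end > t[-1] + 1e-9:
        raise ValueError("segment extends outside the series time range")
    inner = t[(t > segment.t_start) & (t < segment.t_end)]
    return np.concatenate([[segment.t_start], inner, [segment.t_end]]), t


def compute_video_cadence(series: GaitPhaseSeries, segment: TimedSegment) -> float:
    """Cadence c_v (steps/min) from the phase-rate channel.

    c_v = 120 / (2π (t_e − t_s)) · ∫ ω̇ dt over the timed segment: the phase
    rate integrates to strides, converted to steps/min.  Trapezoidal rule
    over frames, with the partial frames at the segment ends handled by
    linear interpolation.
    """
    grid, t = _segment_grid(series, segment)
    omega = np.interp(grid, t, series.phase_rate)
    integral = np.trapezoid(omega, grid)
    return 120.0 / (2 * np.pi * segment.duration_s) * integral


def compute_segment_velocity(series: GaitPhaseSeries, segment: TimedSegment) -> float:
    """Trapezoidal time-average of the pelvis-velocity channel (m/s)."""
    grid, t = _segment_grid(series, segment)
    v = np.interp(grid, t, series.pelvis_velocity)
    return float(np.trapezoid(v, grid) / segment.duration_s)


def flag_clipping(
    track: KeypointTrack,
    segment: TimedSegment | None = None,
    params: PipelineParams | None = None,
) -> SegmentQuality:
    """Per-segment keypoint quality: clipping and mean prosthetic-ankle confidence.

    A frame is clipped when any leg keypoint comes within the margin
    (default 10 px) of the image border; the segment is clipped when the
    clipped-frame fraction exceeds the threshold (default 1%).
    """
    params = params or PipelineParams()
    t = track.frame_times
    if segment is not None:
        sel = (t >= segment.t_start) & (t <= segment.t_end)
        if not np.any(sel):
            raise ValueError("segment contains no keypoint frames")
    else:
        sel = np.ones(len(t), dtype=bool)
    m = params.clip_margin_px
    x, y = track.x[sel], track.y[sel]
    near = (
        (x < m)
        | (x > track.width_px - m)
        | (y < m)
        | (y > track.height_px - m)
    )
    clipped_frames = np.any(near, axis=1)
    fraction = float(np.mean(clipped_frames))
    ankle = float(np.mean(track.ankle_confidence(track.prosthetic_side)[sel]))
    return SegmentQuality(
        ankle_confidence=ankle,
        clipped_fraction=fraction,
        clipped=fraction > params.clip_fraction,
        segment_id=segment.segment_id if segment is not None else "",
    )


def frame_is_clipped(x: float, y: float, params: PipelineParams | None = None,
                     width: int = 1080, height: int = 1920) -> bool:
    """Single-keypoint form of the clipping rule (margin default 10 px)."""
    params = params or PipelineParams()
    m = params.clip_margin_px
    return bool(x < m or x > width - m or y < m or y > height - m)


def filter_by_ankle_quality(
    qualities: Sequence[SegmentQuality],
    threshold: float = 0.7,
) -> tuple[list[SegmentQuality], list[SegmentQuality]]:
    """Partition segments into (included, excluded).

    A segment is included when its mean prosthetic-ankle confidence is at
    least the threshold (strictly-below excludes) and it is not clipped.
    Sets each quality's ``included`` flag in place.
    """
    included, excluded = [], []
    for q in qualities:
        q.included = (q.ankle_confidence >= threshold) and not q.clipped
        (included if q.included else excluded).append(q)
    return included, excluded
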