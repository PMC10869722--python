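"""Prosthetic-limb swing detection from the shank gyroscope.

With the sensor on the lateral shank, the gyro z-axis is roughly normal to
the sagittal plane, so forward shank rotation during swing produces a large
positive lobe.  The detector low-pass filters the z-channel (8th-order
Chebyshev I, 35 Hz), zeroes negative values, applies a 360 ms median filter
to remove brief toe-catch reversals, and reads contiguous positive runs as
swings.  The positive-to-negative transition at the end of each run is the
end-of-swing time — a close, slightly early proxy for foot contact.

The filter is applied forward-backward (zero phase): event timing, not
magnitude fidelity, is what the downstream validation consumes.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, stats

from .config import PipelineParams
from .types import GyroTrace, SwingEventList, TimebaseFit, TimedSegment

__all__ = ["calibrate_timebase", "detect_swings", "swings_in_segment"]


def calibrate_timebase(
    packet_host_times: np.ndarray, packet_sample_indices: np.ndarray
) -> TimebaseFit:
    """OLS calibration of the sensor timebase against host (Android) time.

    Fits host_time = intercept + index / effective_rate.  The effective rate
    typically lands a Hz or two off the nominal value.
    """
    host = np.asarray(packet_host_times, float)
    idx = np.asarray(packet_sample_indices, float)
    if host.shape != idx.shape:
        raise ValueError("host times and sample indices must have equal length")
    if len(host) < 2:
        raise ValueError("timebase calibration needs at least two packets")
    if np.ptp(idx) == 0:
        raise ValueError("sample indices have zero variance")
    fit = stats.linregress(idx, host)
    if fit.slope <= 0:
        raise ValueError("non-increasing host time against sample index")
    resid = host - (fit.intercept + fit.slope * idx)
    return TimebaseFit(
        effective_rate_hz=1.0 / fit.slope,
        intercept_s=float(fit.intercept),
        residual_sd_s=float(np.std(resid)),
    )


def detect_swings(trace: GyroTrace, params: PipelineParams | None = None) -> SwingEventList:
    """Detect swing intervals on the gyro z-channel.

    Pipeline: Chebyshev-I low pass (zero-phase) → rectify (zero out
    negatives) → median filter over the configured span → contiguous strictly
    positive runs are swings.  Interval bounds are taken at the first sample
    of the new sign; at 562.5 Hz one sample is 1.8 ms, far below the timing
    errors that matter downstream.
    """
    params = params or PipelineParams()
    z = np.asarray(trace.gyro_z, float)
    rate = trace.rate_hz
    span = int(round(params.median_span_s * rate))
    if len(z) <= span or len(z) < 3 * params.filter_order:
        raise ValueError("trace shorter than the median-filter span")
    if not 0.8 * trace.nominal_rate_hz <= rate <= 1.2 * trace.nominal_rate_hz:
        raise ValueError(f"sampling rate {rate:.1f} Hz departs >20% from nominal")

    sos = signal.cheby1(
        params.filter_order,
        params.filter_ripple_db,
        params.filter_cutoff_hz,
        btype="low",
        fs=rate,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, z)
    rectified = np.where(filtered > 0, filtered, 0.0)
    kernel = span if span % 2 == 1 else span + 1  # medfilt needs an odd kernel
    deglitched = signal.medfilt(rectified, kernel_size=kernel)

    positive = deglitched > 0
    edges = np.diff(positive.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1  # first positive sample
    ends = np.flatnonzero(edges == -1) + 1  # first non-positive sample
    if positive[0]:
        starts = np.concatenate([[0], starts])
    if positive[-1]:
        ends = np.concatenate([ends, [len(z) - 1]])
    intervals = np.column_stack([trace.t[starts], trace.t[ends]])
    return SwingEventList(intervals=intervals)


def swings_in_segment(events: SwingEventList, segment: TimedSegment) -> SwingEventList:
    """Keep swings whose end-of-swing time falls inside [t_start, t_end].

    The interval is closed at both ends; the retained first/last indices
    (i, j of the sensor-cadence formula) refer to the original list.
    """
    if len(events) == 0:
        return SwingEventList(intervals=np.empty((0, 2)))
    ends = events.ends
    inside = np.flatnonzero((ends >= segment.t_start) & (ends <= segment.t_end))
    if len(inside) == 0:
        return SwingEventList(intervals=np.empty((0, 2)))
    return SwingEventList(
        intervals=events.intervals[inside],
        first_index=int(inside[0]),
        last_index=int(inside[-1]),
    )
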