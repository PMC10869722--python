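"""Core data containers shared by the gait-validation pipeline.

All times are seconds.  Two timebases appear throughout:

* the *video* timebase — frame timestamps of the phone video, which is also
  the timebase of ground-truth annotations and of the synthetic world clock;
* the *sensor* timebase — timestamps of the wearable IMU, offset from the
  video timebase by the (unknown, estimated) clock offset.

Angular velocity is deg/s, phases are radians, pixel coordinates are 0-based
with the origin at the top-left of the portrait frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Names of the four cyclic gait events carried as quadrature channels.
GAIT_EVENTS = (
    "left_foot_contact",
    "right_foot_contact",
    "left_toe_off",
    "right_toe_off",
)

#: Leg keypoints tracked by the pose pipeline, left-to-right, hip-to-ankle.
LEG_JOINTS = (
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

SIDES = ("left", "right")


def _as_1d(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


@dataclass
class GaitGroundTruth:
    """Known event times and gait parameters of a synthetic walking bout.

    Event times are on the world (= video) clock.  Per-leg arrays are keyed
    by side ("left" / "right").
    """

    foot_contacts: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]
    stride_durations: dict[str, np.ndarray]
    velocity_mps: float
    cadence_spm: float
    t_start: float
    t_end: float
    duration_s: float
    prosthetic_side: str = "right"

    def __post_init__(self) -> None:
        for side in SIDES:
            fc = self.foot_contacts[side] = _as_1d(self.foot_contacts[side])
            to = self.toe_offs[side] = _as_1d(self.toe_offs[side])
            self.stride_durations[side] = _as_1d(self.stride_durations[side])
            if np.any(np.diff(fc) <= 0) or np.any(np.diff(to) <= 0):
                raise ValueError(f"{side} event times must be strictly increasing")
            # toe off of a leg lies strictly inside that leg's stride
            n = min(len(to), len(fc) - 1)
            if n > 0 and not (
                np.all(to[:n] > fc[:n]) and np.all(to[:n] < fc[1 : n + 1])
            ):
                raise ValueError(f"{side} toe offs must fall strictly within strides")
        if not self.t_start < self.t_end:
            raise ValueError("segment must satisfy t_start < t_end")

    def swing_intervals(self, side: str) -> np.ndarray:
        """(n, 2) array of [toe_off, next foot contact] per stride of `side`."""
        fc = self.foot_contacts[side]
        to = self.toe_offs[side]
        n = min(len(to), len(fc) - 1)
        return np.column_stack([to[:n], fc[1 : n + 1]])

    def cadence_in_window(self, t_start: float, t_end: float, side: str | None = None) -> float:
        """Cadence (steps/min) over a window from same-leg contact intervals."""
        side = side or self.prosthetic_side
        fc = self.foot_contacts[side]
        inside = fc[(fc >= t_start) & (fc <= t_end)]
        if len(inside) < 2:
            raise ValueError("need at least two in-window contacts for cadence")
        return 120.0 * (len(inside) - 1) / (inside[-1] - inside[0])

    def to_dict(self) -> dict:
        return {
            "foot_contacts": {s: self.foot_contacts[s].tolist() for s in SIDES},
            "toe_offs": {s: self.toe_offs[s].tolist() for s in SIDES},
            "stride_durations": {s: self.stride_durations[s].tolist() for s in SIDES},
            "velocity_mps": self.velocity_mps,
            "cadence_spm": self.cadence_spm,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "duration_s": self.duration_s,
            "prosthetic_side": self.prosthetic_side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaitGroundTruth":
        return cls(
            foot_contacts={s: np.asarray(v, float) for s, v in d["foot_contacts"].items()},
            toe_offs={s: np.asarray(v, float) for s, v in d["toe_offs"].items()},
            stride_durations={s: np.asarray(v, float) for s, v in d["stride_durations"].items()},
            velocity_mps=d["velocity_mps"],
            cadence_spm=d["cadence_spm"],
            t_start=d["t_start"],
            t_end=d["t_end"],
            duration_s=d["duration_s"],
            prosthetic_side=d.get("prosthetic_side", "right"),
        )


@dataclass
class GyroTrace:
    """Timestamped shank gyroscope samples in the sensor timebase."""

    t: np.ndarray
    gyro_z: np.ndarray
    gyro_x: np.ndarray | None = None
    gyro_y: np.ndarray | None = None
    nominal_rate_hz: float = 562.5
    packet_host_times: np.ndarray | None = None
    packet_sample_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = _as_1d(self.t)
        self.gyro_z = _as_1d(self.gyro_z)
        if self.t.shape != self.gyro_z.shape:
            raise ValueError("time and gyro_z must have the same length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def rate_hz(self) -> float:
        """Empirical mean sampling rate."""
        if len(self.t) < 2:
            return self.nominal_rate_hz
        return (len(self.t) - 1) / (self.t[-1] - self.t[0])


@dataclass
class TimebaseFit:
    """OLS calibration of sample index against host (Android) time."""

    effective_rate_hz: float
    intercept_s: float
    residual_sd_s: float

    def __post_init__(self) -> None:
        if self.effective_rate_hz <= 0:
            raise ValueError("effective rate must be positive")

    def sample_time(self, index) -> np.ndarray:
        return self.intercept_s + np.asarray(index, float) / self.effective_rate_hz


@dataclass
class SwingEventList:
    """Detected swing intervals; interval ends are the foot-contact proxy."""

    intervals: np.ndarray  # (n, 2) [start, end]
    first_index: int | None = None  # i of the c_s formula, set by segment selection
    last_index: int | None = None  # j of the c_s formula

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if len(self.intervals):
            if np.any(self.intervals[:, 1] <= self.intervals[:, 0]):
                raise ValueError("swing intervals must have positive duration")
            flat = self.intervals.ravel()
            if np.any(np.diff(flat) < 0):
                raise ValueError("swing intervals must be disjoint and increasing")

    @property
    def ends(self) -> np.ndarray:
        """End-of-swing times s_i (foot-contact proxy)."""
        return self.intervals[:, 1] if len(self.intervals) else np.empty(0)

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0] if len(self.intervals) else np.empty(0)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GaitPhaseSeries:
    """Per-frame video-derived gait outputs at the video frame rate.

    `quadrature` maps each event in :data:`GAIT_EVENTS` to an (n, 2) array of
    (sin φ, cos φ); φ advances 0 → 2π between consecutive occurrences of that
    event, so the event itself sits at the positively directed zero crossing
    of the sin channel (cos ≈ +1 there).
    """

    frame_times: np.ndarray
    quadrature: dict[str, np.ndarray]
    phase_rate: np.ndarray  # stride-cycle dφ/dt, rad/s
    pelvis_velocity: np.ndarray  # m/s
    hip_angle: np.ndarray  # deg, prosthetic side
    knee_angle: np.ndarray  # deg, prosthetic side

    def __post_init__(self) -> None:
        self.frame_times = _as_1d(self.frame_times)
        n = len(self.frame_times)
        for name in GAIT_EVENTS:
            if name not in self.quadrature:
                raise ValueError(f"missing quadrature channel {name!r}")
            q = self.quadrature[name] = np.asarray(self.quadrature[name], float)
            if q.shape != (n, 2):
                raise ValueError(f"quadrature channel {name!r} must be (n, 2)")
            norm = q[:, 0] ** 2 + q[:, 1] ** 2
            if n and (norm.min() < 0.5 or norm.max() > 1.5):
                raise ValueError(
                    f"quadrature channel {name!r} leaves the unit-circle sanity "
                    "band [0.5, 1.5]"
                )
        for arr_name in ("phase_rate", "pelvis_velocity", "hip_angle", "knee_angle"):
            arr = _as_1d(getattr(self, arr_name))
            setattr(self, arr_name, arr)
            if len(arr) != n:
                raise ValueError(f"{arr_name} length mismatch")

    @property
    def fps(self) -> float:
        if len(self.frame_times) < 2:
            return float("nan")
        return (len(self.frame_times) - 1) / (self.frame_times[-1] - self.frame_times[0])

    def contact_channel(self, side: str) -> np.ndarray:
        return self.quadrature[f"{side}_foot_contact"]


@dataclass
class TimedSegment:
    """Annotated 10-m timed walking window with its manual ground truth."""

    t_start: float
    t_end: float
    distance_m: float = 10.0
    view: str = "frontal"
    segment_id: str = ""

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.distance_m <= 0:
            raise ValueError("distance must be positive")

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start

    @property
    def ground_truth_velocity(self) -> float:
        """Annotated velocity: marked distance over elapsed time."""
        return self.distance_m / self.duration_s


@dataclass
class KeypointTrack:
    """Per-frame leg keypoints in pixels with per-joint confidence."""

    frame_times: np.ndarray
    x: np.ndarray  # (n_frames, n_joints)
    y: np.ndarray
    confidence: np.ndarray
    joints: tuple[str, ...] = LEG_JOINTS
    width_px: int = 1080
    height_px: int = 1920
    prosthetic_side: str = "right"

    def __post_init__(self) -> None:
        self.frame_times = _as_1d(self.frame_times)
        n = len(self.frame_times)
        for name in ("x", "y", "confidence"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            if arr.shape != (n, len(self.joints)):
                raise ValueError(f"{name} must be (n_frames, n_joints)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        if np.any(self.confidence < 0) or np.any(self.confidence > 1):
            raise ValueError("confidences must lie in [0, 1]")

    def joint_index(self, joint: str) -> int:
        return self.joints.index(joint)

    def ankle_confidence(self, side: str) -> np.ndarray:
        return self.confidence[:, self.joint_index(f"{side}_ankle")]


@dataclass
class SegmentQuality:
    """Keypoint-quality summary used by the inclusion rules."""

    ankle_confidence: float
    clipped_fraction: float
    clipped: bool
    included: bool | None = None
    segment_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.clipped_fraction <= 1.0:
            raise ValueError("clipped fraction must lie in [0, 1]")


@dataclass
class OffsetEstimate:
    """Video→sensor clock offset: add it to video times to get sensor times."""

    offset_s: float
    objective: float
    search_range_s: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.search_range_s
        if not lo <= self.offset_s <= hi:
            raise ValueError("offset must lie within the search range")


@dataclass
class MatchResult:
    """One-to-one matching of sensor end-of-swing to video foot contacts."""

    offset_s: float  # video lead over sensor end-of-swing (typically positive)
    pairs: np.ndarray  # (n, 2) [sensor_time, video_time]
    residuals: np.ndarray  # video - offset - sensor, seconds
    n_missed: int
    window_s: float = 0.5

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, float).reshape(-1, 2)
        self.residuals = _as_1d(self.residuals) if np.size(self.residuals) else np.empty(0)
        if len(self.residuals) and np.max(np.abs(self.residuals)) > self.window_s + 1e-12:
            raise ValueError("matched residuals must lie within the matching window")

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def detected_fraction(self) -> float:
        total = self.n_matched + self.n_missed
        return self.n_matched / total if total else float("nan")

    @property
    def mae_s(self) -> float:
        return float(np.mean(np.abs(self.residuals))) if len(self.residuals) else float("nan")


@dataclass
class AgreementSummary:
    """Pearson r / MAE agreement between paired per-segment estimates."""

    r: float
    mae: float
    n: int
    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        if not (np.isnan(self.r) or -1.0 <= self.r <= 1.0 + 1e-12):
            raise ValueError("r must lie in [-1, 1]")
        if self.mae < 0:
            raise ValueError("MAE must be non-negative")
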