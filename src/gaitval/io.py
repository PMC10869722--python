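"""Plain-text file formats for scenario directories.

Sensor traces, phase series, and keypoints travel as CSV; ground truth,
segment annotations, configs, and summaries as JSON.  Schemas are stable so
externally produced files with the same columns can be dropped in.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    GAIT_EVENTS,
    GaitGroundTruth,
    GaitPhaseSeries,
    GyroTrace,
    KeypointTrack,
    LEG_JOINTS,
    SwingEventList,
    TimedSegment,
)

__all__ = [
    "write_gyro_csv", "read_gyro_csv",
    "write_phase_csv", "read_phase_csv",
    "write_keypoints_csv", "read_keypoints_csv",
    "write_truth_json", "read_truth_json",
    "write_segments_json", "read_segments_json",
    "write_swings_csv", "read_swings_csv",
]

_FLOAT_FMT = "%.6f"


def write_gyro_csv(trace: GyroTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.t,
            "gyro_x": trace.gyro_x if trace.gyro_x is not None else np.zeros_like(trace.t),
            "gyro_y": trace.gyro_y if trace.gyro_y is not None else np.zeros_like(trace.t),
            "gyro_z": trace.gyro_z,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_gyro_csv(path: str | Path, nominal_rate_hz: float = 562.5) -> GyroTrace:
    df = pd.read_csv(path)
    return GyroTrace(
        t=df["time_s"].to_numpy(),
        gyro_z=df["gyro_z"].to_numpy(),
        gyro_x=df["gyro_x"].to_numpy() if "gyro_x" in df else None,
        gyro_y=df["gyro_y"].to_numpy() if "gyro_y" in df else None,
        nominal_rate_hz=nominal_rate_hz,
    )


def write_phase_csv(series: GaitPhaseSeries, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(len(series.frame_times)),
        "time_s": series.frame_times,
    }
    for name in GAIT_EVENTS:
        cols[f"{name}_sin"] = series.quadrature[name][:, 0]
        cols[f"{name}_cos"] = series.quadrature[name][:, 1]
    cols["phase_rate"] = series.phase_rate
    cols["pelvis_vel"] = series.pelvis_velocity
    cols["hip_ang"] = series.hip_angle
    cols["knee_ang"] = series.knee_angle
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_phase_csv(path: str | Path) -> GaitPhaseSeries:
    df = pd.read_csv(path)
    quad = {
        name: np.column_stack([df[f"{name}_sin"], df[f"{name}_cos"]])
        for name in GAIT_EVENTS
    }
    return GaitPhaseSeries(
        frame_times=df["time_s"].to_numpy(),
        quadrature=quad,
        phase_rate=df["phase_rate"].to_numpy(),
        pelvis_velocity=df["pelvis_vel"].to_numpy(),
        hip_angle=df["hip_ang"].to_numpy(),
        knee_angle=df["knee_ang"].to_numpy(),
    )


def write_keypoints_csv(track: KeypointTrack, path: str | Path) -> None:
    n, j = track.x.shape
    frames = np.repeat(np.arange(n), j)
    df = pd.DataFrame(
        {
            "frame": frames,
            "time_s": np.repeat(track.frame_times, j),
            "joint": list(track.joints) * n,
            "x_px": track.x.ravel(),
            "y_px": track.y.ravel(),
            "confidence": track.confidence.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_keypoints_csv(path: str | Path, prosthetic_side: str = "right") -> KeypointTrack:
    df = pd.read_csv(path)
    wide = df.pivot(index="frame", columns="joint")
    joints = [j for j in LEG_JOINTS if j in wide["x_px"].columns]
    frame_times = df.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
    return KeypointTrack(
        frame_times=frame_times,
        x=wide["x_px"][joints].to_numpy(),
        y=wide["y_px"][joints].to_numpy(),
        confidence=wide["confidence"][joints].to_numpy(),
        joints=tuple(joints),
        prosthetic_side=prosthetic_side,
    )


def write_truth_json(truth: GaitGroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))


def read_truth_json(path: str | Path) -> GaitGroundTruth:
    return GaitGroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_segments_json(segments: list[TimedSegment], path: str | Path) -> None:
    data = [
        {
            "segment_id": s.segment_id,
            "t_start_s": s.t_start,
            "t_end_s": s.t_end,
            "distance_m": s.distance_m,
            "view": s.view,
        }
        for s in segments
    ]
    Path(path).write_text(json.dumps(data, indent=2))


def read_segments_json(path: str | Path) -> list[TimedSegment]:
    data = json.loads(Path(path).read_text())
    return [
        TimedSegment(
            t_start=d["t_start_s"],
            t_end=d["t_end_s"],
            distance_m=d.get("distance_m", 10.0),
            view=d.get("view", "frontal"),
            segment_id=d.get("segment_id", ""),
        )
        for d in data
    ]


def write_swings_csv(swings: SwingEventList, path: str | Path) -> None:
    pd.DataFrame(
        {"swing_start_s": swings.starts, "swing_end_s": swings.ends}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_swings_csv(path: str | Path) -> SwingEventList:
    df = pd.read_csv(path)
    return SwingEventList(
        intervals=np.column_stack([df["swing_start_s"], df["swing_end_s"]])
    )
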