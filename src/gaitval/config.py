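"""Configuration schemas for synthetic scenarios and pipeline runs.

Every threshold that the analysis depends on lives here with its default, so
a sensitivity analysis (say quality threshold 0.6 instead of 0.7) is a single
overridden field in a YAML file rather than a code change.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class SyntheticConfig(BaseModel):
    """Parameters of one synthetic paired sensor + video recording.

    Defaults emulate a typical self-selected-speed walking bout of a
    unilateral lower-limb prosthesis user recorded with a phone camera and a
    shank-mounted IMU: cadence ~100 steps/min, ~1 m/s, 5% stride-time
    variability, moderate gyro noise, and a ~170 ms sensor/video clock skew.
    """

    cadence_spm: float = Field(100.0, gt=0, description="mean cadence, steps/min")
    stride_cv: float = Field(0.05, ge=0, lt=0.3, description="stride-time coefficient of variation")
    velocity_mps: float = Field(1.0, gt=0, description="mean walking velocity, m/s")
    stance_fraction: float = Field(0.62, gt=0, lt=1, description="stance share of the stride cycle")
    duration_s: float = Field(20.0, gt=0, description="recording length, s")
    sensor_rate_hz: float = Field(562.5, gt=0, description="IMU sampling rate, Hz")
    video_fps: float = Field(30.0, gt=0, description="video frame rate, Hz")
    clock_offset_s: float = Field(0.17, description="sensor time minus video time, s")
    gyro_noise_sd_dps: float = Field(10.0, ge=0, description="additive gyro noise SD, deg/s")
    glitch_probability: float = Field(0.0, ge=0, le=1, description="toe-catch probability per swing")
    glitch_duration_s: float = Field(0.12, gt=0, lt=0.36, description="toe-catch pulse duration, s")
    swing_peak_dps: float = Field(300.0, gt=0, description="peak shank angular velocity in swing, deg/s")
    stance_dip_dps: float = Field(20.0, gt=0, description="depth of the negative stance dip, deg/s")
    velocity_modulation_mps: float = Field(0.0, ge=0, description="within-stride pelvis-velocity ripple amplitude, m/s")
    edge_proximity: bool = Field(False, description="place some keypoints near the image border")
    edge_fraction: float = Field(0.05, ge=0, le=1, description="fraction of frames with a near-edge leg keypoint")
    ankle_confidence: float = Field(0.85, ge=0, le=1, description="mean prosthetic-ankle keypoint confidence")
    prosthetic_side: Literal["left", "right"] = "right"
    segment_distance_m: float = Field(10.0, gt=0, description="timed-walk marked distance, m")
    segment_view: Literal["frontal", "sagittal", "mixed"] = "frontal"
    seed: int = Field(0, ge=0, description="generator seed; fixed seed => identical output")

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        stride_s = 120.0 / self.cadence_spm
        if self.glitch_duration_s >= (1 - self.stance_fraction) * stride_s:
            raise ValueError("glitch must be shorter than the swing it perturbs")
        return self


class PipelineParams(BaseModel):
    """Processing constants of the analysis stages."""

    filter_order: int = Field(8, ge=1, description="Chebyshev low-pass order")
    filter_cutoff_hz: float = Field(35.0, gt=0, description="low-pass cutoff, Hz")
    filter_ripple_db: float = Field(0.5, gt=0, description="Type-I passband ripple, dB")
    median_span_s: float = Field(0.36, gt=0, description="deglitching median-filter span, s")
    quality_threshold: float = Field(0.7, ge=0, le=1, description="minimum mean prosthetic-ankle confidence")
    clip_margin_px: int = Field(10, ge=0, description="border margin that flags a frame as clipped, px")
    clip_fraction: float = Field(0.01, ge=0, le=1, description="clipped-frame fraction that excludes a segment")
    match_window_s: float = Field(0.5, gt=0, description="event-matching detection window, s")
    match_offset_range_s: float = Field(0.4, gt=0, description="half-range of the match-offset grid, s")
    match_offset_step_s: float = Field(0.001, gt=0, description="match-offset grid step, s")
    clock_offset_range_s: float = Field(0.5, gt=0, description="half-range of the clock-offset grid, s")
    clock_offset_step_s: float = Field(0.001, gt=0, description="clock-offset grid step, s")
    window_frames: int = Field(90, ge=2, description="sliding-window length for model inference, frames")


class RunConfig(BaseModel):
    """A reproducible scenario run: what to simulate and how to analyse it."""

    scenario_dir: Path = Path("scenarios")
    out_dir: Path = Path("results")
    seed: int = Field(1, ge=0)
    n_scenarios: int = Field(1, ge=1)
    cadence_range_spm: tuple[float, float] = (70.0, 130.0)
    velocity_range_mps: tuple[float, float] = (0.4, 1.6)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    params: PipelineParams = Field(default_factory=PipelineParams)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.model_dump(mode="json")
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
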