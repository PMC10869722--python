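"""Scenario orchestration: simulate, validate, report.

A *scenario* is one synthetic paired recording in its own directory
(sensor.csv, phase.csv, keypoints.csv, truth.json, segments.json,
config.json).  ``run_simulate`` writes scenarios from a RunConfig,
``run_validate`` replays the full sensor → video → matching analysis over
them and writes per-segment metrics plus a JSON summary, and ``run_report``
renders the summary the way the validation figures report it: r, MAE and n
per metric, stratified by view and inclusion status.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, matching, sensor, synthetic, video
from .config import RunConfig, SyntheticConfig
from .types import SwingEventList

log = logging.getLogger("gaitval")

__all__ = ["run_simulate", "run_validate", "run_report", "validate_scenario"]


def _scenario_configs(config: RunConfig) -> list[SyntheticConfig]:
    """Per-scenario synthetic configs; sweeps draw cadence/velocity uniformly."""
    base = config.synthetic
    if config.n_scenarios == 1:
        return [base.model_copy(update={"seed": config.seed})]
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_scenarios):
        cadence = rng.uniform(*config.cadence_range_spm)
        velocity = rng.uniform(*config.velocity_range_mps)
        duration = max(
            base.duration_s,
            1.5 + base.segment_distance_m / velocity + 2.5,
        )
        out.append(
            base.model_copy(
                update={
                    "cadence_spm": float(cadence),
                    "velocity_mps": float(velocity),
                    "duration_s": float(duration),
                    "seed": int((config.seed * 1009 + i) % 2**31),
                }
            )
        )
    return out


def run_simulate(config: RunConfig) -> Path:
    """Write every scenario of `config` under its scenario directory.

    Each scenario directory holds the three signal CSVs and three JSONs;
    a manifest at the root records all seeds and parameters.
    """
    root = Path(config.scenario_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "scenarios": []}
    for i, sc in enumerate(_scenario_configs(config)):
        d = root / f"scenario_{i:03d}"
        d.mkdir(parents=True, exist_ok=True)
        truth, gyro, series, track, segment = synthetic.generate_scenario(sc)
        io.write_gyro_csv(gyro, d / "sensor.csv")
        io.write_phase_csv(series, d / "phase.csv")
        io.write_keypoints_csv(track, d / "keypoints.csv")
        io.write_truth_json(truth, d / "truth.json")
        io.write_segments_json([segment], d / "segments.json")
        (d / "config.json").write_text(sc.model_dump_json(indent=2))
        manifest["scenarios"].append({"dir": d.name, **sc.model_dump(mode="json")})
        log.info("simulated %s: cadence %.1f spm, velocity %.2f m/s, seed %d",
                 d.name, sc.cadence_spm, sc.velocity_mps, sc.seed)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root


def validate_scenario(scenario_dir: str | Path, config: RunConfig) -> list[dict]:
    """Run the full analysis over one scenario directory; one row per segment."""
    d = Path(scenario_dir)
    params = config.params
    for required in ("sensor.csv", "phase.csv", "keypoints.csv", "segments.json"):
        if not (d / required).exists():
            raise FileNotFoundError(f"{d / required} is missing")
    sc = SyntheticConfig.model_validate_json((d / "config.json").read_text()) \
        if (d / "config.json").exists() else config.synthetic
    side = sc.prosthetic_side

    def _stage(label, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {label!r} failed in {d.name}: {exc}") from exc

    trace = _stage("read_sensor", io.read_gyro_csv, d / "sensor.csv", sc.sensor_rate_hz)
    swings = _stage("detect_swings", sensor.detect_swings, trace, params)
    series = _stage("read_phase", io.read_phase_csv, d / "phase.csv")
    track = _stage("read_keypoints", io.read_keypoints_csv, d / "keypoints.csv", side)
    segments = _stage("read_segments", io.read_segments_json, d / "segments.json")
    clock = _stage("estimate_clock_offset", matching.estimate_clock_offset,
                   trace, series, params)
    log.info("%s: %d swings, clock offset %.1f ms", d.name, len(swings),
             1e3 * clock.offset_s)

    # move sensor events onto the video timebase for segment bookkeeping
    swings_video = SwingEventList(intervals=swings.intervals - clock.offset_s)
    contacts = _stage("decode_foot_contacts", video.decode_foot_contacts, series, side)

    rows = []
    for seg in segments:
        seg_swings = sensor.swings_in_segment(swings_video, seg)
        c_s = matching.compute_sensor_cadence(seg_swings, seg)
        c_v = video.compute_video_cadence(series, seg)
        v_est = video.compute_segment_velocity(series, seg)
        quality = video.flag_clipping(track, seg, params)
        near = contacts[
            (contacts >= seg.t_start - params.match_window_s)
            & (contacts <= seg.t_end + params.match_window_s)
        ]
        if len(seg_swings):
            match = matching.match_events(
                seg_swings.ends, near, params.match_window_s, params
            )
            n_matched, n_missed = match.n_matched, match.n_missed
            residual_mae, det_frac, m_off = match.mae_s, match.detected_fraction, match.offset_s
        else:
            n_matched = n_missed = 0
            residual_mae = det_frac = m_off = float("nan")
        rows.append(
            {
                "scenario": d.name,
                "segment_id": seg.segment_id or d.name,
                "view": seg.view,
                "v_video": v_est,
                "v_truth": seg.ground_truth_velocity,
                "c_v": c_v,
                "c_s": np.nan if c_s is None else c_s,
                "n_matched": n_matched,
                "n_missed": n_missed,
                "residual_mae_s": residual_mae,
                "detected_fraction": det_frac,
                "match_offset_s": m_off,
                "clock_offset_s": clock.offset_s,
                "ankle_confidence": quality.ankle_confidence,
                "clipped_fraction": quality.clipped_fraction,
                "clipped": quality.clipped,
                "included": bool(
                    quality.ankle_confidence >= params.quality_threshold
                    and not quality.clipped
                ),
            }
        )
        log.info(
            "%s %s: c_v %.1f, c_s %s, v %.2f/%.2f, matched %d missed %d, included %s",
            d.name, seg.segment_id, c_v, f"{c_s:.1f}" if c_s else "undef",
            v_est, seg.ground_truth_velocity, n_matched, n_missed, rows[-1]["included"],
        )
    return rows


def _agreement(df: pd.DataFrame, a: str, b: str) -> dict:
    sub = df[[a, b]].dropna()
    if len(sub) == 0:
        return {"r": None, "mae": None, "n": 0}
    s = matching.summarize_agreement(sub.to_numpy())
    return {"r": None if np.isnan(s.r) else s.r, "mae": s.mae, "n": s.n}


def summarize_metrics(df: pd.DataFrame) -> dict:
    """Cohort summary over the per-segment metric rows."""
    inc = df[df["included"]]
    total_matched = int(df["n_matched"].sum())
    total_missed = int(df["n_missed"].sum())
    summary = {
        "segments_total": int(len(df)),
        "segments_included": int(len(inc)),
        "segments_excluded": int(len(df) - len(inc)),
        "segments_clipped": int(df["clipped"].sum()),
        "events_matched": total_matched,
        "events_missed": total_missed,
        "detected_fraction": (
            total_matched / (total_matched + total_missed)
            if total_matched + total_missed else None
        ),
        "velocity": _agreement(inc, "v_video", "v_truth"),
        "cadence": _agreement(inc, "c_v", "c_s"),
        "velocity_all": _agreement(df, "v_video", "v_truth"),
        "cadence_all": _agreement(df, "c_v", "c_s"),
        "residual_mae_s": (
            float(inc["residual_mae_s"].dropna().mean())
            if len(inc["residual_mae_s"].dropna()) else None
        ),
        "residual_mae_s_all": (
            float(df["residual_mae_s"].dropna().mean())
            if len(df["residual_mae_s"].dropna()) else None
        ),
    }
    return summary


def run_validate(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Validate every scenario; write metrics.csv and summary.json."""
    root = Path(config.scenario_dir)
    if not root.exists():
        raise FileNotFoundError(f"scenario directory {root} does not exist")
    dirs = sorted(p for p in root.iterdir() if p.is_dir() and p.name.startswith("scenario_"))
    if not dirs:
        raise FileNotFoundError(f"no scenario_* directories under {root}")
    rows: list[dict] = []
    for d in dirs:
        rows.extend(validate_scenario(d, config))
    df = pd.DataFrame(rows)
    summary = summarize_metrics(df)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "metrics.csv", index=False, float_format="%.6f")
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return df, summary


def _fmt(x, unit="") -> str:
    return "undefined" if x is None else f"{x:.3f}{unit}"


def run_report(metrics: pd.DataFrame | str | Path) -> str:
    """Human-readable agreement report, stratified by view and inclusion."""
    df = pd.read_csv(metrics) if isinstance(metrics, (str, Path)) else metrics
    lines = ["Gait validation report", "======================"]
    if len(df) == 0:
        lines.append("no segments")
        return "\n".join(lines)
    for view in sorted(df["view"].unique()):
        for included in (True, False):
            sub = df[(df["view"] == view) & (df["included"] == included)]
            if len(sub) == 0:
                continue
            label = f"{view}, {'included' if included else 'excluded'}"
            vel = _agreement(sub, "v_video", "v_truth")
            cad = _agreement(sub, "c_v", "c_s")
            res = sub["residual_mae_s"].dropna()
            lines.append(f"\n[{label}]  n = {len(sub)} segments")
            lines.append(
                f"  velocity: r = {_fmt(vel['r'])}, MAE = {_fmt(vel['mae'], ' m/s')}"
            )
            lines.append(
                f"  cadence:  r = {_fmt(cad['r'])}, MAE = {_fmt(cad['mae'], ' steps/min')}"
            )
            lines.append(
                "  foot-contact residual MAE = "
                + (_fmt(float(res.mean()), " s") if len(res) else "undefined")
            )
    if not df["included"].any():
        lines.append("\nno segments passed the inclusion rules")
    return "\n".join(lines)
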