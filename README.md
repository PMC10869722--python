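# gaitval

Validation tooling for smartphone-video gait analysis in lower-limb
prosthesis users, checked against a shank-mounted inertial sensor.

Clinical gait metrics — walking velocity, cadence, and foot-contact timing —
can be estimated from an ordinary phone video via pose estimation and a
sequence model, but those estimates need a reference. This package
implements the complete analysis that performs such a validation:

* **Sensor side** — detect prosthetic-limb swings from the shank gyroscope
  z-channel (8th-order Chebyshev-I low pass at 35 Hz, rectification, 360 ms
  median deglitching; positive runs are swings), take each swing's end as a
  foot-contact proxy, and calibrate the sensor timebase against host time by
  linear regression.
* **Video side** — stitch sliding-window (90-frame) model outputs into a
  per-frame series; decode cyclic gait events from their quadrature
  encoding (sin φ, cos φ), where an event is the positively directed zero
  crossing of sin φ with cos φ > 0; integrate the phase rate into cadence;
  time-average pelvis velocity over annotated 10-m segments; and apply
  keypoint-quality rules (frames clipped within 10 px of the image border,
  segments excluded above 1% clipped frames or below 0.7 mean prosthetic-
  ankle confidence).
* **Synchronization and agreement** — recover the video–sensor clock offset
  by sliding the derivative of the video-derived hip+knee sagittal angle
  against the gyro (z-scored MSE over a 1 ms grid), match sensor
  end-of-swing to video foot contacts one-to-one within a 0.5 s window, and
  summarize agreement as Pearson r, MAE, and detected fraction.

The key per-segment estimators are

```
c_v = 120 / (2π (t_e − t_s)) ∫ ω̇(t) dt        (video cadence, steps/min)
c_s = 120 (j − i) / (s_j − s_i)                (sensor cadence, steps/min)
v   = ⟨pelvis velocity⟩ over [t_s, t_e]        vs  v_ref = distance / (t_e − t_s)
```

where ω̇ is the stride-phase rate and s_i … s_j are the prosthetic-limb
end-of-swing times inside the timed segment.

Because the underlying clinical recordings are not public, the package
ships a first-class synthetic gait generator (`gaitval.synthetic`) that
emits paired sensor/video recordings with known ground truth — stride-time
variability, clock offset, gyro noise, mid-swing toe-catch reversals, and
near-edge keypoints — so the whole pipeline is testable end to end.

## Worked example

```sh
gaitval simulate --seed 3 --out scenarios
gaitval validate --scenarios scenarios --out results
gaitval report results/metrics.csv
```

prints

```
Gait validation report
======================

[frontal, included]  n = 1 segments
  velocity: r = undefined, MAE = 0.000 m/s
  cadence:  r = undefined, MAE = 1.204 steps/min
  foot-contact residual MAE = 0.008 s
```

One default scenario (cadence 100 steps/min, 1 m/s, 5% stride CV, 10 deg/s
gyro noise, 170 ms clock offset) was simulated and analysed: the estimated
velocity matches the annotated 10-m velocity to the printed precision,
video and sensor cadence agree within ~1 step/min, and foot contacts
decoded from video land within ~8 ms of the sensor's end-of-swing events
after synchronization (r is undefined with a single segment). With more
scenarios (`--n-scenarios`), the report adds Pearson r per metric and
stratifies by camera view and inclusion status.

The same flow is available as a library:

```python
from gaitval import RunConfig, run_simulate, run_validate

cfg = RunConfig(seed=3, n_scenarios=10)
run_simulate(cfg)
metrics, summary = run_validate(cfg)
```

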