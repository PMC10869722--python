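# Methods

This note documents the models, parameter choices, and numerical decisions
behind `gaitval`, and what its synthetic validation does and does not show
about real recordings.

## The validation problem

A phone video and a shank-mounted IMU record the same walking bout on two
clocks. The video side yields per-frame gait outputs — quadrature-encoded
cyclic event phases, a stride-phase rate, pelvis velocity, and hip/knee
sagittal angles — at 30 fps; the sensor side yields 3-axis gyroscope data
at a nominal 562.5 Hz, timestamped per BLE packet by the host. Validation
means: put both on one clock, detect the prosthetic limb's gait events
independently on each side, and quantify agreement in foot-contact timing,
cadence, and walking velocity over annotated 10-m segments.

## Sensor-side model

**Timebase calibration.** Host time is regressed on sample index (OLS);
the reciprocal slope is the effective sampling rate, typically 1–2 Hz off
nominal. Fewer than two packets, or packets with zero index spread, are
errors rather than degenerate fits.

**Swing detection.** The gyro z-channel (normal to the sagittal plane for a
laterally mounted sensor) is low-pass filtered with an 8th-order Chebyshev
type-I filter, 35 Hz cutoff, 0.5 dB passband ripple; negatives are zeroed;
a 360 ms median filter removes brief sign reversals from toe catches; and
contiguous strictly positive runs are swings. End of swing — the forward
shank rotation stopping — is the foot-contact proxy, and precedes true
contact slightly.

Numerical choices:

* The filter is applied forward–backward (`sosfiltfilt`). Zero-phase
  filtering costs nothing here and avoids shifting event times by the
  filter's group delay; the filter is designed at order 8, and the doubled
  effective attenuation is irrelevant because timing, not magnitude
  fidelity, is consumed downstream.
* Chebyshev type and ripple are configurable (`PipelineParams`); type I
  with 0.5 dB is the conventional default, with the cutoff read as the
  passband edge.
* The median window is the span in samples rounded up to odd (203 samples
  at 562.5 Hz). A running median of span w fills an opposite-sign gap only
  when the gap is shorter than w/2, so reversals up to ~180 ms are removed;
  this comfortably covers brief toe-catch scuffs while leaving the
  0.4–0.6 s swing and stance phases untouched.
* Transition times are taken at the first sample of the new sign; one
  sample is 1.8 ms, far below every error bound that matters.
* Segment membership uses the end-of-swing time on a closed interval.

## Video-side model

The trained sequence model is out of scope; its defined computation is
implemented around a caller-supplied window model. `assemble_sliding_window`
runs a 90-frame (3 s) window across the sequence, taking the centre output
row per position and padding the first and last 45 frames from the first
and last windows.

**Event decoding.** Each cyclic event is carried as (sin φ, cos φ) with
φ = 0 at the event. Events are the positively directed zero crossings of
sin φ, located sub-frame by linear interpolation; crossings with a negative
interpolated cos φ are rejected, because on a noisy circle sin crosses zero
upward twice per cycle and only the φ ≈ 0 crossing (cos ≈ +1) is the event.
This gate is exact on clean signals and necessary on noisy ones.

**Cadence and velocity.** c_v integrates the stride-phase rate over the
segment (trapezoid over frames, partial end frames by linear
interpolation) and converts strides to steps/min; segment velocity is the
trapezoidal time-average of the pelvis-velocity channel, compared against
distance/(t_e − t_s) from the manual annotation.

**Quality rules.** A frame is clipped when any leg keypoint lies within
10 px of the image border (1080 × 1920 portrait); a segment is clipped when
more than 1% of its frames are; a segment enters the agreement summaries
only if not clipped and its mean prosthetic-ankle confidence is ≥ 0.7
(strictly-below excludes; the boundary is kept). Bilateral cases would
average both prosthetic ankles.

## Synchronization and matching

Two offsets are deliberately estimated independently, mirroring their
distinct physical origins:

* **Clock offset** (video start latency, ~170 ms): the derivative of the
  summed hip+knee sagittal angle (central differences at 30 fps) tracks
  shank angular velocity up to scale. Both signals are resampled to a
  common 200 Hz grid, z-scored, and the mean squared difference is
  minimized over a 1 ms offset grid spanning ±0.5 s. A grid search is used
  instead of a continuous optimizer because the objective has plateaus and
  local dips; 1 ms resolution is far below the video frame period. The gyro
  is pre-filtered with the same 35 Hz low pass to keep the objective smooth
  under sensor noise. Flat angle channels or under 3 s of overlap are
  errors.
* **Match offset** (end of swing precedes foot contact, ~100 ms): per
  segment, the video events' lead over the sensor events is fit on a 1 ms
  grid over ±0.4 s minimizing the mean absolute nearest-neighbour residual;
  matching is then greedy one-to-one in ascending |residual| within a 0.5 s
  window. At gait event spacing (≥ 0.4 s between same-type events) greedy
  and optimal assignment coincide except in pathological inputs. Least
  absolute error (not least squares) defines "closest matches"; the choice
  is recorded in config by the grid objective.

Unmatched sensor events count as missed; detected fraction is
matched/(matched+missed); residual MAE is over matched pairs. Agreement per
metric is Pearson r and MAE over included segments; r is reported as
undefined (NaN) below two pairs or under zero variance.

## Synthetic data generator

The generator emulates a self-selected-speed clinic walking bout of a
unilateral prosthesis user:

| parameter | default | rationale |
|---|---|---|
| cadence | 100 steps/min | typical for prosthesis users, slower than able-bodied 110–120 |
| stride-time CV | 0.05 | moderate clinical variability |
| velocity | 1.0 m/s | mid community-ambulator range |
| stance fraction | 0.62 | typical human gait |
| swing gyro peak | 300 deg/s | shank angular velocity at comfortable speed |
| stance dip | −20 deg/s | small negative bias so crossings are unambiguous |
| gyro noise SD | 10 deg/s | moderate MEMS + soft-tissue noise |
| clock offset | 0.17 s | observed video start latency scale |
| glitch duration | 0.12 s | a brief toe-catch scuff |
| ankle confidence | 0.85 | good-quality tracking level |

Stride durations are truncated-normal (±3 SD) so durations stay positive;
the contralateral leg steps half a stride later, which smooths its stride
series slightly relative to the prosthetic side's i.i.d. draws. The
timed segment starts 0.5 s after the first contact and spans
distance/velocity when the recording allows, with the annotated distance
always equal to velocity × elapsed time.

The gyro template is a half-sine swing lobe over each swing and a shallow
negative half-sine dip over each stance, hence continuous and exactly zero
at toe off and foot contact — a constant stance level would put a step
discontinuity at the crossing and bias the filtered event time. Toe-catch
glitches invert the lobe locally and smoothly (g → −g·cos(2πu/d) within
the pulse), so the signed reversal lasts about half the configured pulse
duration regardless of where in the lobe it lands; this is what a brief
toe-catch deceleration looks like and keeps configured pulses up to 0.35 s
within the median filter's removal range. Hip and knee angles integrate
the noiseless template (split 35/65 between joints, linearly detrended to
stay bounded), so their summed derivative equals the shank angular velocity
up to an additive constant — exactly the structure the clock-offset
estimator exploits. Within-stride pelvis-velocity modulation exists as an
option but defaults to off; its realism is untested, and with it off the
velocity channel is exactly the configured speed.

All streams derive from per-component child seeds of one scenario seed and
are bit-reproducible.

**What passing does not show.** The generator's video outputs are idealized
model outputs: quadrature channels are a clean unit circle, pelvis velocity
has no bias, keypoints never swap to a bystander, and the angle channels
match the gyro by construction. Passing therefore validates the *analysis*
— detection, decoding, synchronization, matching, filtering, and the
formulas — under known truth; it says nothing about the accuracy of a
trained pose or gait model on real video, which is exactly what the
clinical study this analysis serves must measure.

## Problem sizes

Default recordings are 20 s (one 10-m segment); the validation sweep uses
50 scenarios spanning cadence 70–130 steps/min and velocity 0.4–1.6 m/s,
auto-sizing each recording to fit its 10-m segment (up to ~29 s at
0.4 m/s). These sizes give every segment 8–20 strides — enough for stable
cadence and residual statistics while keeping a full sweep to seconds.

## Known limitations

* `swings_in_segment` and the cadence formulas assume the prosthetic side;
  bilateral users would need per-side event streams.
* The clock-offset estimator assumes the hip+knee derivative correlates
  with the shank gyro within the search range; severely degraded angle
  channels would need the cross-correlation fallback the tests use as an
  oracle.
* No Kalman smoothing of decoded events: raw zero crossings are used, and
  whether smoothing changes timing materially on real model outputs is
  untested here.
* Sagittal-view velocity correction, step-length validation, and joint
  kinematics are out of scope.
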