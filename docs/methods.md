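# Methods

## The problem and the model

A cockroach carrying an inertial backpack explores a circular arena
(80 cm diameter, coordinates normalized to the unit disk).  Left alone
it alternates between walking and long stops, and spends most of its
moving time following the wall.  The closed-loop system watches the
6-channel IMU stream (longitudinal/lateral/vertical acceleration a_x,
a_y, a_z; roll/pitch/yaw rate g_x, g_y, g_z), classifies each 1.5-s
window as *stop* or *move*, and after one second of confirmed stop
applies a short electrical burst to the cerci that usually re-triggers
walking.  The package implements this whole analysis offline, replacing
the animals with a behavioral simulator so that every stage can be
exercised and scored deterministically.

## Behavior simulator

Locomotion is a discrete-time Markov state machine at the IMU rate
(20 Hz; a 1.5-s window is exactly 30 samples).  Per-second transition
probabilities p are converted to per-step probabilities via
p_step = 1 − (1 − p)^(1/rate).  The walker starts at the center in the
move state.

* **Central zone** (r < 0.9): heading-diffusion random walk —
  heading += N(0, σ²·dt) with σ² the heading diffusion, position
  advances by speed·dt along the heading.
* **Peripheral zone** (r ≥ 0.9, the 4-cm annulus on a 40-cm radius):
  wall following — tangential motion with persistent handedness
  (kept with probability 0.99 per step), small radial jitter clipped to
  the band, and exit events that point the heading inward.
* **Stops** freeze the position; spontaneous stop→move and move→stop
  transitions occur with per-animal rates.
* The wall is handled with a standoff at r = 0.995, so positions always
  satisfy x² + y² < 1 and the zone label (peripheral ⇔ r ≥ 0.9) is a
  pure function of position.

The per-animal activity profiles differ only in the spontaneous
stop→move rate: inactive 0.005/s, intermediate 0.02/s, active 0.08/s
for the three test animals, and 0.01/s / 0.06/s for the two training
animals (training and test animals are disjoint, mirroring the original
protocol).  The shared defaults are: move→stop 0.05/s, exit 0.05/s,
speed 0.1 normalized units/s (4 cm/s — chosen so free-trial path
lengths over 7 minutes fall in the recorded 5–50 range), heading
diffusion 1.0 rad²/s, and stimulation response probability 0.9 per
burst.  These rates are free parameters of the generator — the original
study reports no transition numbers — chosen once to reproduce the
qualitative activity ordering of the recorded animals and not tuned
thereafter.

## IMU model

Each channel is `bias + noise + oscillations`:

* a per-animal bias, drawn once per animal (accelerometer ±2 m/s² per
  axis — the backpack's attitude on the animal offsets gravity into the
  body axes — gyroscope ±5 deg/s);
* Gaussian noise whose standard deviation depends on the state
  (defaults: accelerometer 0.05 m/s² stopped vs 0.4 m/s² moving;
  gyroscope 0.5 vs 8 deg/s) — motion is noisier than rest;
* a 4-Hz gait oscillation (below the 10-Hz Nyquist limit) with random
  per-channel phase while moving, and an extra 6-Hz transient while a
  stimulation burst is applied, reflecting the body bending under
  stimulation.

Because the bias varies across animals and the two states differ mainly
in dispersion and rotational energy, a fixed threshold on any single
channel cannot separate stop from move across animals — which is what
motivates the learned classifier.  The generator does **not** model
drift over time, temperature effects, sensor saturation, gait harmonics
or inter-leg variability; passing tests therefore demonstrate the
pipeline's correctness and the separability logic, not performance on
real recordings.

## Features

Per window and channel: mean, variance (1/(L−1)), skewness
(Σ(x−x̄)³/((L−1)s³)), kurtosis (Σ(x−x̄)⁴/((L−1)s⁴), non-excess — the
formula is used exactly as printed, without the −3 correction), range,
mean absolute deviation about the mean, and interquartile range with
linear-interpolation quartiles — 42 values — plus the gyro energy
(1/L)Σg² of each gyroscope axis, for 45 features.  The accelerometer
channels pass through the first-order low-pass H(s) = K/(τs+1), K = 1,
τ = 0.1 s, discretized as y_i = αx_i + (1−α)y_{i−1} with
α = Δt/(τ+Δt) and y_0 = x_0 (no startup transient); gyroscope channels
are used raw, since the energy features are deliberately sensitive to
high-frequency rotation.  A zero-variance window gets skewness and
kurtosis 0 by convention instead of NaN.  A window's label is the
majority per-sample state; exact ties resolve to *stop*, the
conservative choice for a stimulate-on-stop policy.  Training windows
are non-overlapping (stride 30); the online recognizer re-evaluates the
trailing window every 0.5 s.

## Classifier benchmark

Seven models are compared under shuffled 10-fold cross-validation:
logistic regression (library defaults), Gaussian naive Bayes, KNN with
k = round(√n_train) forced odd (tie avoidance in binary voting) and
Euclidean Minkowski distance, and SVMs — linear C = 1000, cubic
polynomial C = 1, RBF C = 1000 γ = 0.01, sigmoid C = 1.  Features are
z-standardized inside each training fold for LR/KNN/SVM; an SVM with
C = 1000 on raw mixed-unit features (m/s² next to squared deg/s) would
be dominated by the large-scale channels, so standardization is treated
as part of the model.  The "default" kernel coefficient of the cubic
and sigmoid kernels is pinned to 1/(n_features·Var(X)) and recorded in
each report so results cannot drift with library versions.  Metrics are
computed from the pooled TP/TN/FP/FN counts with move = positive class;
0/0 ratios are defined as 0.  The deployment model is the argmax by
mean F1 (ties: accuracy, then a fixed family order); on the default
synthetic benchmark all seven models exceed 0.95 per-class accuracy and
the linear SVM is competitive at the top, so it is the default
deployment spec.

## Arena metrics

The arena is discretized by the square lattice (j/100, k/100),
j, k ∈ [−100, 100]; a lattice point is interior when its radius is
**strictly** below 1, giving exactly 31,397 interior points.  A point is
*searched* when its minimum Euclidean distance to the route (computed
exactly with a k-d tree over the route points) is strictly below the
virtual-sensor reach 0.1.  Search rate ε is the searched fraction.
Strict inequalities are used throughout, matching the piecewise
definitions of the scores; note that a stationary animal at the center
therefore reaches 305 lattice points (j² + k² < 100), not the 317 of
the non-strict count.  Central rate is the fraction of samples with
r < 0.9; stop and stimulation times are the corresponding sample
fractions scaled by the trial duration, which reproduces the recorded
420-s maximum exactly.  Per-animal summaries average over trials; the
overall row averages the per-animal means (equal weight per animal).
Improvement percentages are computed per animal from per-animal means
and then averaged — this per-animal reading reproduces the recorded 78%
stop-time reduction (76.3/94.8/61.9% per animal); the pooled reading
(≈78.9% for stop time, ≈69.4%/68.5% for search rate and distance) is
reported alongside but not asserted, since the two printed headline
percentages for search rate and distance (68%/70%) match neither
reading exactly.

The packaged per-trial tables transcribe the recorded free and
stimulated trials (9 each) and are checksum-verified on load.  One
internal inconsistency in the source is preserved as-is: the recorded
mean stop time of the first animal is printed as 354.55 s while its
trial values average 355.01 s; the trial-level values are taken as
ground truth.

## Closed-loop policy

Decisions are produced every 0.5 s from the trailing 1.5-s window (the
first at t = 1.5 s).  A burst fires when the accumulated decisions span
the full 1-s confirm delay and are all *stop*; decisions made while a
burst is active are excluded from confirmation, and the buffer is
cleared at burst start, so stop must be re-confirmed for a full second
after each burst — bursts are therefore strictly separated and the
stimulation-time metric equals the summed burst durations exactly.  The
0.5-s burst length and 0.5-s decision stride are free operational
choices (the original system specifies only the 1-s rule); the
stimulus waveform is metadata.  The experiment pairs seeds across the
free and stimulated conditions, animal by animal and trial by trial, to
cancel Monte-Carlo variance from the improvement estimates — a luxury
the physical experiment does not have.  With the response probability
set to 0 the paired runs coincide exactly, because the behavioral,
IMU-noise and response random streams are split from one seed.

## Video tracking

Frames are rendered as a filled body ellipse (major axis along the
direction of motion) over a dark arena, with optional Gaussian pixel
noise.  Tracking is Canny edge detection (with built-in Gaussian
smoothing), morphological closing, hole filling, largest connected
component within the configured axis bounds, then a least-squares
ellipse fit to the component contour (falling back to the region
centroid if the fit is degenerate).  Pixel coordinates use the image
convention (origin top-left, y down); one calibration function maps to
normalized arena coordinates and flips y.  Invalid frames hold the last
valid position (causal, like an online tracker).  On synthetic frames
with 8-bit noise sd 5 the tracker recovers centers to ≈0.1 px RMS, and
a render → track → metrics round trip preserves path length within 5%
and search rate within ±0.02.

## Problem sizes and numerical choices

Default study conditions: 7-minute trials at 20 Hz (8,400 samples), 3
test animals × 3 trials × 2 conditions; classifier benchmark 500
windows per class from the two training animals; grid resolution 100.
The test suite and the acceptance script run these sizes as-is.
Tolerances used by the tests: feature statistics match a brute-force
oracle at 1e-10 relative; the low-pass corner-frequency response is
checked to 5%; search rate is rotation-invariant only up to grid
discretization (|Δε| ≤ 0.02 for 200-point routes).  All randomness
derives from explicit integer seeds through `numpy.random.SeedSequence`.

## Known limitations

* The behavior transition rates and stimulation response probability
  are plausible defaults, not fitted to animals; absolute simulated
  quantities (e.g. per-trial stimulation seconds) should not be read as
  predictions of animal behavior — only the directional closed-loop
  effects and the exactly recomputable published summaries are asserted.
* The IMU model's class separation is larger than real recordings would
  show; the benchmark demonstrates pipeline correctness, not field
  accuracy.
* No real-time concerns (latency, jitter, threading) are modeled; the
  pipeline is batch-only by design.
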