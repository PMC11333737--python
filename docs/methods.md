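# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the `hrea` package.

## Attitude estimation

Each wearable sensor streams 9-axis samples at 30 Hz: accelerometer (g),
gyroscope (deg/s), magnetometer (µT). The estimator tracks the 6-dim state
x = [roll, pitch, yaw, roll_rate, pitch_rate, yaw_rate] with a *linear*
Kalman filter.

**Pseudo-measurement.** The raw 9-dim reading is reduced to a 6-dim
observation before filtering: roll = atan2(a_y, a_z),
pitch = atan2(−a_x, √(a_y² + a_z²)), yaw = the tilt-compensated magnetometer
heading (the magnetometer is de-rotated by the accelerometer roll/pitch, then
heading = atan2(−m_y′, m_x′)); the angular rates are the gyroscope readings.
This keeps the observation model exactly linear with H = I(6). The design was
genuinely open — a 9-dim raw measurement cannot be mapped linearly onto a
6-dim Euler-angle state — and the pseudo-measurement reduction is the
package's resolution of it.

**Model matrices (defaults, all configurable).**

* F: constant angular velocity — angles integrate their rates over
  dt = 1/30 s, rates persist. This is the minimal transition model consistent
  with the state.
* Q = diag(1e−3 deg² × 3, 1e−2 (deg/s)² × 3): small process noise, slightly
  larger on the rates, which change faster during a movement.
* R = diag(4 deg² × 3, 1 (deg/s)² × 3): accelerometer/magnetometer-derived
  angles are noisier than gyroscope rates at this sample rate.
* P0 = I(6); the filter state is initialized from the first
  pseudo-measurement.

**Numerical conventions.** All angles live in (−180°, 180°]; innovations are
computed on the shortest angular arc (mod 360). Covariances are re-symmetrized
after every step and verified PSD in tests (min eigenvalue ≥ −1e−9). A
numerically singular innovation covariance (condition number > 1e12) is
rejected with a diagnostic rather than silently inverted. The update uses the
textbook form P ← (I − KH)P; the Joseph form is unnecessary at these
conditioning levels.

**Gyro-rate convention.** The forward synthesizer produces gyroscope readings
as finite-difference Euler-angle rates, and the filter treats gyroscope
readings as Euler-angle rates directly. For the modest tilts of the assessed
movements the Euler-rate/body-rate distinction is below the sensor noise
floor; a quaternion or EKF formulation that models it properly is out of
scope.

## Synthetic scored-action generator

The generator emulates the study conditions: five FMA upper-limb actions,
each graded 0/1/2, recorded by two sensors at 30 Hz.

* **Templates.** Each action is a smoothstep rise (2 s), hold (5 s — the
  clinical instruction is to hold the end position for five seconds), and
  smoothstep return (2 s), peaking at 80–100° on its primary channel.
  Shoulder actions (A1, A4, A5) load the proximal upper-arm sensor #S2;
  elbow flexion (A2) and forearm rotation (A3) load the distal forearm
  sensor #S1. The non-primary sensor receives a 0.2 leakage fraction of the
  primary trajectory plus independent noise — complementary but correlated
  channels, which is what makes fusion informative.
* **Score profiles.** The clinical wording orders grades by completeness of
  the movement; the generator operationalizes that as amplitude-factor bands:
  score 2 → (0.9, 1.0); score 1 → (0.4, 0.6) plus two hesitation jerks
  (Gaussian dips during rise/return, each forcing a velocity reversal);
  score 0 → (0.05, 0.15) plus 3° tremor. Bands are disjoint and the grades
  are separable by peak amplitude alone by construction. This is a declared
  convention: the clinical scale states no kinematics for a "partial"
  movement.
* **Noise.** White angle noise of 1° SD on every channel; raw-IMU synthesis
  adds accelerometer 0.02 g, gyroscope 0.5 deg/s, magnetometer 0.5 µT by
  default. The reference magnetic field is fixed at (22, 0, 42) µT
  (horizontal + vertical component); declination is ignored since only
  relative yaw matters.
* **Determinism.** Every recording is a pure function of (action, score,
  seed); dataset seeds are spawned from the master seed via
  `numpy.random.SeedSequence`.

**What the generator does not emulate:** compensatory trunk movements,
inter-subject kinematic variability, sensor drift, soft-tissue artifacts, or
any overlap between grade bands. Passing tests on this data shows the
pipeline machinery is correct and that fusion exploits correlated channels;
it does not certify clinical accuracy on patient data, which requires real
recordings.

## Preprocessing

Fixed-bound min–max normalization maps the sensor range (−180°, 180°) onto
(−1, 1). Fixed bounds (not per-recording min/max) preserve the amplitude
information that carries the clinical grade — a weak movement must stay
small after normalization. A literal mode mapping onto [0, 1] is available
(`literal=True`). Values outside the bounds are clipped and counted.

Recordings are linearly resampled to a fixed 128-sample model input, the
window length of the UCI-HAR benchmark, so pretrained convolution shapes
transfer; each recording is one whole window (no sliding segmentation —
every recording is a single scored action). Labels 0–2 sit in a 6-class
space whose classes 3–5 are reserved placeholders with zero support and are
never emitted; weighted metrics are invariant to them.

Splits are stratified 6:2:2 (train/validation/test) with largest-remainder
rounding per class and a seeded shuffle.

## Per-channel scorer

Two convolution blocks (Conv1D kernel 10, valid padding → ReLU →
Dropout 0.5 → MaxPool window 2 stride 2), then Flatten → Dense(6) → softmax;
feature-length chain 128 → 119 → 59 → 50 → 25, flattened to 400. Choices the
source conditions left open, fixed here: 16 filters per block (keeps the
model in the few-thousand-parameter regime consistent with millisecond CPU
inference), Adam optimizer, batch size 32, Glorot-uniform initialization.
Learning rates: 0.001 for training on assessment data (120 epochs), 0.01 for
the optional UCI-HAR pretraining. Dropout is inverted and disabled at
inference; the epsilon floor in the loss is 1e−12.

The layers and backpropagation are implemented in NumPy inside the package
(`hrea._nn`): the windows are small enough that dense einsum convolutions
train in seconds, and a single `numpy.random.Generator` seeded from the
config drives initialization, shuffling and dropout, making runs exactly
reproducible.

Transfer initialization copies the convolution blocks of a pretrained scorer
and re-initializes the dense head (copy-all mode exists when shapes match);
the pretrained model is never mutated.

## Fusion

Decision rules operate on the two channels' 6-class posteriors:
max, sum, Dempster–Shafer and Naive Bayes. Two conventions worth noting:

* **D-S normalization.** The implemented constant is
  K = 1 − Σᵢ p(ĉᵢ|x₁) p(ĉᵢ|x₂) — the complement of the *agreement* mass,
  not the standard pairwise-conflict sum of Dempster's rule. It is
  implemented exactly in that form. Because K does not depend on the class,
  the decision always coincides with the plain product rule; this equivalence
  is asserted against a brute-force oracle in the tests, so the choice of
  constant is harmless for classification. |K| < 1e−12 falls back to
  unnormalized products with a warning.
* **Naive Bayes priors.** Defaults to empirical training-label frequencies
  (classes 3–5 then get zero mass); uniform priors and additive smoothing are
  available. With uniform priors the rule reduces to the product rule.

Ties break toward the lowest class index everywhere. Products switch to log
space when any posterior entry is below 1e−12.

The MCFF comparator concatenates the two channels' flattened convolutional
features (2 × 400) before a single dense head and trains end-to-end with the
same loss and optimizer.

## Evaluation

Per-class precision/recall/F1 from the confusion matrix with the 0-on-
zero-denominator convention; weighted averages use class support shares
N_i / N_total. Model comparison is a two-sided paired t-test at α = 0.05 on
per-run metric values; the intended resampling unit is repeated stratified
6:2:2 splits paired by seed (default 10 repeats), a concrete choice where
the pairing unit was left open. All-zero differences return p = 1 by
convention. Reports render percentages to two decimals; internal values keep
full precision.

## Problem sizes

The test suite and the acceptance script run the full synthetic experiment at
150 recordings (10 per action × score), 120 training epochs per channel and
three repeated seeds — the smallest configuration at which the fused model's
behavior (weighted F1 above 0.90 and above the weaker single channel) is
stable; larger datasets only sharpen the margins.

## Known limitations

* The Kalman filter is linear on Euler angles: no gimbal-proof quaternion
  state, no gyro-bias estimation, no magnetometer calibration.
* The synthetic grades are a convention, cleanly separable by design;
  real clinical boundary cases (a score 1 that almost reaches full range)
  are harder than anything the generator produces.
* D-S fusion is pairwise only (two channels).
* UCI-HAR pretraining is an optional benchmark requiring the external
  dataset; the loader is tested against a synthetic miniature of the
  directory layout, and no claims are made about pretraining accuracy.
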