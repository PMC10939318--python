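# Methods

This note documents the models, conventions and numerical choices behind
`gaitkit`. It is the place to look when a default value or a tie-break
matters for your analysis.

## Data model and conventions

All signals use SI units except angular velocity, which is kept in
degrees per second for readability: acceleration in m/s², distance in m,
time in s. Orientations are unit quaternions stored in **(x, y, z, w)**
order, Hamilton convention, acting as active rotations. Acceleration is
a *specific force*: a static, level sensor reads `(0, 0, +9.81)`.

Interval lists (strides, ZUPT regions) are 0-based, half-open
`[start, end)` sample indices, sorted and non-overlapping; every
serialized file carries the marker string `"0-based,half-open"`.

### Sensor and body frame

The sensor frame has x pointing roughly forward, y to the left and z up.
The body frame of the foot uses (pa, ml, si) = posterior→anterior,
medial→lateral, superior→inferior axes. The fixed axis mapping is

* `pa = +x`, `si = −z` for both feet,
* `ml = +y` for the left foot, `ml = −y` for the right foot.

Left and right body frames are therefore mirror images. Acceleration
(a point vector) transforms with these matrices directly; angular
velocity is a *pseudo-vector* and picks up an extra handedness factor
`det(A) = ±1` under the improper (mirror) part of the mapping. With
that factor, identical anatomical motion produces identical body-frame
gyroscope traces on both feet — dorsiflexion is `gyr_ml > 0` on either
side — which is what makes one event detector work for both feet. The
"transforms differ only in the ml sign" picture applies to the
acceleration matrices; the gyroscope matrices include the handedness
factor on top.

The `si` axis points downward, so a static upright foot has
`acc_si = −9.81`. This is one consistent choice; the sign convention of
`si` readings is not standardized elsewhere.

## Gravity alignment

Static regions are found by thresholding a windowed metric (mean, max
or variance) of the gyroscope norm. Windows slide with a 1-sample hop
and all passing windows merge into maximal regions; tumbling windows
would miss region boundaries. The alignment rotation is the single
shortest-arc rotation taking the pooled mean acceleration over all
static samples onto `(0, 0, 9.81)`, computed with the half-angle
formula; antiparallel vectors rotate 180° about +x (deterministic
tie-break). Data whose mean static acceleration is below 0.5 g is
rejected as free-fall-like rather than silently aligned.

## Stride segmentation (subsequence DTW)

The template is one gait cycle of `gyr_ml` (toe-off to toe-off). Local
cost is the squared difference of amplitude-scaled samples (both signal
and template are divided by the template's `scaling`, default
500 deg/s); the accumulated cost is **not** length-normalized, so
`max_cost` scales with template length. Steps are diagonal, vertical,
horizontal; the first template row is initialized to the local cost
(free start); ties prefer diagonal, then vertical, then horizontal.

Match ends are local minima of the final-row cost below `max_cost`.
Cost **plateaus contribute their last sample**: when template and
signal both end in a near-constant stance, every end inside the stance
is equally cheap, and taking the last one extends the match to the
stride border instead of stopping right after the swing. Starts come
from backtracking; overlapping candidates keep the lower cost (ties:
the earlier one); matches outside the duration bounds
(default 0.6–3.0 s, non-normative) are dropped.

The constrained variant forbids more than `max_local_run` consecutive
vertical or horizontal steps along the chosen path. This suppresses
degenerate warps that collapse long flat stretches onto single samples;
under sensor noise this is what keeps match borders from drifting
through the stance, so the end-to-end pipeline enables it by default
(`max_local_run = 3`).

The bundled default template is **synthetic**: one noise-free simulated
stride at 204.8 Hz generated by `gaitkit.synthetic_gait` and frozen as a
JSON fixture. Real deployments should supply a template extracted from
their own data.

`snap_to_min` moves each border to the signal minimum within
±`snap_window/2` (default 100 ms) and reverts any move that would
produce crossing or empty intervals. It is provided but off by default:
whether stride borders sit exactly at signal minima is a dataset
convention.

## Event detection

Works per segmented stride on body-frame signals:

* **Swing peak**: argmax of `gyr_ml` (the dominant positive mid-swing
  dorsiflexion peak).
* **tc (toe-off)**: the last sample of `gyr_ml` at or below zero before
  the swing peak — the zero crossing that launches the swing. If the
  signal is positive from the stride border on, the border itself is tc.
* **ic (heel strike)**: argmin of `acc_pa` within
  `(peak, peak + ic_search_fraction · stride_length]` (default fraction
  0.5). The landing foot brakes hard, so `acc_pa` dips sharply at
  contact.
* **min_vel (mid-stance)**: center of the `min_vel_window`-long window
  (default 100 ms) with minimal gyroscope energy after ic.

The "filtered" variant low-passes the **gyroscope** channels with a
zero-phase Butterworth filter (default order 2, cutoff 15 Hz) before
computing the peak, tc and min_vel searches. The accelerometer is left
unfiltered on purpose: the ic landing spike is intrinsically one-sided
(acceleration stops dead at foot contact), and low-passing it shifts
its minimum systematically backward in time. Filtering the gyroscope
stabilizes the search windows under noise without biasing ic.

Strides without the expected signal structure (flat `gyr_ml`, empty
search windows) are flagged not-detectable; no sentinel indices are
emitted. All search fractions and filter parameters are config-exposed
and non-normative.

Min_vel strides `[min_vel_k, min_vel_{k+1})` are built from consecutive
detectable strides only; an undetectable stride splits the sequence and
nothing bridges the gap.

## ZUPT detection

Three detectors share one windowing engine (default window 100 ms,
overlap 50%):

* **ared** — mean of ‖gyr‖² per window, threshold in (deg/s)². The
  default threshold (100 (deg/s)²) passes a still foot with ~1 deg/s
  gyro noise.
* **norm** — a chosen metric (mean/max/variance) of a chosen sensor's
  norm; the generalized form of the same idea.
* **shoe** — per-window mean of
  `‖acc − g·ā/‖ā‖‖²/σ_a² + ‖gyr‖²/σ_g²`, with `ā` the window-mean
  acceleration: the gravity direction is estimated per window, not
  globally. As `σ_a → ∞` this reduces exactly to ared with a rescaled
  threshold.

Windows below threshold are merged into maximal regions. Trailing
samples not covered by any full window inherit the label of the last
evaluated window. All thresholds are fixture-calibrated and
non-normative.

## Trajectory reconstruction

All methods share a strapdown core. Degrees→radians conversion happens
exactly once at module entry. Orientation propagates with the exact
per-sample quaternion exponential `q_{k+1} = q_k ⊗ Δq(ω_k Δt)`;
velocity and position use trapezoidal integration with Δt fixed by the
sampling rate. Initial conditions default to the origin, zero velocity
and the identity orientation (or the gravity-alignment rotation of the
first static window).

**Madgwick (IMU-only)** uses the same gyroscope stepping plus
`−β Δt` times the normalized gradient of the accelerometer-gravity
objective; with `β = 0` it is bitwise identical to plain gyro
integration. Zero-norm accelerometer samples skip the gradient step.

**Forward-backward integration** integrates velocity forward with
`v(start) = 0` and backward with `v(end) = 0` over a region bounded by
zero-velocity instants, and blends the two with a sigmoid ramp
(steepness 10 over the normalized region), so both boundary conditions
hold exactly. Vertical position is linearly detrended to
`z(end) = z(start)` (level-walking assumption).

**Piecewise-linear dedrifting** models integration drift as linear in
time between ZUPT regions: the drift series equals the measured
velocity at each ZUPT midpoint, interpolates linearly between
midpoints, and is held constant outside; after subtraction, velocity is
clamped to exactly zero inside ZUPT regions. A constant accelerometer
bias produces exactly linear velocity drift, which this model removes
exactly.

**RTS-smoothed error-state Kalman filter.** The nominal state is the
strapdown trajectory; the 9-dim error state is (δp, δv, δθ) with a
*local* (body-side) multiplicative orientation error in rotation-vector
form. The transition uses `δv ← δv − R[a_s]× δθ Δt` (local-error
convention) and `δθ ← (I − [ω]×Δt) δθ`; process noise enters δv and δθ
as white densities (`accel_noise` in m/s²·√s, `gyro_noise` in
deg/s·√s). Every sample inside a ZUPT region contributes a
velocity-is-zero measurement (H selects δv; Joseph-form update). The
error state is **not** injected during the forward pass: filtered and
predicted (state, covariance) sequences feed a standard
Rauch-Tung-Striebel backward pass
(`C_k = P_k F_kᵀ P⁻¹_pred,k+1`), and the smoothed errors are injected
into the nominal trajectory once at the end (position and velocity
additively, orientation as `q ⊗ Δq(δθ)`). Deferred injection keeps the
error sequence linear, which is what the RTS recursion assumes; for the
session lengths this package targets (minutes), nominal-trajectory
linearization error is negligible because ZUPTs bound the error growth
per stride.

Defaults (`accel_noise = 0.1`, `gyro_noise = 0.1`,
`zupt_measurement_noise = 1e-3 m/s`, initial covariance `1e-8 I`) are
simulator-calibrated, non-normative values in the range of consumer
MEMS sensors. Smoothing never increases the covariance trace and
reduces velocity RMS error; its effect on *position* RMS is marginal
and only holds on average, because position error is observable from
zero-velocity measurements only through its coupling to δv.

## Spatio-temporal parameters

Temporal parameters come from events:
`stride_time_k = (ic_k − ic_{k−1})/f_s`,
`swing_time_k = (ic_k − tc_k)/f_s`, `stance = stride − swing`. The
first stride of a sequence yields only a swing time. Missing events
propagate as NaN, never as zero.

Stride length is the **ground-plane** (x, y) displacement between
min_vel-stride borders — the level-walking convention of the classic
parameter literature; the 3-D norm is available behind `use_3d_norm`.
Gait velocity is stride length over stride time, an identity that holds
per stride by construction.

## Evaluation

A detected stride matches a reference stride iff both its start and end
are within the tolerance (default **30 ms**, converted to samples by
rounding half up) of the reference borders. Among all
maximum-cardinality one-to-one matchings, the one minimizing the summed
border distance is chosen (implemented as a linear assignment with a
large penalty on infeasible pairs; a brute-force oracle checks it in
the tests). Maximum-cardinality matching makes the score independent of
list order, unlike greedy matching.

Precision, recall and F1 flag empty denominators as undefined (`None`)
instead of reporting 0. Parameter errors aggregate at two levels — per
test (mean over strides of one recording) and per fold (mean of
per-test values) — because the two schemes genuinely disagree and
results are only comparable within one scheme.

Cross-validation is group-aware: no participant appears in both train
and test. Fold assignment ranks a seeded permutation of the group
labels, so the split is deterministic, serializable in a run manifest,
and independent of dataset order.

## Synthetic gait model

The simulator is the package's ground-truth oracle. A session is
`stance, swing, stance, …, swing, stance` with `n_strides` swings;
segmented strides run toe-off to toe-off `[tc_k, tc_{k+1})`, the last
one ending at the session end. Within a swing of duration `T`
(normalized `s = t/T`):

* forward displacement `x(s) = L(4s³ − 3s⁴)`: velocity `∝ s²(1−s)`
  rises slowly and ends in a sharp braking ramp that mimics the landing
  deceleration spike — this is what gives ic detection its signature;
* vertical arc `z(s) = 16 H s²(1−s)²` peaking at the foot clearance;
* sagittal pitch `φ(s) = −A sin²(πs)` about the lateral axis:
  dorsiflexion through the swing for toe clearance, back to level
  before landing, producing the dominant positive `gyr_ml` mid-swing
  peak. The discrete profiles reach their end values one sample before
  stance, so the first stance sample is exactly at rest (clean ZUPT
  ground truth).

Stance phases are perfectly static and level. Defaults (1.3 m strides,
1.1 s stride time, 55% stance, 10 cm clearance, ±25° pitch, 204.8 Hz)
describe a typical healthy adult at comfortable speed.

The IMU signal is derived by inverse strapdown: world acceleration from
second differences of position, rotated by the inverse orientation with
gravity added; angular velocity from per-sample relative quaternions,
so forward quaternion integration reproduces the true orientations
exactly and the strapdown round trip is discretely consistent
(sub-millimeter over 10 strides). Noise is white Gaussian per axis plus
an optional constant per-axis gyro bias, both seeded; identical seeds
give bitwise-identical recordings.

### What the simulator does and does not capture

It captures the features the algorithms key on: cyclic
stance/swing alternation, the sagittal gyroscope stride signature, the
landing deceleration, gravity leakage under tilt, white sensor noise
and constant bias. It does **not** capture turns or heading change,
slopes or stairs, double-support rolling (stance is perfectly static,
with no heel-strike/push-off rotation inside stance), pathological gait
asymmetries, or colored/random-walk sensor errors. Passing tests
therefore demonstrate algorithmic correctness under the stated model,
not clinical-grade accuracy on real recordings: real stance phases are
never exactly static, so border localization and ZUPT detection will be
less sharp in practice.

### Problem sizes used in the shipped checks

The test-suite and the acceptance script run sessions of 4–50 strides
at 204.8 Hz (up to roughly a minute of signal). These sizes were chosen
because every reported quantity has already converged at them: the
recovery errors are flat in session length once a handful of strides is
present.

## Known limitations

* Single-template DTW only; no HMM segmentation, no multi-template
  voting.
* No gait-sequence (bout) detection; recordings are assumed to contain
  walking.
* Heading is unobservable without magnetometer or movement-direction
  alignment; yaw drift in long sessions is not corrected.
* The Kalman filter assumes a constant sampling rate and white process
  noise; sensor bias states are not estimated.
* Stride matching tie-breaks ("earlier reference") inside the linear
  assignment are best-effort: when several optimal matchings have equal
  cardinality and distance, any of them may be returned.
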