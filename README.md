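# gaitkit

Gait analysis from foot-worn inertial measurement units (IMUs).

Clinical gait studies increasingly replace camera-based motion capture
with a small IMU strapped to each shoe. Turning those raw accelerometer
(m/s²) and gyroscope (deg/s) streams into clinically meaningful numbers
— stride time, swing/stance time, stride length, gait velocity —
requires a chain of algorithms, each published separately and rarely
available as reusable code. `gaitkit` implements that full chain for
researchers and application developers working with foot-worn sensors:

1. **Preprocessing** — static-window detection and rotation of the
   recording so measured gravity aligns with the world vertical.
2. **Stride segmentation** — subsequence dynamic time warping (DTW) of
   a one-cycle `gyr_ml` template against the continuous signal, with an
   optional local warping constraint and border snapping.
3. **Event detection** — terminal contact (toe-off), initial contact
   (heel strike) and mid-stance (`min_vel`) per stride from body-frame
   signal features, plus re-segmentation into mid-stance-to-mid-stance
   strides for integration.
4. **Zero-velocity detection** — ARED, generalized-norm and SHOE
   window detectors of the stance phase.
5. **Trajectory reconstruction** — gyroscope strapdown integration,
   Madgwick sensor fusion, dedrifted double integration
   (forward-backward and piecewise-linear), and a ZUPT-aided
   error-state Kalman filter with Rauch-Tung-Striebel smoothing.
6. **Parameters** — per-stride temporal and spatial gait parameters.
7. **Evaluation** — tolerance-based stride matching (30 ms default)
   with precision/recall/F1, two-level error aggregation, and
   group-aware cross-validation.
8. **Synthetic gait** — a kinematic simulator that generates IMU
   signals by inverse strapdown with complete ground truth (strides,
   events, stance regions, trajectory, parameters), used as the test
   oracle for every stage.

## The core model

Foot orientation is propagated from the gyroscope,
`q_{k+1} = q_k ⊗ Δq(ω_k Δt)`, and position follows from
gravity-corrected, orientation-rotated acceleration,
`a_w = R(q) a_s − g ẑ`, integrated twice. Pure double integration
drifts quadratically, so every practical method exploits the one thing
a foot guarantees: it is stationary once per stride. During detected
zero-velocity (ZUPT) phases the filter state is corrected with a
velocity-is-zero pseudo-measurement; a 9-state error-state Kalman
filter (δp, δv, δθ) with RTS smoothing distributes those corrections
over the whole stride. Stride length is then the ground-plane
displacement between consecutive mid-stance instants, and gait velocity
is stride length over stride time.

Units are SI except angular velocity (deg/s); orientations are unit
quaternions in (x, y, z, w) order; all interval indices are 0-based and
half-open. See `docs/methods.md` for every convention and default.

## Worked example

```python
import numpy as np
from gaitkit.synthetic_gait import GaitProfile, simulate_session
from gaitkit.stride_segmentation import default_template
from gaitkit.pipeline import GaitPipeline
from gaitkit.evaluation import match_stride_lists, precision_recall_f1

# a simulated 40-stride walk at 204.8 Hz with known ground truth
bundle = simulate_session(GaitProfile(n_strides=40))

pipe = GaitPipeline(template=default_template())
result = pipe.run(bundle.recording)

m = match_stride_lists(result.segmented_strides, bundle.strides,
                       tolerance=0.03, rate=204.8)
print("strides detected:", len(result.segmented_strides))
print("F1 vs ground truth:", precision_recall_f1(m).f1)
print("mean stride length [m]:",
      round(float(np.nanmean(result.spatial['stride_length'])), 3))
print("mean gait velocity [m/s]:", round(result.mean_gait_velocity, 3))
```

prints

```
strides detected: 40
F1 vs ground truth: 1.0
mean stride length [m]: 1.3
mean gait velocity [m/s]: 1.183
```

All 40 simulated strides are found with both borders within 30 ms of
the truth (F1 = 1.0); the reconstructed stride length matches the
simulated 1.30 m, and the mean gait velocity matches the ground-truth
1.30 m / 1.099 s = 1.183 m/s (stride time is quantized to whole
samples at 204.8 Hz).

## Scope

Foot/shoe-mounted sensors only — no trunk, wrist or hip placements, no
multi-segment fusion, no gait-sequence detection, no HMM segmentation,
no stair-specific event detection, and no heading alignment. Turns are
not simulated; see `docs/methods.md` for the full list of assumptions
and limitations.
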