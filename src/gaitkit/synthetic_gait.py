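"""Synthetic gait with complete ground truth.

The simulator builds a foot trajectory from smooth kinematic primitives
and derives the IMU signals by inverse strapdown (second differences of
position, relative quaternions), so every downstream module can be
tested against exact ground truth.

A session is a chain ``stance, swing, stance, swing, ..., stance`` of
``n_strides`` swing phases.  Within each swing of duration ``T``
(normalized time ``s = t/T``):

* forward displacement follows ``x(s) = L · (4s³ − 3s⁴)`` — the velocity
  profile ``v ∝ s²(1−s)`` rises slowly and ends with a sharp braking
  ramp, mimicking the deceleration spike of foot landing;
* vertical position follows the C¹ arc ``z(s) = H · 16 s²(1−s)²``
  peaking at the foot clearance ``H`` in mid-swing;
* sagittal pitch follows ``φ(s) = −A · sin²(πs)`` about the world
  lateral axis (dorsiflexion through swing for toe clearance, back to
  level before landing), so the body-frame ``gyr_ml`` shows the
  classic dominant positive mid-swing peak.

Stance phases are perfectly static (the zero-velocity ground truth) and
the foot is level, so a static sensor reads ``acc = (0, 0, 9.81)``.

Ground-truth segmented strides run toe-off to toe-off,
``[tc_k, tc_{k+1})``; ``ic`` is the swing→stance transition and
``min_vel`` the midpoint of the following stance.  All ground-truth
parameters are exact by construction (stride length equals the profile
value; times are quantized to whole samples).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from gaitkit.core_types import (
    GRAVITY_VECTOR,
    EventList,
    ImuRecording,
    IntervalList,
    Trajectory,
    quat_conjugate,
    quat_from_axis_angle,
    quat_multiply,
    quat_normalize,
    quat_rotate,
    quat_to_rotation_vector,
)


@dataclass(frozen=True)
class GaitProfile:
    """Kinematic and sensor parameters of a simulated walking session.

    Defaults describe a typical healthy adult walking at a comfortable
    speed, recorded at 204.8 Hz: 1.3 m strides of 1.1 s with 55% stance,
    10 cm foot clearance and a ±25° sagittal pitch sweep.  Noise sigmas
    and the constant gyro bias default to zero (noise-free ground truth).
    """

    n_strides: int = 10
    stride_length: float = 1.3
    stride_time: float = 1.1
    stance_fraction: float = 0.55
    foot_clearance: float = 0.1
    pitch_range: float = 25.0
    sampling_rate: float = 204.8
    acc_noise_sigma: float = 0.0
    gyro_noise_sigma: float = 0.0
    gyro_bias: float = 0.0
    seed: int = 0
    side: str = "left"

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        for name in ("stride_length", "stride_time", "foot_clearance",
                     "pitch_range", "sampling_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.acc_noise_sigma < 0 or self.gyro_noise_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")

    @property
    def n_stance_samples(self) -> int:
        return max(2, round(self.stance_fraction * self.stride_time
                            * self.sampling_rate))

    @property
    def n_swing_samples(self) -> int:
        total = max(4, round(self.stride_time * self.sampling_rate))
        return max(2, total - self.n_stance_samples)

    @property
    def n_stride_samples(self) -> int:
        return self.n_stance_samples + self.n_swing_samples


@dataclass(frozen=True)
class GroundTruthBundle:
    """A recording tied to its complete ground truth."""

    recording: ImuRecording
    trajectory: Trajectory
    strides: IntervalList
    events: EventList
    zupts: IntervalList
    parameters: pd.DataFrame
    profile: GaitProfile


def _swing_profiles(profile: GaitProfile) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-swing-sample (x-fraction, z, pitch_deg) arrays of length n_swing."""
    # s reaches 1 one sample before stance, so the discrete velocity is
    # already zero at the first stance sample (clean ZUPT ground truth)
    n = profile.n_swing_samples
    s = np.arange(n) / (n - 1)
    x_frac = 4 * s**3 - 3 * s**4
    z = profile.foot_clearance * 16 * s**2 * (1 - s) ** 2
    pitch_deg = -profile.pitch_range * np.sin(np.pi * s) ** 2
    return x_frac, z, pitch_deg


def simulate_trajectory(
    profile: GaitProfile,
) -> tuple[Trajectory, IntervalList, EventList, IntervalList, pd.DataFrame]:
    """Build the true trajectory plus strides, events, ZUPTs and parameters."""
    n_st = profile.n_stance_samples
    n_sw = profile.n_swing_samples
    n_total = n_st + profile.n_strides * (n_sw + n_st)
    pos = np.zeros((n_total, 3))
    pitch_deg = np.zeros(n_total)
    x_frac, z_arc, pitch_swing = _swing_profiles(profile)

    tc_idx = np.zeros(profile.n_strides + 1, dtype=int)
    ic_idx = np.zeros(profile.n_strides, dtype=int)
    cursor = n_st
    x_base = 0.0
    for k in range(profile.n_strides):
        tc_idx[k] = cursor
        sl = slice(cursor, cursor + n_sw)
        pos[sl, 0] = x_base + profile.stride_length * x_frac
        pos[sl, 2] = z_arc
        pitch_deg[sl] = pitch_swing
        cursor += n_sw
        ic_idx[k] = cursor
        x_base += profile.stride_length
        pos[cursor:cursor + n_st, 0] = x_base
        cursor += n_st
    tc_idx[-1] = cursor  # == n_total: virtual toe-off ending the last stride

    quats = quat_from_axis_angle(
        np.broadcast_to([0.0, 1.0, 0.0], (n_total, 3)),
        np.deg2rad(pitch_deg),
    )
    traj = Trajectory(position=pos, orientation=quats,
                      sampling_rate=profile.sampling_rate)

    strides = IntervalList(np.column_stack([tc_idx[:-1], tc_idx[1:]]))
    min_vel = ic_idx + n_st // 2
    events = EventList(
        stride_id=np.arange(profile.n_strides),
        tc=tc_idx[:-1].astype(float),
        ic=ic_idx.astype(float),
        min_vel=min_vel.astype(float),
        detectable=np.ones(profile.n_strides, dtype=bool),
    )
    zupt_bounds = [(0, n_st)] + [
        (ic_idx[k], ic_idx[k] + n_st) for k in range(profile.n_strides)
    ]
    zupts = IntervalList(np.asarray(zupt_bounds, dtype=int))

    rate = profile.sampling_rate
    stride_time = (n_sw + n_st) / rate
    params = pd.DataFrame(
        {
            "stride_id": np.arange(profile.n_strides),
            "stride_time": stride_time,
            "swing_time": n_sw / rate,
            "stance_time": n_st / rate,
            "stride_length": profile.stride_length,
            "gait_velocity": profile.stride_length / stride_time,
        }
    ).set_index("stride_id")
    return traj, strides, events, zupts, params


def trajectory_to_imu(traj: Trajectory, profile: GaitProfile) -> ImuRecording:
    """Inverse strapdown: derive the sensor-frame IMU signal from a trajectory.

    World acceleration comes from second differences of position (end
    samples padded with zero — sessions start and end at rest); the
    sensor-frame specific force adds gravity and rotates by the inverse
    orientation; angular velocity comes from per-sample relative
    quaternions (so forward quaternion integration reproduces the input
    orientations exactly).  Optional white Gaussian noise and a constant
    per-axis gyro bias are seeded by the profile.
    """
    n = len(traj)
    if n < 3:
        raise ValueError("trajectory must have at least 3 samples")
    dt = 1.0 / traj.sampling_rate
    a_w = np.zeros((n, 3))
    a_w[1:-1] = (traj.position[2:] - 2 * traj.position[1:-1]
                 + traj.position[:-2]) / dt**2
    acc = quat_rotate(quat_conjugate(traj.orientation),
                      a_w + GRAVITY_VECTOR)
    rel = quat_multiply(quat_conjugate(traj.orientation[:-1]),
                        traj.orientation[1:])
    rotvec = quat_to_rotation_vector(quat_normalize(rel))
    gyr = np.zeros((n, 3))
    gyr[:-1] = np.rad2deg(rotvec) / dt
    if profile.acc_noise_sigma > 0 or profile.gyro_noise_sigma > 0 \
            or profile.gyro_bias != 0:
        rng = np.random.default_rng(profile.seed)
        if profile.acc_noise_sigma > 0:
            acc = acc + rng.normal(0.0, profile.acc_noise_sigma, acc.shape)
        if profile.gyro_noise_sigma > 0:
            gyr = gyr + rng.normal(0.0, profile.gyro_noise_sigma, gyr.shape)
        gyr = gyr + profile.gyro_bias
    return ImuRecording(acc=acc, gyr=gyr, sampling_rate=traj.sampling_rate,
                        frame="sensor", side=profile.side)


def simulate_session(profile: GaitProfile | None = None) -> GroundTruthBundle:
    """Simulate one continuous walking bout with full ground truth."""
    profile = profile or GaitProfile()
    traj, strides, events, zupts, params = simulate_trajectory(profile)
    rec = trajectory_to_imu(traj, profile)
    return GroundTruthBundle(
        recording=rec, trajectory=traj, strides=strides, events=events,
        zupts=zupts, parameters=params, profile=profile,
    )


def simulate_walk_test(
    profile: GaitProfile | None = None,
    n_bouts: int = 4,
    bout_distance: float = 10.0,
) -> GroundTruthBundle:
    """Convenience preset emulating a 4×10 m walk test.

    ``n_bouts`` straight bouts (turns are not simulated; heading stays
    constant) are chained with the regular stance pauses between them;
    strides per bout are rounded to cover ``bout_distance``.
    """
    profile = profile or GaitProfile()
    strides_per_bout = max(1, round(bout_distance / profile.stride_length))
    bout_profile = replace(profile, n_strides=strides_per_bout)
    bundles = [simulate_session(replace(bout_profile, seed=profile.seed + b))
               for b in range(n_bouts)]
    return concatenate_bundles(bundles)


def concatenate_bundles(bundles: list[GroundTruthBundle]) -> GroundTruthBundle:
    """Chain bouts end to end, shifting indices and positions."""
    if not bundles:
        raise ValueError("need at least one bundle")
    acc, gyr, pos, quats = [], [], [], []
    stride_rows, zupt_mask_parts, event_frames, param_frames = [], [], [], []
    offset = 0
    pos_offset = np.zeros(3)
    for b in bundles:
        acc.append(b.recording.acc)
        gyr.append(b.recording.gyr)
        pos.append(b.trajectory.position + pos_offset)
        quats.append(b.trajectory.orientation)
        stride_rows.append(b.strides.intervals + offset)
        n = b.recording.n_samples
        mask = b.zupts.to_mask(n)
        zupt_mask_parts.append(mask)
        event_frames.append(
            pd.DataFrame(
                {
                    "tc": b.events.tc + offset,
                    "ic": b.events.ic + offset,
                    "min_vel": b.events.min_vel + offset,
                    "detectable": b.events.detectable,
                }
            )
        )
        param_frames.append(b.parameters.reset_index(drop=True))
        pos_offset = pos_offset + (b.trajectory.position[-1]
                                   - b.trajectory.position[0])
        offset += n
    first = bundles[0]
    rec = ImuRecording(
        acc=np.vstack(acc), gyr=np.vstack(gyr),
        sampling_rate=first.recording.sampling_rate,
        frame="sensor", side=first.recording.side,
    )
    traj = Trajectory(
        position=np.vstack(pos), orientation=np.vstack(quats),
        sampling_rate=first.trajectory.sampling_rate,
    )
    ev = pd.concat(event_frames, ignore_index=True)
    events = EventList(
        stride_id=np.arange(len(ev)), tc=ev["tc"].to_numpy(),
        ic=ev["ic"].to_numpy(), min_vel=ev["min_vel"].to_numpy(),
        detectable=ev["detectable"].to_numpy(),
    )
    params = pd.concat(param_frames, ignore_index=True)
    params.index.name = "stride_id"
    return GroundTruthBundle(
        recording=rec,
        trajectory=traj,
        strides=IntervalList(np.vstack(stride_rows)),
        events=events,
        zupts=IntervalList.from_mask(np.concatenate(zupt_mask_parts)),
        parameters=params,
        profile=first.profile,
    )
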