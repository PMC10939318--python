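"""Trajectory reconstruction from foot-worn IMU data.

All methods share the same strapdown core: orientation is propagated by
quaternion integration of the gyroscope, acceleration is rotated into
the world frame and gravity-corrected, and velocity/position follow by
trapezoidal integration.  What distinguishes the methods is how they
fight integration drift:

* :func:`integrate_gyro` / :func:`madgwick` — orientation only.
* :func:`forward_backward_integration` — double integration run forward
  and backward over a region bounded by zero-velocity instants, blended
  with a sigmoid weight.
* :func:`piecewise_linear_dedrifted_integration` — a piecewise-linear
  velocity drift model anchored at ZUPT midpoints.
* :func:`rts_kalman` — a 9-state (δp, δv, δθ) error-state Kalman filter
  with per-sample zero-velocity measurements inside ZUPT regions and a
  Rauch-Tung-Striebel backward smoothing pass.

Degrees→radians conversion happens exactly once, at module entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from gaitkit.core_types import (
    GRAVITY,
    ImuRecording,
    IntervalList,
    Trajectory,
    quat_from_axis_angle,
    quat_identity,
    quat_multiply,
    quat_normalize,
    quat_rotate,
)


# ---------------------------------------------------------------------------
# Orientation estimation
# ---------------------------------------------------------------------------

def _gyro_step_quats(gyr_deg: np.ndarray, dt: float) -> np.ndarray:
    """Per-sample incremental rotations Δq(gyr_k · Δt), exact exponential."""
    omega = np.deg2rad(gyr_deg)
    angle = np.linalg.norm(omega, axis=1) * dt
    safe = np.where(angle == 0, 1.0, np.linalg.norm(omega, axis=1))
    axis = omega / safe[:, None]
    return quat_from_axis_angle(axis, angle)


def integrate_gyro(rec: ImuRecording, q0: np.ndarray | None = None) -> np.ndarray:
    """Dead-reckon orientation: ``q_{k+1} = q_k ⊗ Δq(gyr_k · Δt)``.

    Returns one unit quaternion per sample, ``q[0] == q0`` (identity by
    default); the last gyroscope sample is unused.
    """
    q0 = quat_identity() if q0 is None else np.asarray(q0, dtype=float)
    dt = 1.0 / rec.sampling_rate
    steps = _gyro_step_quats(rec.gyr[:-1], dt)
    out = np.empty((rec.n_samples, 4))
    out[0] = q0
    for k in range(steps.shape[0]):
        q = quat_multiply(out[k], steps[k])
        out[k + 1] = q / np.linalg.norm(q)
    return out


def madgwick(
    rec: ImuRecording, beta: float = 0.1, q0: np.ndarray | None = None
) -> np.ndarray:
    """Madgwick AHRS orientation estimate (IMU-only form).

    Each step propagates the quaternion with the gyroscope (same
    exponential stepping as :func:`integrate_gyro`) and, for ``beta > 0``,
    subtracts ``beta · Δt`` times the normalized gradient of the
    accelerometer-gravity objective.  With ``beta == 0`` the output is
    bitwise identical to :func:`integrate_gyro`.  Zero-norm accelerometer
    samples skip the gradient step.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    q0 = quat_identity() if q0 is None else np.asarray(q0, dtype=float)
    dt = 1.0 / rec.sampling_rate
    steps = _gyro_step_quats(rec.gyr[:-1], dt)
    out = np.empty((rec.n_samples, 4))
    out[0] = q0
    for k in range(steps.shape[0]):
        q = quat_multiply(out[k], steps[k])
        if beta > 0:
            grad = _gravity_objective_gradient(q, rec.acc[k + 1])
            if grad is not None:
                q = q - beta * dt * grad
        out[k + 1] = q / np.linalg.norm(q)
    return out


def _gravity_objective_gradient(q: np.ndarray, acc: np.ndarray) -> np.ndarray | None:
    """Normalized gradient of ``‖R(q)ᵀ ẑ − acc/‖acc‖‖²`` w.r.t. q.

    Returns None for zero-norm accelerometer samples.
    """
    norm = np.linalg.norm(acc)
    if norm == 0:
        return None
    ax, ay, az = acc / norm
    x, y, z, w = q
    f1 = 2 * (x * z - w * y) - ax
    f2 = 2 * (y * z + w * x) - ay
    f3 = 1 - 2 * (x * x + y * y) - az
    grad = np.array(
        [
            2 * z * f1 + 2 * w * f2 - 4 * x * f3,
            -2 * w * f1 + 2 * z * f2 - 4 * y * f3,
            2 * x * f1 + 2 * y * f2,
            -2 * y * f1 + 2 * x * f2,
        ]
    )
    gnorm = np.linalg.norm(grad)
    if gnorm == 0:
        return None
    return grad / gnorm


# ---------------------------------------------------------------------------
# Strapdown helpers
# ---------------------------------------------------------------------------

def _world_linear_acc(
    acc: np.ndarray, orientations: np.ndarray, gravity: float = GRAVITY
) -> np.ndarray:
    """Rotate sensor acc to world and remove the gravity specific force."""
    a_w = quat_rotate(orientations, acc)
    a_w[:, 2] -= gravity
    return a_w


def _trapezoid_cumulative(values: np.ndarray, dt: float,
                          initial: np.ndarray | None = None) -> np.ndarray:
    """Cumulative trapezoidal integral, same length as input, out[0]=initial."""
    out = np.zeros_like(values)
    if initial is not None:
        out[0] = initial
    increments = 0.5 * dt * (values[1:] + values[:-1])
    out[1:] = out[0] + np.cumsum(increments, axis=0)
    return out


# ---------------------------------------------------------------------------
# Dedrifted double integration
# ---------------------------------------------------------------------------

def forward_backward_integration(
    rec: ImuRecording,
    orientations: np.ndarray,
    region: tuple[int, int] | None = None,
    *,
    gravity: float = GRAVITY,
    weight_steepness: float = 10.0,
) -> Trajectory:
    """Drift-free position over a region bounded by zero-velocity instants.

    Velocity is integrated forward with ``v(start) = 0`` and backward
    with ``v(end) = 0``; the two are blended with a sigmoid ramp so the
    boundary conditions hold exactly at both ends.  The vertical position
    is linearly detrended so ``z(end) == z(start)`` (level-walking
    assumption).
    """
    start, end = region if region is not None else (0, rec.n_samples)
    if end - start < 3:
        raise ValueError("region must span at least 3 samples")
    dt = 1.0 / rec.sampling_rate
    q = orientations[start:end]
    a_w = _world_linear_acc(rec.acc[start:end], q, gravity)
    v_fwd = _trapezoid_cumulative(a_w, dt)
    v_bwd = _trapezoid_cumulative(a_w[::-1], dt)[::-1] * -1.0
    n = end - start
    s = np.linspace(0.0, 1.0, n)
    w = expit(weight_steepness * (s - 0.5))[:, None]
    v = (1 - w) * v_fwd + w * v_bwd
    pos = _trapezoid_cumulative(v, dt)
    pos[:, 2] -= np.linspace(0.0, pos[-1, 2] - pos[0, 2], n)
    return Trajectory(position=pos, orientation=q, sampling_rate=rec.sampling_rate)


def piecewise_linear_dedrifted_integration(
    rec: ImuRecording,
    orientations: np.ndarray,
    zupts: IntervalList,
    *,
    gravity: float = GRAVITY,
) -> Trajectory:
    """Double integration with a piecewise-linear velocity drift model.

    The raw integrated velocity is assumed to be the true velocity plus a
    drift that is linear in time between zero-velocity regions.  The
    drift series equals the measured velocity at each ZUPT midpoint, is
    linearly interpolated between midpoints and held constant outside the
    first/last; after subtraction the velocity is clamped to exactly zero
    inside every ZUPT region.
    """
    if len(zupts) < 2:
        raise ValueError(
            "need at least 2 ZUPT regions; use forward_backward_integration "
            "for single-region data"
        )
    dt = 1.0 / rec.sampling_rate
    a_w = _world_linear_acc(rec.acc, orientations, gravity)
    v_raw = _trapezoid_cumulative(a_w, dt)
    mids = ((zupts.starts + zupts.ends - 1) // 2).astype(int)
    t = np.arange(rec.n_samples)
    drift = np.column_stack(
        [np.interp(t, mids, v_raw[mids, axis]) for axis in range(3)]
    )
    v = v_raw - drift
    v[zupts.to_mask(rec.n_samples)] = 0.0
    pos = _trapezoid_cumulative(v, dt)
    return Trajectory(position=pos, orientation=orientations,
                      sampling_rate=rec.sampling_rate)


# ---------------------------------------------------------------------------
# ZUPT-aided error-state Kalman filter with RTS smoothing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KalmanConfig:
    """Noise densities and initial covariance of the error-state filter.

    ``accel_noise`` (m/s²·√s) and ``gyro_noise`` (deg/s·√s) are white
    process-noise densities; ``zupt_measurement_noise`` (m/s) is the
    standard deviation of the pseudo-measurement "velocity is zero".
    Defaults are simulator-calibrated, non-normative values in the range
    typical for consumer MEMS sensors.
    """

    accel_noise: float = 0.1
    gyro_noise: float = 0.1
    zupt_measurement_noise: float = 1e-3
    initial_covariance: tuple = (1e-8,) * 3 + (1e-8,) * 3 + (1e-8,) * 3
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        if not (self.accel_noise > 0 and self.gyro_noise > 0
                and self.zupt_measurement_noise > 0):
            raise ValueError("all noise parameters must be positive")
        if len(self.initial_covariance) != 9:
            raise ValueError("initial_covariance needs 9 diagonal entries")


@dataclass(frozen=True)
class RtsKalmanResult:
    """Smoothed trajectory plus diagnostics of the forward pass."""

    trajectory: Trajectory
    velocity: np.ndarray  # smoothed world velocity (n, 3) m/s
    filtered_trajectory: Trajectory
    filtered_velocity: np.ndarray
    filtered_cov_trace: np.ndarray  # trace of P_filtered per sample
    smoothed_cov_trace: np.ndarray


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def rts_kalman(
    rec: ImuRecording,
    zupts: IntervalList,
    cfg: KalmanConfig | None = None,
    q0: np.ndarray | None = None,
    p0: np.ndarray | None = None,
) -> RtsKalmanResult:
    """ZUPT-aided error-state Kalman filter with RTS smoothing.

    The nominal state is propagated by strapdown integration; a 9-dim
    error state (δp, δv, δθ — local multiplicative orientation error,
    rotation-vector parameterization) is filtered with a zero-velocity
    measurement at every sample inside a ZUPT region, then smoothed
    backward with the Rauch-Tung-Striebel gain
    ``C_k = P_k F_kᵀ P⁻¹_pred,k+1``.  The smoothed errors are injected
    into the nominal trajectory once, after smoothing (position and
    velocity additively, orientation as ``q ⊗ Δq(δθ)``).
    """
    cfg = cfg or KalmanConfig()
    q0 = quat_identity() if q0 is None else np.asarray(q0, dtype=float)
    p0 = np.zeros(3) if p0 is None else np.asarray(p0, dtype=float)
    n = rec.n_samples
    dt = 1.0 / rec.sampling_rate
    zupt_mask = zupts.to_mask(n)
    if not zupt_mask[0]:
        warnings.warn("no ZUPT at region start; initial velocity assumed 0")

    # --- nominal strapdown -------------------------------------------------
    quats = integrate_gyro(rec, q0)
    a_w = _world_linear_acc(rec.acc, quats, cfg.gravity)
    vel = _trapezoid_cumulative(a_w, dt)
    pos = _trapezoid_cumulative(vel, dt, initial=p0)

    # --- forward filter on the error state --------------------------------
    sigma_g_rad = np.deg2rad(cfg.gyro_noise)
    q_proc = np.zeros((9, 9))
    q_proc[3:6, 3:6] = np.eye(3) * cfg.accel_noise**2 * dt
    q_proc[6:9, 6:9] = np.eye(3) * sigma_g_rad**2 * dt
    r_meas = np.eye(3) * cfg.zupt_measurement_noise**2
    h = np.zeros((3, 9))
    h[:, 3:6] = np.eye(3)

    x_filt = np.zeros((n, 9))
    x_pred = np.zeros((n, 9))
    p_filt = np.zeros((n, 9, 9))
    p_pred = np.zeros((n, 9, 9))
    f_mats = np.zeros((n - 1, 9, 9)) if n > 1 else np.zeros((0, 9, 9))

    p_cur = np.diag(np.asarray(cfg.initial_covariance, dtype=float))
    x_cur = np.zeros(9)
    x_pred[0] = x_cur
    p_pred[0] = p_cur
    x_cur, p_cur = _maybe_update(x_cur, p_cur, zupt_mask[0], vel[0], h, r_meas)
    x_filt[0], p_filt[0] = x_cur, p_cur

    eye9 = np.eye(9)
    omega_rad = np.deg2rad(rec.gyr)
    for k in range(n - 1):
        f = eye9.copy()
        f[0:3, 3:6] = np.eye(3) * dt
        rot_acc = quat_rotate(quats[k], rec.acc[k])
        f[3:6, 6:9] = -_skew(rot_acc) * dt
        f[6:9, 6:9] = np.eye(3) - _skew(omega_rad[k]) * dt
        f_mats[k] = f
        x_cur = f @ x_cur
        p_cur = f @ p_cur @ f.T + q_proc
        x_pred[k + 1] = x_cur
        p_pred[k + 1] = p_cur
        if not np.all(np.isfinite(p_cur)):
            raise FloatingPointError(
                f"non-finite covariance at sample {k + 1}"
            )
        x_cur, p_cur = _maybe_update(
            x_cur, p_cur, zupt_mask[k + 1], vel[k + 1], h, r_meas
        )
        x_filt[k + 1], p_filt[k + 1] = x_cur, p_cur

    # --- RTS backward smoothing -------------------------------------------
    x_smooth = x_filt.copy()
    p_smooth = p_filt.copy()
    for k in range(n - 2, -1, -1):
        c = p_filt[k] @ f_mats[k].T @ np.linalg.inv(p_pred[k + 1])
        x_smooth[k] = x_filt[k] + c @ (x_smooth[k + 1] - x_pred[k + 1])
        p_smooth[k] = p_filt[k] + c @ (p_smooth[k + 1] - p_pred[k + 1]) @ c.T

    smoothed = _inject(pos, vel, quats, x_smooth, rec.sampling_rate)
    filtered = _inject(pos, vel, quats, x_filt, rec.sampling_rate)
    return RtsKalmanResult(
        trajectory=smoothed[0],
        velocity=smoothed[1],
        filtered_trajectory=filtered[0],
        filtered_velocity=filtered[1],
        filtered_cov_trace=np.trace(p_filt, axis1=1, axis2=2),
        smoothed_cov_trace=np.trace(p_smooth, axis1=1, axis2=2),
    )


def _maybe_update(x, p, is_zupt, v_nominal, h, r_meas):
    if not is_zupt:
        return x, p
    innov = -v_nominal - h @ x
    s = h @ p @ h.T + r_meas
    k_gain = p @ h.T @ np.linalg.inv(s)
    x = x + k_gain @ innov
    ikh = np.eye(9) - k_gain @ h
    p = ikh @ p @ ikh.T + k_gain @ r_meas @ k_gain.T  # Joseph form
    return x, p


def _inject(pos, vel, quats, errors, sampling_rate):
    pos_c = pos + errors[:, 0:3]
    vel_c = vel + errors[:, 3:6]
    dtheta = errors[:, 6:9]
    angle = np.linalg.norm(dtheta, axis=1)
    axis = np.where(angle[:, None] == 0, 0.0,
                    dtheta / np.where(angle[:, None] == 0, 1.0, angle[:, None]))
    dq = quat_from_axis_angle(axis, angle)
    quats_c = quat_normalize(quat_multiply(quats, dq))
    traj = Trajectory(position=pos_c, orientation=quats_c,
                      sampling_rate=sampling_rate)
    return traj, vel_c
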