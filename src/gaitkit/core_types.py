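"""Standardized data model: units, frames, quaternions, interval lists.

Conventions used across the package
-----------------------------------
* Acceleration in m/s² (specific force: a static, level sensor reads
  ``(0, 0, +9.81)``), angular velocity in deg/s.
* Orientations are unit quaternions stored in ``(x, y, z, w)`` order,
  Hamilton convention, acting as active rotations.
* All interval lists (strides, ZUPT regions) are 0-based, half-open
  ``[start, end)`` sample indices, sorted and non-overlapping.
* Sensor frame: x points roughly forward, y to the left, z up.
* Body frame axes (pa, ml, si): posterior→anterior, medial→lateral,
  superior→inferior.  Left and right body frames are mirror images of
  each other, so the same anatomical movement yields the same
  body-frame signal on either foot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

GRAVITY = 9.81
"""Magnitude of the specific-force reading of a static, level sensor (m/s²)."""

GRAVITY_VECTOR = np.array([0.0, 0.0, GRAVITY])
"""World-frame specific force of a static sensor: +z up, magnitude g."""

INDEX_CONVENTION = "0-based,half-open"

Frame = Literal["sensor", "body", "world-aligned"]
Side = Literal["left", "right", "n/a"]

#: Column order of body-frame signal arrays.
BODY_FRAME_AXES = ("pa", "ml", "si")


# ---------------------------------------------------------------------------
# Quaternion algebra — (x, y, z, w) storage, Hamilton convention, active.
# ---------------------------------------------------------------------------

def quat_identity() -> np.ndarray:
    """Identity rotation ``(0, 0, 0, 1)``."""
    return np.array([0.0, 0.0, 0.0, 1.0])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Return ``q`` scaled to unit norm (works on ``(..., 4)`` arrays)."""
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("cannot normalize a zero quaternion")
    return q / norm


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    """Conjugate (inverse for unit quaternions): negate the vector part."""
    q = np.asarray(q, dtype=float)
    return q * np.array([-1.0, -1.0, -1.0, 1.0])


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product ``q1 ⊗ q2`` on ``(..., 4)`` arrays in (x,y,z,w) order.

    The composed rotation applies ``q2`` first, then ``q1``:
    ``rotate(q1 ⊗ q2, v) == rotate(q1, rotate(q2, v))``.
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    x1, y1, z1, w1 = np.moveaxis(q1, -1, 0)
    x2, y2, z2, w2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        ],
        axis=-1,
    )


def quat_from_axis_angle(axis: np.ndarray, angle_rad: float | np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_rad`` about ``axis``.

    ``axis`` is normalized internally; a zero-norm axis with zero angle
    yields the identity.  Broadcasts over leading dimensions.
    """
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle_rad, dtype=float)
    norm = np.linalg.norm(axis, axis=-1, keepdims=True)
    safe = np.where(norm == 0, 1.0, norm)
    unit = axis / safe
    half = angle / 2.0
    xyz = unit * np.sin(half)[..., None]
    w = np.cos(half)[..., None]
    return np.concatenate([xyz, w], axis=-1)


def quat_to_rotation_vector(q: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle, rad) of a unit quaternion ``(..., 4)``."""
    q = np.asarray(q, dtype=float)
    # enforce the short arc (w >= 0) so the angle is in [0, pi]
    q = np.where(q[..., 3:4] < 0, -q, q)
    xyz = q[..., :3]
    w = np.clip(q[..., 3], -1.0, 1.0)
    sin_half = np.linalg.norm(xyz, axis=-1)
    angle = 2.0 * np.arctan2(sin_half, w)
    scale = np.where(sin_half > 1e-12, angle / np.where(sin_half == 0, 1.0, sin_half), 2.0)
    return xyz * scale[..., None]


def quat_rotate(q: np.ndarray, v: np.ndarray, *, tol: float = 1e-6) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q`` (active rotation).

    Raises ``ValueError`` when ``q`` is not a unit quaternion within
    ``tol``.  Norm of ``v`` is preserved exactly up to floating point.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norm - 1.0) > tol):
        raise ValueError("quat_rotate requires unit quaternions")
    xyz = q[..., :3]
    w = q[..., 3:4]
    # v' = v + 2 w (q_v × v) + 2 q_v × (q_v × v)
    t = 2.0 * np.cross(xyz, v)
    return v + w * t + np.cross(xyz, t)


# ---------------------------------------------------------------------------
# Interval lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalList:
    """Sorted, non-overlapping 0-based half-open ``[start, end)`` intervals."""

    intervals: np.ndarray  # (n, 2) int

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.intervals, dtype=int))
        if arr.size == 0:
            arr = np.empty((0, 2), dtype=int)
        if arr.shape[1] != 2:
            raise ValueError("intervals must be an (n, 2) array")
        if np.any(arr[:, 0] < 0) or np.any(arr[:, 0] >= arr[:, 1]):
            raise ValueError("each interval needs 0 <= start < end")
        if arr.shape[0] > 1:
            if np.any(np.diff(arr[:, 0]) < 0):
                raise ValueError("intervals must be sorted by start")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError("intervals must not overlap")
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.intervals[:, 1]

    def to_mask(self, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask of length ``n_samples``."""
        mask = np.zeros(n_samples, dtype=bool)
        for start, end in self.intervals:
            mask[start:min(end, n_samples)] = True
        return mask

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "IntervalList":
        """Maximal runs of ``True`` in a boolean mask as intervals."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0:
            return cls(np.empty((0, 2), dtype=int))
        edges = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if mask[0]:
            starts = np.r_[0, starts]
        if mask[-1]:
            ends = np.r_[ends, mask.size]
        return cls(np.column_stack([starts, ends]))


StrideList = IntervalList
ZuptSequence = IntervalList


# ---------------------------------------------------------------------------
# Event list
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventList:
    """Per-stride gait events as absolute sample indices.

    ``tc`` (terminal contact / toe-off), ``ic`` (initial contact / heel
    strike) and ``min_vel`` (mid-stance) are float arrays holding integer
    indices; strides whose events could not be determined carry
    ``detectable == False`` and NaN entries (the flag is authoritative).
    """

    stride_id: np.ndarray
    tc: np.ndarray
    ic: np.ndarray
    min_vel: np.ndarray
    detectable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sid = np.atleast_1d(np.asarray(self.stride_id, dtype=int))
        tc = np.atleast_1d(np.asarray(self.tc, dtype=float))
        ic = np.atleast_1d(np.asarray(self.ic, dtype=float))
        mv = np.atleast_1d(np.asarray(self.min_vel, dtype=float))
        if self.detectable is None:
            det = ~(np.isnan(tc) | np.isnan(ic) | np.isnan(mv))
        else:
            det = np.atleast_1d(np.asarray(self.detectable, dtype=bool))
        lengths = {sid.size, tc.size, ic.size, mv.size, det.size}
        if len(lengths) != 1:
            raise ValueError("all event columns must have the same length")
        object.__setattr__(self, "stride_id", sid)
        object.__setattr__(self, "tc", tc)
        object.__setattr__(self, "ic", ic)
        object.__setattr__(self, "min_vel", mv)
        object.__setattr__(self, "detectable", det)

    def __len__(self) -> int:
        return self.stride_id.size

    def validate_against(self, strides: IntervalList) -> None:
        """Check that every detectable event lies inside its stride and tc < ic."""
        if len(self) != len(strides):
            raise ValueError("event list and stride list length mismatch")
        for k in range(len(self)):
            if not self.detectable[k]:
                continue
            start, end = strides.intervals[k]
            for name in ("tc", "ic", "min_vel"):
                idx = getattr(self, name)[k]
                if not (start <= idx < end):
                    raise ValueError(
                        f"event {name}={idx} outside stride [{start}, {end})"
                    )
            if not self.tc[k] < self.ic[k]:
                raise ValueError(f"stride {self.stride_id[k]}: tc must precede ic")


# ---------------------------------------------------------------------------
# IMU recording
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImuRecording:
    """Fixed-rate 6-axis IMU time series in a declared coordinate frame.

    ``acc`` in m/s² and ``gyr`` in deg/s, both ``(n, 3)``.  Sensor- and
    world-aligned-frame columns are (x, y, z); body-frame columns are
    (pa, ml, si).
    """

    acc: np.ndarray
    gyr: np.ndarray
    sampling_rate: float
    frame: Frame = "sensor"
    side: Side = "n/a"

    def __post_init__(self) -> None:
        acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        gyr = np.atleast_2d(np.asarray(self.gyr, dtype=float))
        if acc.shape != gyr.shape or acc.ndim != 2 or acc.shape[1] != 3:
            raise ValueError("acc and gyr must both be (n, 3) with equal n")
        if acc.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.frame not in ("sensor", "body", "world-aligned"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.side not in ("left", "right", "n/a"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.frame == "body" and self.side == "n/a":
            raise ValueError("body-frame recordings must declare a side")
        object.__setattr__(self, "acc", acc)
        object.__setattr__(self, "gyr", gyr)

    def __len__(self) -> int:
        return self.acc.shape[0]

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """Per-sample world-frame position (m) and unit-quaternion orientation."""

    position: np.ndarray  # (n, 3) m
    orientation: np.ndarray  # (n, 4) unit quaternions, (x,y,z,w)
    sampling_rate: float

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.position, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientation, dtype=float))
        if pos.shape[1] != 3 or ori.shape[1] != 4 or pos.shape[0] != ori.shape[0]:
            raise ValueError("position (n,3) and orientation (n,4) must align")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        norms = np.linalg.norm(ori, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("all orientations must be unit quaternions")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", ori)

    def __len__(self) -> int:
        return self.position.shape[0]


# ---------------------------------------------------------------------------
# Sensor-frame <-> body-frame conversion
# ---------------------------------------------------------------------------

# Point-vector (acceleration) mapping, rows = (pa, ml, si) in sensor (x, y, z):
#   pa = +x, si = -z for both feet; ml = +y (left) / -y (right).
_ACC_MATRIX = {
    "left": np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, -1.0]]),
    "right": np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]]),
}
# Angular velocity is a pseudo-vector: under the improper (mirror) part of
# the mapping it picks up an extra handedness sign det(A).  This is what
# makes left and right body-frame gyroscope traces identical for identical
# anatomical motion (e.g. dorsiflexion is gyr_ml > 0 on both feet).
_GYR_MATRIX = {
    side: np.linalg.det(mat) * mat for side, mat in _ACC_MATRIX.items()
}


def to_body_frame(rec: ImuRecording, side: Side | None = None) -> ImuRecording:
    """Convert a sensor-frame recording to the mirrored (pa, ml, si) body frame.

    The conversion is a fixed axis relabeling with signs; it preserves
    per-sample vector norms and is exactly invertible via
    :func:`from_body_frame`.
    """
    if rec.frame != "sensor":
        raise ValueError("to_body_frame expects a sensor-frame recording")
    side = side if side is not None else rec.side
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    acc = rec.acc @ _ACC_MATRIX[side].T
    gyr = rec.gyr @ _GYR_MATRIX[side].T
    return ImuRecording(acc=acc, gyr=gyr, sampling_rate=rec.sampling_rate,
                        frame="body", side=side)


def from_body_frame(rec: ImuRecording) -> ImuRecording:
    """Invert :func:`to_body_frame` (bitwise, the matrices are orthogonal signed
    permutations)."""
    if rec.frame != "body":
        raise ValueError("from_body_frame expects a body-frame recording")
    acc = rec.acc @ _ACC_MATRIX[rec.side]  # A^-1 == A^T; columns are ±unit
    gyr = rec.gyr @ _GYR_MATRIX[rec.side]
    return ImuRecording(acc=acc, gyr=gyr, sampling_rate=rec.sampling_rate,
                        frame="sensor", side=rec.side)


def body_frame_matrices(side: Side) -> tuple[np.ndarray, np.ndarray]:
    """Return (acc, gyr) sensor→body matrices for ``side`` (copies)."""
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return _ACC_MATRIX[side].copy(), _GYR_MATRIX[side].copy()
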