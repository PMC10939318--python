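"""Static-window detection and gravity alignment of raw recordings.

Before any trajectory math the recording is rotated so that the gravity
vector measured while the sensor is at rest points along world +z with
magnitude 9.81 m/s² (specific-force convention).  Rest is detected from
the gyroscope norm with a 1-sample-hop sliding window; all passing
windows are merged into maximal static regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from gaitkit.core_types import (
    GRAVITY,
    GRAVITY_VECTOR,
    ImuRecording,
    IntervalList,
    quat_from_axis_angle,
    quat_rotate,
)


@dataclass(frozen=True)
class StaticWindowConfig:
    """Window detector configuration.

    ``window_length`` in seconds; ``metric`` is applied to the per-sample
    gyroscope norm inside each window; ``threshold`` in deg/s (or (deg/s)²
    for the variance metric).
    """

    window_length: float = 0.1
    metric: Literal["mean", "max", "variance"] = "mean"
    threshold: float = 5.0

    def __post_init__(self) -> None:
        if not self.window_length > 0:
            raise ValueError("window_length must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.metric not in ("mean", "max", "variance"):
            raise ValueError(f"unknown metric {self.metric!r}")


def _window_metric(values: np.ndarray, window: int, metric: str) -> np.ndarray:
    """Metric of every length-``window`` sliding window (hop 1) of ``values``."""
    views = np.lib.stride_tricks.sliding_window_view(values, window)
    if metric == "mean":
        return views.mean(axis=1)
    if metric == "max":
        return views.max(axis=1)
    return views.var(axis=1)


def find_static_windows(rec: ImuRecording, cfg: StaticWindowConfig | None = None) -> IntervalList:
    """Maximal regions where the windowed gyr-norm metric stays below threshold.

    Windows slide with a 1-sample hop; every sample covered by at least one
    passing window belongs to a static region.  Strictly-below comparison,
    so a zero threshold on a noisy signal yields an empty list.
    """
    cfg = cfg or StaticWindowConfig()
    window = max(1, round(cfg.window_length * rec.sampling_rate))
    if window > rec.n_samples:
        raise ValueError(
            f"window of {window} samples longer than recording ({rec.n_samples})"
        )
    gyr_norm = np.linalg.norm(rec.gyr, axis=1)
    stats = _window_metric(gyr_norm, window, cfg.metric)
    passing = stats < cfg.threshold
    mask = np.zeros(rec.n_samples, dtype=bool)
    # window i covers samples [i, i + window)
    for i in np.flatnonzero(passing):
        mask[i:i + window] = True
    return IntervalList.from_mask(mask)


def align_to_gravity(
    rec: ImuRecording, cfg: StaticWindowConfig | None = None
) -> tuple[ImuRecording, np.ndarray]:
    """Rotate the recording so the mean static acc maps onto ``(0, 0, 9.81)``.

    The rotation is the single shortest-arc rotation taking the pooled
    mean acceleration over all detected static samples to the world
    vertical.  Returns the rotated recording and the rotation quaternion.

    Raises if no static window is found (rotate manually in that case) or
    if the mean static acceleration is implausibly small (free-fall-like).
    """
    cfg = cfg or StaticWindowConfig()
    static = find_static_windows(rec, cfg)
    if len(static) == 0:
        raise ValueError(
            "no static window found; supply a manual rotation instead"
        )
    mask = static.to_mask(rec.n_samples)
    mean_acc = rec.acc[mask].mean(axis=0)
    if np.linalg.norm(mean_acc) < 0.5 * GRAVITY:
        raise ValueError(
            "mean static acceleration below 0.5 g; data looks free-fall-like"
        )
    q = shortest_arc_rotation(mean_acc, GRAVITY_VECTOR)
    acc = quat_rotate(q[None, :], rec.acc)
    gyr = quat_rotate(q[None, :], rec.gyr)
    aligned = ImuRecording(
        acc=acc, gyr=gyr, sampling_rate=rec.sampling_rate,
        frame=rec.frame, side=rec.side,
    )
    return aligned, q


def shortest_arc_rotation(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal-angle rotation mapping direction ``v_from`` onto ``v_to``.

    Built from the half-angle formula on the normalized cross product.
    Antiparallel inputs are a 180° rotation; the axis is then ambiguous
    and fixed to +x (deterministic tie-break).
    """
    a = np.asarray(v_from, dtype=float)
    b = np.asarray(v_to, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    dot = float(np.clip(a @ b, -1.0, 1.0))
    if dot < -1.0 + 1e-12:
        return quat_from_axis_angle(np.array([1.0, 0.0, 0.0]), np.pi)
    cross = np.cross(a, b)
    # q = [cross / (2 cos(theta/2)), cos(theta/2)] with cos(theta/2) from dot
    cos_half = np.sqrt((1.0 + dot) / 2.0)
    xyz = cross / (2.0 * cos_half)
    q = np.array([*xyz, cos_half])
    return q / np.linalg.norm(q)
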