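"""Per-stride spatio-temporal gait parameters.

Temporal parameters come from the event list (units: seconds):
``stride_time_k = (ic_k − ic_{k−1}) / rate``,
``swing_time_k = (ic_k − tc_k) / rate``,
``stance_time_k = stride_time_k − swing_time_k``.
The first stride of a sequence has no preceding initial contact and
therefore yields only its swing time.

Spatial parameters come from the reconstructed trajectory evaluated at
min_vel-stride borders: stride length is the ground-plane (x, y)
displacement between stride start and end (the level-walking convention;
the 3-D norm is available behind a flag), and gait velocity is stride
length over stride time.  Missing inputs yield NaN entries flagged as
missing — never silent zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gaitkit.core_types import EventList, StrideList, Trajectory


def temporal_parameters(events: EventList, rate: float) -> pd.DataFrame:
    """Stride, swing and stance time (s) per stride, indexed by stride_id."""
    if not rate > 0:
        raise ValueError("rate must be positive")
    n = len(events)
    if n < 2:
        raise ValueError("need at least 2 consecutive strides with events")
    stride_time = np.full(n, np.nan)
    swing_time = np.full(n, np.nan)
    stance_time = np.full(n, np.nan)
    for k in range(n):
        if not events.detectable[k]:
            continue
        swing_time[k] = (events.ic[k] - events.tc[k]) / rate
        if k > 0 and events.detectable[k - 1]:
            stride_time[k] = (events.ic[k] - events.ic[k - 1]) / rate
            stance_time[k] = stride_time[k] - swing_time[k]
    return pd.DataFrame(
        {
            "stride_id": events.stride_id,
            "stride_time": stride_time,
            "swing_time": swing_time,
            "stance_time": stance_time,
        }
    ).set_index("stride_id")


def spatial_parameters(
    traj: Trajectory,
    strides: StrideList,
    temporal: pd.DataFrame | None = None,
    *,
    use_3d_norm: bool = False,
) -> pd.DataFrame:
    """Stride length (m) and gait velocity (m/s) per min_vel stride.

    ``strides`` must be covered by the trajectory; ``temporal`` (as
    returned by :func:`temporal_parameters`, aligned by position) supplies
    the stride times for the velocity; without it velocity falls back to
    stride borders over the sampling rate.
    """
    n_traj = len(traj)
    lengths = np.full(len(strides), np.nan)
    for k, (start, end) in enumerate(strides):
        if end > n_traj or start >= n_traj:
            raise ValueError(f"trajectory does not cover stride {k}")
        disp = traj.position[min(end, n_traj - 1)] - traj.position[start]
        if use_3d_norm:
            lengths[k] = np.linalg.norm(disp)
        else:
            lengths[k] = np.hypot(disp[0], disp[1])
    if temporal is not None:
        if len(temporal) != len(strides):
            raise ValueError("temporal table and stride list length mismatch")
        stride_time = temporal["stride_time"].to_numpy()
    else:
        stride_time = (
            np.diff(np.r_[strides.starts, strides.ends[-1]])
            / traj.sampling_rate
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        velocity = lengths / stride_time
    return pd.DataFrame(
        {
            "stride_id": np.arange(len(strides)),
            "stride_length": lengths,
            "stride_time": stride_time,
            "gait_velocity": velocity,
        }
    ).set_index("stride_id")
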