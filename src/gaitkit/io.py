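"""Reading and writing the package's on-disk formats.

IMU recordings travel as delimited text with columns
``acc_x, acc_y, acc_z, gyr_x, gyr_y, gyr_z`` (or ``acc_pa, ...`` for
body-frame data); sampling rate and frame/side live in a JSON sidecar or
are passed explicitly.  Interval, stride and event lists are JSON with an
explicit ``"0-based,half-open"`` convention marker.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gaitkit.core_types import (
    BODY_FRAME_AXES,
    INDEX_CONVENTION,
    EventList,
    ImuRecording,
    IntervalList,
)

_SENSOR_COLS = [f"{s}_{a}" for s in ("acc", "gyr") for a in ("x", "y", "z")]
_BODY_COLS = [f"{s}_{a}" for s in ("acc", "gyr") for a in BODY_FRAME_AXES]


def write_imu_csv(path: str | Path, rec: ImuRecording) -> None:
    """Write a recording as CSV plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    cols = _BODY_COLS if rec.frame == "body" else _SENSOR_COLS
    df = pd.DataFrame(np.hstack([rec.acc, rec.gyr]), columns=cols)
    df.to_csv(path, index=False)
    sidecar = {
        "sampling_rate_hz": rec.sampling_rate,
        "frame": rec.frame,
        "side": rec.side,
        "units": {"acc": "m/s^2", "gyr": "deg/s"},
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_imu_csv(
    path: str | Path,
    sampling_rate: float | None = None,
    frame: str | None = None,
    side: str | None = None,
) -> ImuRecording:
    """Read a recording; metadata comes from the sidecar unless overridden."""
    path = Path(path)
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    sampling_rate = sampling_rate or meta.get("sampling_rate_hz")
    if sampling_rate is None:
        raise ValueError("sampling_rate not given and no sidecar found")
    frame = frame or meta.get("frame", "sensor")
    side = side or meta.get("side", "n/a")
    df = pd.read_csv(path)
    cols = _BODY_COLS if frame == "body" else _SENSOR_COLS
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing signal columns: {missing}")
    return ImuRecording(
        acc=df[cols[:3]].to_numpy(),
        gyr=df[cols[3:]].to_numpy(),
        sampling_rate=float(sampling_rate),
        frame=frame,  # type: ignore[arg-type]
        side=side,  # type: ignore[arg-type]
    )


def write_interval_list(path: str | Path, intervals: IntervalList) -> None:
    payload = {
        "convention": INDEX_CONVENTION,
        "intervals": [
            {"start": int(s), "end": int(e)} for s, e in intervals
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_interval_list(path: str | Path) -> IntervalList:
    payload = json.loads(Path(path).read_text())
    if payload.get("convention") != INDEX_CONVENTION:
        raise ValueError(f"expected convention {INDEX_CONVENTION!r}")
    arr = [(item["start"], item["end"]) for item in payload["intervals"]]
    return IntervalList(np.asarray(arr, dtype=int).reshape(-1, 2))


def write_event_list(path: str | Path, events: EventList) -> None:
    rows = []
    for k in range(len(events)):
        row: dict = {"stride_id": int(events.stride_id[k]),
                     "detectable": bool(events.detectable[k])}
        for name in ("tc", "ic", "min_vel"):
            val = getattr(events, name)[k]
            row[name] = None if np.isnan(val) else int(val)
        rows.append(row)
    payload = {"convention": INDEX_CONVENTION, "events": rows}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_event_list(path: str | Path) -> EventList:
    payload = json.loads(Path(path).read_text())
    if payload.get("convention") != INDEX_CONVENTION:
        raise ValueError(f"expected convention {INDEX_CONVENTION!r}")
    rows = payload["events"]
    nan = float("nan")
    return EventList(
        stride_id=[r["stride_id"] for r in rows],
        tc=[nan if r["tc"] is None else r["tc"] for r in rows],
        ic=[nan if r["ic"] is None else r["ic"] for r in rows],
        min_vel=[nan if r["min_vel"] is None else r["min_vel"] for r in rows],
        detectable=[r["detectable"] for r in rows],
    )
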