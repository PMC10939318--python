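"""Gait-event detection inside segmented strides.

Works on body-frame signals, where the mid-swing rotation of the foot
produces the dominant positive peak of ``gyr_ml`` (dorsiflexion positive
on both feet thanks to the mirrored body frames):

* ``tc`` (terminal contact / toe-off): the last non-positive sample of
  ``gyr_ml`` before the swing peak — i.e. the zero crossing from
  negative (or rest) to positive that launches the swing.
* ``ic`` (initial contact / heel strike): the minimum of the
  posterior-anterior acceleration ``acc_pa`` in a window after the swing
  peak; the landing foot brakes hard, so ``acc_pa`` dips sharply at
  contact.  The "filtered" variant low-passes the gyroscope channels
  that define the search windows (zero-phase Butterworth), which
  stabilizes peak and zero-crossing localization under sensor noise;
  the sharp accelerometer landing spike itself is left untouched.
* ``min_vel`` (mid-stance): the center of the window with minimal
  gyroscope energy after ``ic``.

Strides whose signals do not show the expected structure (e.g. a flat
``gyr_ml``) are flagged not-detectable rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from gaitkit.core_types import EventList, ImuRecording, IntervalList, StrideList


@dataclass(frozen=True)
class EventDetectionConfig:
    """Search windows and (optional) filtering for event detection.

    ``ic_search_fraction`` bounds the ic search to that fraction of the
    stride after the swing peak; ``min_vel_window`` (s) is the energy
    window for mid-stance; setting ``lowpass_cutoff`` (Hz) activates the
    filtered variant.  All values are non-normative defaults.
    """

    ic_search_fraction: float = 0.5
    min_vel_window: float = 0.1
    lowpass_cutoff: float | None = None
    filter_order: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.ic_search_fraction <= 1:
            raise ValueError("ic_search_fraction must be in (0, 1]")
        if not self.min_vel_window > 0:
            raise ValueError("min_vel_window must be positive")
        if self.lowpass_cutoff is not None and not self.lowpass_cutoff > 0:
            raise ValueError("lowpass_cutoff must be positive")


FILTERED_DEFAULTS = EventDetectionConfig(lowpass_cutoff=15.0, filter_order=2)
"""Filtered-variant preset: zero-phase Butterworth, order 2, 15 Hz."""


def detect_events(
    rec: ImuRecording,
    strides: StrideList,
    cfg: EventDetectionConfig | None = None,
) -> EventList:
    """Detect tc, ic and min_vel in every stride; indices are absolute.

    Requires a body-frame recording.  Undetectable strides are flagged,
    with NaN event entries.
    """
    cfg = cfg or EventDetectionConfig()
    if rec.frame != "body":
        raise ValueError("detect_events expects a body-frame recording")
    gyr = rec.gyr
    acc_pa = rec.acc[:, 0]
    if cfg.lowpass_cutoff is not None:
        nyq = rec.sampling_rate / 2
        b, a = butter(cfg.filter_order, cfg.lowpass_cutoff / nyq, btype="low")
        gyr = filtfilt(b, a, gyr, axis=0)
    gyr_ml = gyr[:, 1]
    gyr_energy = np.sum((gyr / 100.0) ** 2, axis=1)  # scaled, units moot
    mv_window = max(1, round(cfg.min_vel_window * rec.sampling_rate))

    n = len(strides)
    tc = np.full(n, np.nan)
    ic = np.full(n, np.nan)
    min_vel = np.full(n, np.nan)
    detectable = np.zeros(n, dtype=bool)
    for k, (start, end) in enumerate(strides):
        ev = _detect_in_stride(
            gyr_ml[start:end], acc_pa[start:end], gyr_energy[start:end],
            cfg.ic_search_fraction, mv_window,
        )
        if ev is None:
            continue
        tc[k], ic[k], min_vel[k] = (v + start for v in ev)
        detectable[k] = True
    return EventList(
        stride_id=np.arange(n), tc=tc, ic=ic, min_vel=min_vel,
        detectable=detectable,
    )


def _detect_in_stride(
    gyr_ml: np.ndarray,
    acc_pa: np.ndarray,
    gyr_energy: np.ndarray,
    ic_search_fraction: float,
    mv_window: int,
) -> tuple[int, int, int] | None:
    """Event indices relative to the stride, or None if not detectable."""
    n = gyr_ml.size
    if n < 4 or not np.any(gyr_ml > 0):
        return None
    peak = int(np.argmax(gyr_ml))
    # tc: last sample at or below zero before the swing peak.  If the
    # signal is positive from the very first sample the launch happened at
    # the stride border itself.
    before = np.flatnonzero(gyr_ml[: peak + 1] <= 0)
    tc = int(before[-1]) if before.size else 0
    # ic: argmin of (filtered) acc_pa in (peak, peak + fraction * n]
    ic_end = min(n, peak + 1 + round(ic_search_fraction * n))
    if peak + 1 >= ic_end:
        return None
    ic = peak + 1 + int(np.argmin(acc_pa[peak + 1:ic_end]))
    if not tc < ic:
        return None
    # min_vel: center of the minimal-energy window in (ic, end]
    seg = gyr_energy[ic + 1:]
    if seg.size == 0:
        return None
    win = min(mv_window, seg.size)
    sums = np.convolve(seg, np.ones(win), mode="valid")
    best = int(np.argmin(sums))
    min_vel = ic + 1 + best + win // 2
    if min_vel >= n:
        min_vel = n - 1
    return tc, ic, min_vel


def to_min_vel_strides(
    events: EventList, strides: StrideList
) -> tuple[StrideList, EventList]:
    """Re-segment strides from mid-stance to mid-stance.

    Consecutive detectable strides yield min_vel strides
    ``[min_vel_k, min_vel_{k+1})``; a not-detectable stride splits the
    sequence; first/last partials are dropped, so an unbroken run of
    ``m`` strides yields ``m - 1`` min_vel strides.  Events are
    re-assigned to the new stride that contains them.
    """
    if len(events) != len(strides):
        raise ValueError("event list and stride list length mismatch")
    n_detected = int(np.sum(events.detectable))
    if n_detected < 2:
        warnings.warn("fewer than 2 detectable min_vel events; empty output")
        empty = IntervalList(np.empty((0, 2), dtype=int))
        return empty, EventList(
            stride_id=np.empty(0, dtype=int), tc=np.empty(0), ic=np.empty(0),
            min_vel=np.empty(0), detectable=np.empty(0, dtype=bool),
        )
    new_intervals = []
    for k in range(len(strides) - 1):
        if events.detectable[k] and events.detectable[k + 1]:
            new_intervals.append(
                (int(events.min_vel[k]), int(events.min_vel[k + 1]))
            )
    if not new_intervals:
        warnings.warn("no consecutive detectable strides; empty output")
        empty = IntervalList(np.empty((0, 2), dtype=int))
        return empty, EventList(
            stride_id=np.empty(0, dtype=int), tc=np.empty(0), ic=np.empty(0),
            min_vel=np.empty(0), detectable=np.empty(0, dtype=bool),
        )
    new_strides = IntervalList(np.asarray(new_intervals, dtype=int))
    # re-assign events: for stride [mv_k, mv_k+1) the tc/ic of original
    # stride k+1 fall inside it (they follow stride k+1's start > mv_k).
    tc, ic, mv, det = [], [], [], []
    all_tc = events.tc
    all_ic = events.ic
    all_mv = events.min_vel
    for start, end in new_strides:
        in_tc = [t for t in all_tc if not np.isnan(t) and start <= t < end]
        in_ic = [t for t in all_ic if not np.isnan(t) and start <= t < end]
        in_mv = [t for t in all_mv if not np.isnan(t) and start <= t < end]
        tc.append(in_tc[0] if in_tc else np.nan)
        ic.append(in_ic[0] if in_ic else np.nan)
        mv.append(in_mv[0] if in_mv else np.nan)
        det.append(bool(in_tc and in_ic))
    new_events = EventList(
        stride_id=np.arange(len(new_strides)),
        tc=np.asarray(tc), ic=np.asarray(ic), min_vel=np.asarray(mv),
        detectable=np.asarray(det, dtype=bool),
    )
    return new_strides, new_events
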