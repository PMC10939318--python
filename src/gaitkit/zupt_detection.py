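"""Zero-velocity (stance) detection by windowed thresholding.

Three detectors from the same window machinery:

* ``ared`` — angular-rate energy: mean of ``‖gyr‖²`` per window,
  threshold in (deg/s)².
* ``norm`` — generalized window thresholding: a chosen metric (mean,
  max, variance) of the chosen sensor's norm.
* ``shoe`` — the combined accelerometer/gyroscope likelihood statistic:
  per window, ``mean_k[ ‖acc_k − g·ā/‖ā‖‖²/σ_a² + ‖gyr_k‖²/σ_g² ]``
  with ``ā`` the window-mean acceleration (the gravity direction is
  estimated per window, not globally).

Windows below threshold are marked static and merged into maximal
regions.  Trailing samples not covered by any full window inherit the
label of the last evaluated window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from gaitkit.core_types import GRAVITY, ImuRecording, IntervalList


@dataclass(frozen=True)
class ZuptConfig:
    """Windowing and threshold parameters for the ZUPT detectors.

    ``window_length`` in seconds, ``window_overlap`` as fraction of the
    window; threshold units depend on the detector ((deg/s)² for ared,
    dimensionless for shoe, signal units for norm).  Defaults are
    non-normative and sized so a still foot with ~1 deg/s gyro noise
    passes the ared test.
    """

    window_length: float = 0.1
    window_overlap: float = 0.5
    threshold: float = 100.0
    detector: Literal["ared", "norm", "shoe"] = "ared"
    sensor: Literal["acc", "gyr"] = "gyr"
    metric: Literal["mean", "max", "variance"] = "mean"
    sigma_a: float = 0.1
    sigma_g: float = 1.0

    def __post_init__(self) -> None:
        if not self.window_length > 0:
            raise ValueError("window_length must be positive")
        if not 0 <= self.window_overlap < 1:
            raise ValueError("window_overlap must be in [0, 1)")
        if self.detector not in ("ared", "norm", "shoe"):
            raise ValueError(f"unknown detector {self.detector!r}")
        if not (self.sigma_a > 0 and self.sigma_g > 0):
            raise ValueError("sigma_a and sigma_g must be positive")


def _window_starts(n_samples: int, window: int, hop: int) -> np.ndarray:
    return np.arange(0, n_samples - window + 1, hop)


def _window_statistics(rec: ImuRecording, cfg: ZuptConfig, window: int,
                       starts: np.ndarray) -> np.ndarray:
    stats = np.empty(starts.size)
    for i, s in enumerate(starts):
        acc = rec.acc[s:s + window]
        gyr = rec.gyr[s:s + window]
        if cfg.detector == "ared":
            stats[i] = np.mean(np.sum(gyr**2, axis=1))
        elif cfg.detector == "norm":
            sig = acc if cfg.sensor == "acc" else gyr
            norm = np.linalg.norm(sig, axis=1)
            if cfg.metric == "mean":
                stats[i] = norm.mean()
            elif cfg.metric == "max":
                stats[i] = norm.max()
            else:
                stats[i] = norm.var()
        else:  # shoe
            mean_acc = acc.mean(axis=0)
            mean_norm = np.linalg.norm(mean_acc)
            if mean_norm == 0:
                grav = np.zeros(3)
            else:
                grav = GRAVITY * mean_acc / mean_norm
            acc_term = np.sum((acc - grav) ** 2, axis=1) / cfg.sigma_a**2
            gyr_term = np.sum(gyr**2, axis=1) / cfg.sigma_g**2
            stats[i] = np.mean(acc_term + gyr_term)
    return stats


def detect_zupt(rec: ImuRecording, cfg: ZuptConfig | None = None) -> IntervalList:
    """Zero-velocity regions of the recording as maximal merged intervals."""
    cfg = cfg or ZuptConfig()
    window = max(1, round(cfg.window_length * rec.sampling_rate))
    if window > rec.n_samples:
        raise ValueError(
            f"window of {window} samples longer than recording ({rec.n_samples})"
        )
    hop = max(1, round(window * (1 - cfg.window_overlap)))
    starts = _window_starts(rec.n_samples, window, hop)
    stats = _window_statistics(rec, cfg, window, starts)
    passing = stats < cfg.threshold
    mask = np.zeros(rec.n_samples, dtype=bool)
    for s, ok in zip(starts, passing):
        if ok:
            mask[s:s + window] = True
    # trailing samples with no full window inherit the last window's label
    last_covered = starts[-1] + window
    if last_covered < rec.n_samples and passing[-1]:
        mask[last_covered:] = True
    return IntervalList.from_mask(mask)
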