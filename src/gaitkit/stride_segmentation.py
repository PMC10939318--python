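"""Stride segmentation by subsequence dynamic time warping.

A stride template (one gait cycle of the body-frame sagittal gyroscope,
``gyr_ml``) is matched against the continuous signal with a subsequence
DTW: the accumulated-cost matrix has a free start (the first template row
is initialized to the local cost), admissible steps are diagonal,
vertical and horizontal, and every local minimum of the final-row cost
below ``max_cost`` seeds one candidate match whose start is found by
backtracking.  Overlapping candidates keep the lower cost (ties: the
earlier one), matches outside the duration bounds are dropped.

The constrained variant additionally forbids warping paths that contain
more than ``max_local_run`` consecutive vertical or horizontal steps,
which suppresses pathological matches that collapse long signal stretches
onto single template samples.

Local cost is the squared difference of amplitude-scaled samples and the
accumulated cost is *not* length-normalized, so ``max_cost`` scales with
template length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from gaitkit.core_types import IntervalList, StrideList

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=False)(func)
except Exception:  # pragma: no cover
    def _jit(func):
        return func

_NO_LIMIT = np.iinfo(np.int64).max // 2


@dataclass(frozen=True)
class StrideTemplate:
    """One-cycle ``gyr_ml`` template (deg/s) with an amplitude scaling.

    Both template and signal are divided by ``scaling`` before the squared
    difference is taken, making ``max_cost`` dimensionless.
    """

    samples: np.ndarray
    sampling_rate: float
    scaling: float = 500.0
    provenance: str = ""

    def __post_init__(self) -> None:
        samples = np.atleast_1d(np.asarray(self.samples, dtype=float))
        if samples.size < 3:
            raise ValueError("template needs at least 3 samples")
        if not self.scaling > 0:
            raise ValueError("scaling must be positive")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    def resample(self, rate: float) -> "StrideTemplate":
        """Linear-interpolation resample to ``rate`` (no-op if equal)."""
        if rate == self.sampling_rate:
            return self
        n_new = max(3, round(self.samples.size * rate / self.sampling_rate))
        old_t = np.arange(self.samples.size) / self.sampling_rate
        new_t = np.arange(n_new) / rate
        samples = np.interp(new_t, old_t, self.samples)
        return replace(self, samples=samples, sampling_rate=rate)

    def save(self, path: str | Path) -> None:
        payload = {
            "samples": self.samples.tolist(),
            "sampling_rate_hz": self.sampling_rate,
            "scaling": self.scaling,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StrideTemplate":
        payload = json.loads(Path(path).read_text())
        return cls(
            samples=np.asarray(payload["samples"], dtype=float),
            sampling_rate=payload["sampling_rate_hz"],
            scaling=payload["scaling"],
            provenance=payload.get("provenance", ""),
        )


def default_template() -> StrideTemplate:
    """The bundled synthetic one-stride ``gyr_ml`` template at 204.8 Hz."""
    ref = resources.files("gaitkit.templates") / "synthetic_stride_gyr_ml.json"
    payload = json.loads(ref.read_text())
    return StrideTemplate(
        samples=np.asarray(payload["samples"], dtype=float),
        sampling_rate=payload["sampling_rate_hz"],
        scaling=payload["scaling"],
        provenance=payload.get("provenance", ""),
    )


@dataclass(frozen=True)
class DtwConfig:
    """Matching thresholds and post-processing parameters.

    ``max_cost`` is the acceptance threshold on the accumulated (not
    length-normalized) cost of a match.  ``max_local_run`` is the maximum
    number of consecutive non-diagonal steps; ``None`` disables the local
    warping constraint.  Duration bounds and ``snap_window`` are seconds.
    The defaults are non-normative working values.
    """

    max_cost: float = 4.0
    min_match_duration: float = 0.6
    max_match_duration: float = 3.0
    max_local_run: int | None = None
    snap_window: float = 0.1

    def __post_init__(self) -> None:
        if self.max_cost < 0:
            raise ValueError("max_cost must be non-negative")
        if not 0 < self.min_match_duration <= self.max_match_duration:
            raise ValueError("need 0 < min_match_duration <= max_match_duration")
        if self.max_local_run is not None and self.max_local_run < 1:
            raise ValueError("max_local_run must be >= 1 (or None)")
        if self.snap_window < 0:
            raise ValueError("snap_window must be non-negative")


@_jit
def _dtw_forward(tpl: np.ndarray, sig: np.ndarray, max_run: int):
    """Accumulated cost and step-choice matrices of the subsequence DTW.

    choice codes: 0 = free start in row 0, 1 = diagonal, 2 = vertical,
    3 = horizontal.  Ties prefer diagonal, then vertical, then horizontal.
    ``v_run`` / ``h_run`` count consecutive vertical / horizontal steps on
    the chosen path into each cell; a step that would push a counter past
    ``max_run`` is inadmissible.
    """
    m = tpl.shape[0]
    n = sig.shape[0]
    inf = np.inf
    acc = np.empty((m, n))
    choice = np.zeros((m, n), dtype=np.int8)
    v_run = np.zeros((m, n), dtype=np.int64)
    h_run = np.zeros((m, n), dtype=np.int64)
    for j in range(n):
        d = tpl[0] - sig[j]
        acc[0, j] = d * d
    for i in range(1, m):
        for j in range(n):
            d = tpl[i] - sig[j]
            local = d * d
            best = inf
            best_step = 1
            if j > 0:
                best = acc[i - 1, j - 1]
                best_step = 1
            if v_run[i - 1, j] < max_run and acc[i - 1, j] < best:
                best = acc[i - 1, j]
                best_step = 2
            if j > 0 and h_run[i, j - 1] < max_run and acc[i, j - 1] < best:
                best = acc[i, j - 1]
                best_step = 3
            if best == inf:
                acc[i, j] = inf
                choice[i, j] = 1
                continue
            acc[i, j] = local + best
            choice[i, j] = best_step
            if best_step == 2:
                v_run[i, j] = v_run[i - 1, j] + 1
                h_run[i, j] = 0
            elif best_step == 3:
                h_run[i, j] = h_run[i, j - 1] + 1
                v_run[i, j] = 0
            else:
                v_run[i, j] = 0
                h_run[i, j] = 0
    return acc, choice


def _backtrack(choice: np.ndarray, end_col: int) -> int:
    """Follow the stored step choices from ``(m-1, end_col)`` to row 0."""
    i = choice.shape[0] - 1
    j = end_col
    while i > 0:
        step = choice[i, j]
        if step == 1:
            i -= 1
            j -= 1
        elif step == 2:
            i -= 1
        else:
            j -= 1
    return j


def _final_row_minima(final: np.ndarray, max_cost: float) -> list[int]:
    """Indices of local minima of the final-row cost strictly below max_cost.

    Plateaus contribute their last sample: a flat stretch of equally
    cheap match ends (typical when template and signal both end in a
    near-constant stance) should extend through the whole stretch rather
    than stop at its first sample.
    """
    n = final.size
    out = []
    for j in range(n):
        if not final[j] < max_cost:
            continue
        left_ok = j == 0 or final[j] <= final[j - 1]
        right_ok = j == n - 1 or final[j] < final[j + 1]
        if left_ok and right_ok:
            out.append(j)
    return out


def subsequence_dtw(
    signal: np.ndarray,
    template: StrideTemplate,
    cfg: DtwConfig | None = None,
    sampling_rate: float | None = None,
    *,
    resolve_overlaps: bool = True,
) -> tuple[StrideList, np.ndarray]:
    """Find all template matches in ``signal``; returns strides and costs.

    ``signal`` must be sampled at ``template.sampling_rate`` (pass
    ``sampling_rate`` to assert this; resample the template otherwise).
    Setting ``cfg.max_local_run`` to a finite value activates the local
    warping constraint; ``resolve_overlaps=False`` returns all duration-
    filtered candidates without the lower-cost-wins overlap resolution —
    as a plain ``(n, 2)`` index array, since raw candidates may overlap
    (useful for threshold-monotonicity analyses).
    """
    cfg = cfg or DtwConfig()
    sig = np.atleast_1d(np.asarray(signal, dtype=float))
    if sig.size == 0:
        raise ValueError("signal must not be empty")
    rate = template.sampling_rate
    if sampling_rate is not None and sampling_rate != rate:
        raise ValueError(
            f"signal rate {sampling_rate} != template rate {rate}; "
            "resample the template first"
        )
    tpl = template.samples / template.scaling
    sig_scaled = sig / template.scaling
    max_run = _NO_LIMIT if cfg.max_local_run is None else int(cfg.max_local_run)
    acc, choice = _dtw_forward(tpl, sig_scaled, max_run)
    final = acc[-1]
    candidates = []
    for j in _final_row_minima(final, cfg.max_cost):
        start = _backtrack(choice, j)
        end = j + 1
        dur = (end - start) / rate
        if cfg.min_match_duration <= dur <= cfg.max_match_duration:
            candidates.append((start, end, float(final[j])))
    if resolve_overlaps:
        candidates = _resolve_overlaps(candidates)
    candidates.sort(key=lambda c: c[0])
    arr = np.asarray([(s, e) for s, e, _ in candidates], dtype=int).reshape(-1, 2)
    costs = np.asarray([c for _, _, c in candidates])
    if not resolve_overlaps:
        # raw candidates may overlap; return them as a plain array
        return arr, costs
    return IntervalList(arr), costs


def _resolve_overlaps(candidates: list[tuple[int, int, float]]) -> list:
    """Keep the lower-cost match among overlapping candidates (ties: earlier)."""
    accepted: list[tuple[int, int, float]] = []
    for cand in sorted(candidates, key=lambda c: (c[2], c[0])):
        if all(cand[1] <= a[0] or cand[0] >= a[1] for a in accepted):
            accepted.append(cand)
    return accepted


def constrained_subsequence_dtw(
    signal: np.ndarray,
    template: StrideTemplate,
    cfg: DtwConfig | None = None,
    sampling_rate: float | None = None,
    **kwargs,
) -> tuple[StrideList, np.ndarray]:
    """Subsequence DTW with the local warping constraint active.

    Identical to :func:`subsequence_dtw` except that an unset
    ``cfg.max_local_run`` defaults to 3 instead of unlimited.
    """
    cfg = cfg or DtwConfig()
    if cfg.max_local_run is None:
        cfg = replace(cfg, max_local_run=3)
    return subsequence_dtw(signal, template, cfg, sampling_rate, **kwargs)


def snap_to_min(
    strides: StrideList,
    signal: np.ndarray,
    snap_window: float,
    rate: float,
) -> StrideList:
    """Move each stride border to the signal minimum within ±snap_window/2.

    Moves that would produce invalid intervals (crossing or empty) are
    reverted for all borders involved; the output always satisfies the
    interval-list invariants.
    """
    sig = np.atleast_1d(np.asarray(signal, dtype=float))
    half = round(snap_window * rate / 2)
    if half == 0 or len(strides) == 0:
        return strides
    original = strides.intervals.copy()
    snapped = original.copy()
    for k in range(original.shape[0]):
        for col in (0, 1):
            b = original[k, col]
            lo = max(0, b - half)
            hi = min(sig.size, b + half + 1)
            if hi <= lo:
                continue
            snapped[k, col] = lo + int(np.argmin(sig[lo:hi]))
    # revert any borders whose moves break the interval invariants
    for k in range(snapped.shape[0]):
        if snapped[k, 0] >= snapped[k, 1]:
            snapped[k] = original[k]
    for k in range(snapped.shape[0] - 1):
        if snapped[k + 1, 0] < snapped[k, 1]:
            snapped[k, 1] = original[k, 1]
            snapped[k + 1, 0] = original[k + 1, 0]
    try:
        return IntervalList(snapped)
    except ValueError:
        return IntervalList(original)
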