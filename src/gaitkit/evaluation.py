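"""Scoring pipeline outputs against ground truth.

Stride matching follows the tolerance rule used for IMU stride
benchmarks: a detected stride counts as a true positive if *both* its
start and end lie within the tolerance (30 ms by default) of a reference
stride, with a maximum-cardinality one-to-one assignment so the result
does not depend on list order.  Precision, recall and F1 follow, with
explicit undefined flags (``None``) instead of silent zeros for empty
denominators.

Parameter errors are aggregated at two levels — per test (mean over the
strides of one recording) and per fold (mean of per-test values inside a
cross-validation fold) — because the two schemes give different numbers
and results are only comparable within one scheme.

Cross-validation is group-aware (no participant in both train and test);
fold assignment derives from hashing the group labels with an explicit
seed so a run manifest can reproduce the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from gaitkit.core_types import StrideList

DEFAULT_TOLERANCE_S = 0.03
"""Default stride-border matching tolerance: 30 ms."""


@dataclass(frozen=True)
class MatchResult:
    """One-to-one stride matching outcome at a given tolerance."""

    pairs: tuple  # ((detected_id, reference_id), ...)
    false_positives: tuple  # detected ids with no match
    false_negatives: tuple  # reference ids with no match
    tolerance: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)


def match_stride_lists(
    detected: StrideList,
    reference: StrideList,
    tolerance: float = DEFAULT_TOLERANCE_S,
    rate: float = 1.0,
) -> MatchResult:
    """Maximum-cardinality one-to-one matching of stride borders.

    A (detected, reference) pair is feasible iff both start and end
    indices differ by at most ``round(tolerance * rate)`` samples
    (tolerance in seconds, converted by rounding half up).  Among all
    maximum-cardinality matchings the one with the smallest summed border
    distance is returned.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    tol_samples = int(np.floor(tolerance * rate + 0.5))
    n_det, n_ref = len(detected), len(reference)
    if n_det == 0 or n_ref == 0:
        return MatchResult(
            pairs=(), false_positives=tuple(range(n_det)),
            false_negatives=tuple(range(n_ref)), tolerance=tolerance,
        )
    d_start = np.abs(detected.starts[:, None] - reference.starts[None, :])
    d_end = np.abs(detected.ends[:, None] - reference.ends[None, :])
    feasible = (d_start <= tol_samples) & (d_end <= tol_samples)
    dist = (d_start + d_end).astype(float)
    # a BIG cost per infeasible pair makes the assignment maximize the
    # number of feasible pairs first, then minimize total border distance
    big = dist.max() * (min(n_det, n_ref) + 1) + 1.0
    cost = np.where(feasible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = tuple(
        (int(r), int(c)) for r, c in zip(rows, cols) if feasible[r, c]
    )
    matched_det = {p[0] for p in pairs}
    matched_ref = {p[1] for p in pairs}
    return MatchResult(
        pairs=pairs,
        false_positives=tuple(i for i in range(n_det) if i not in matched_det),
        false_negatives=tuple(j for j in range(n_ref) if j not in matched_ref),
        tolerance=tolerance,
    )


@dataclass(frozen=True)
class Scores:
    """Precision/recall/F1 with None marking undefined (0/0) entries."""

    precision: float | None
    recall: float | None
    f1: float | None


def precision_recall_f1(m: MatchResult) -> Scores:
    tp, fp, fn = m.tp, m.fp, m.fn
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Scores(precision=precision, recall=recall, f1=f1)


def parameter_errors(
    pred: pd.DataFrame,
    ref: pd.DataFrame,
    parameter: str,
    *,
    test_id: Sequence | None = None,
    fold_id: Sequence | None = None,
) -> dict:
    """Signed and absolute per-stride errors with two-level aggregation.

    ``pred`` and ``ref`` are per-stride tables sharing an index of
    matched strides (unmatched strides must be excluded beforehand; their
    count is reported by the matcher).  ``test_id`` groups strides into
    recordings, ``fold_id`` groups recordings into cross-validation
    folds.  Returns per-stride errors plus ``per_test`` and ``per_fold``
    mean-absolute-error tables; per-fold values are means of the per-test
    means, mirroring the dual reporting of benchmark studies.
    """
    common = pred.index.intersection(ref.index)
    if len(common) == 0:
        raise ValueError("no overlapping strides between pred and ref")
    err = pred.loc[common, parameter] - ref.loc[common, parameter]
    table = pd.DataFrame({"error": err, "abs_error": err.abs()})
    table["test_id"] = (
        np.asarray(test_id)[: len(table)] if test_id is not None else 0
    )
    table["fold_id"] = (
        np.asarray(fold_id)[: len(table)] if fold_id is not None else 0
    )
    per_test = table.groupby("test_id").agg(
        mean_error=("error", "mean"),
        mae=("abs_error", "mean"),
        fold_id=("fold_id", "first"),
        n_strides=("error", "size"),
    )
    per_fold = per_test.groupby("fold_id").agg(
        mean_error=("mean_error", "mean"),
        mae=("mae", "mean"),
        n_tests=("mae", "size"),
    )
    return {"per_stride": table, "per_test": per_test, "per_fold": per_fold}


@dataclass
class CrossValidationResult:
    fold_assignment: dict
    per_item: pd.DataFrame
    per_fold: pd.DataFrame


def grouped_cross_validation(
    pipeline,
    dataset: Sequence,
    groups: Sequence,
    k: int,
    scorer: Callable,
    *,
    seed: int = 0,
) -> CrossValidationResult:
    """Group-aware k-fold cross-validation with per-item and per-fold scores.

    ``dataset`` is a sequence of items, ``groups`` the parallel group
    (participant) labels; no group appears in both train and test of a
    fold.  ``pipeline`` may expose ``optimize(train_items)`` returning a
    fitted clone/self, which is called on the train split only;
    ``scorer(pipeline, item) -> float`` runs on each test item.  Folds
    are assigned by ranking a seeded hash of each group label, making the
    split deterministic and serializable.
    """
    groups = list(groups)
    unique_groups = sorted(set(groups), key=str)
    if k > len(unique_groups):
        raise ValueError(f"k={k} exceeds the {len(unique_groups)} groups")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(unique_groups)))
    fold_of_group = {
        g: order[i] % k for i, g in enumerate(unique_groups)
    }
    rows = []
    for fold in range(k):
        test_idx = [i for i, g in enumerate(groups) if fold_of_group[g] == fold]
        train_items = [
            dataset[i] for i, g in enumerate(groups) if fold_of_group[g] != fold
        ]
        fitted = pipeline
        if hasattr(pipeline, "optimize"):
            fitted = pipeline.optimize(train_items) or pipeline
        for i in test_idx:
            rows.append(
                {
                    "item": i,
                    "group": groups[i],
                    "fold": fold,
                    "score": scorer(fitted, dataset[i]),
                }
            )
    per_item = pd.DataFrame(rows)
    per_fold = per_item.groupby("fold").agg(
        mean_score=("score", "mean"), n_items=("score", "size")
    )
    return CrossValidationResult(
        fold_assignment=fold_of_group, per_item=per_item, per_fold=per_fold
    )
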