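import numpy as np
import pandas as pd
import pytest

from gaitkit.core_types import IntervalList
from gaitkit.evaluation import (
    MatchResult,
    grouped_cross_validation,
    match_stride_lists,
    parameter_errors,
    precision_recall_f1,
)
from tests._oracles import matching_oracle


def _jittered(reference, rng, jitter):
    arr = reference.intervals + rng.integers(-jitter, jitter + 1,
                                             reference.intervals.shape)
    arr = np.sort(arr, axis=0)
    arr[:, 1] = np.maximum(arr[:, 1], arr[:, 0] + 1)
    # repair overlaps so the list is valid
    for k in range(1, len(arr)):
        arr[k, 0] = max(arr[k, 0], arr[k - 1, 1])
        arr[k, 1] = max(arr[k, 1], arr[k, 0] + 1)
    return IntervalList(arr)


class TestMatchStrideLists:
    def test_identical_lists_are_all_true_positive(self):
        ref = IntervalList([[0, 100], [100, 200], [200, 300]])
        m = match_stride_lists(ref, ref, 0.03, 100.0)
        assert m.tp == 3 and m.fp == 0 and m.fn == 0

    def test_shift_beyond_tolerance_is_fp_plus_fn(self):
        ref = IntervalList([[0, 100]])
        det = IntervalList([[10, 110]])  # 10 samples = 100 ms > 30 ms
        m = match_stride_lists(det, ref, 0.03, 100.0)
        assert m.tp == 0 and m.fp == 1 and m.fn == 1

    def test_shift_within_tolerance_matches(self):
        ref = IntervalList([[0, 100]])
        det = IntervalList([[2, 102]])  # 20 ms < 30 ms
        m = match_stride_lists(det, ref, 0.03, 100.0)
        assert m.tp == 1

    def test_matches_exhaustive_assignment_oracle(self):
        """Max cardinality + min summed distance equals brute force, 10 seeds."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 11))
            starts = np.cumsum(rng.integers(80, 120, n))
            ref = IntervalList(np.column_stack([starts, starts + 70]))
            det = _jittered(ref, rng, jitter=5)
            tol_samples = 3
            m = match_stride_lists(det, ref, tolerance=tol_samples / 100,
                                   rate=100.0)
            card, dist = matching_oracle(det.intervals.tolist(),
                                         ref.intervals.tolist(), tol_samples)
            assert m.tp == card
            got_dist = sum(
                abs(det.intervals[i, 0] - ref.intervals[j, 0])
                + abs(det.intervals[i, 1] - ref.intervals[j, 1])
                for i, j in m.pairs
            )
            assert got_dist == dist

    def test_count_invariants_and_symmetry(self, rng):
        starts = np.cumsum(rng.integers(80, 120, 8))
        ref = IntervalList(np.column_stack([starts, starts + 70]))
        det = _jittered(ref, rng, jitter=6)
        m = match_stride_lists(det, ref, 0.03, 100.0)
        assert m.tp + m.fp == len(det)
        assert m.tp + m.fn == len(ref)
        swapped = match_stride_lists(ref, det, 0.03, 100.0)
        assert swapped.tp == m.tp
        assert swapped.fp == m.fn and swapped.fn == m.fp

    def test_negative_tolerance_rejected(self):
        ref = IntervalList([[0, 10]])
        with pytest.raises(ValueError):
            match_stride_lists(ref, ref, -0.1, 100.0)


class TestScores:
    def test_hand_computed_example(self):
        m = MatchResult(pairs=tuple((i, i) for i in range(8)),
                        false_positives=(8, 9),
                        false_negatives=(8, 9), tolerance=0.03)
        s = precision_recall_f1(m)
        assert s.precision == pytest.approx(0.8)
        assert s.recall == pytest.approx(0.8)
        assert s.f1 == pytest.approx(0.8)

    def test_perfect_detection_scores_one(self):
        m = MatchResult(pairs=((0, 0), (1, 1)), false_positives=(),
                        false_negatives=(), tolerance=0.03)
        s = precision_recall_f1(m)
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_empty_denominator_is_flagged_not_zero(self):
        m = MatchResult(pairs=(), false_positives=(),
                        false_negatives=(0, 1, 2, 3, 4), tolerance=0.03)
        s = precision_recall_f1(m)
        assert s.recall == 0.0
        assert s.precision is None
        assert s.f1 is None

    def test_f1_harmonic_identity(self, rng):
        for _ in range(10):
            tp, fp, fn = rng.integers(1, 20, 3)
            m = MatchResult(
                pairs=tuple((i, i) for i in range(tp)),
                false_positives=tuple(range(tp, tp + fp)),
                false_negatives=tuple(range(tp, tp + fn)),
                tolerance=0.03,
            )
            s = precision_recall_f1(m)
            assert s.f1 == pytest.approx(
                2 * s.precision * s.recall / (s.precision + s.recall)
            )


class TestParameterErrors:
    def test_identical_tables_give_zero_errors_everywhere(self):
        df = pd.DataFrame({"stride_length": [1.2, 1.3, 1.4]})
        out = parameter_errors(df, df.copy(), "stride_length")
        assert np.allclose(out["per_stride"]["abs_error"], 0.0)
        assert np.allclose(out["per_test"]["mae"], 0.0)
        assert np.allclose(out["per_fold"]["mae"], 0.0)

    def test_per_fold_is_mean_of_per_test_values(self):
        pred = pd.DataFrame({"v": [1.1, 1.3, 1.0, 1.0]})
        ref = pd.DataFrame({"v": [1.0, 1.0, 1.0, 1.0]})
        out = parameter_errors(pred, ref, "v",
                               test_id=[0, 0, 1, 1], fold_id=[0, 0, 0, 0])
        assert out["per_test"]["mae"].tolist() == pytest.approx([0.2, 0.0])
        assert out["per_fold"]["mae"].iloc[0] == pytest.approx(0.1)

    def test_aggregation_schemes_can_disagree(self):
        """Per-test and per-fold medians differ on a constructed case."""
        # fold 0: tests with MAE 0.1 and 0.5; fold 1: one test with MAE 0.2
        pred = pd.DataFrame({"v": [1.1, 1.5, 1.2]})
        ref = pd.DataFrame({"v": [1.0, 1.0, 1.0]})
        out = parameter_errors(pred, ref, "v",
                               test_id=[0, 1, 2], fold_id=[0, 0, 1])
        per_test_median = out["per_test"]["mae"].median()
        per_fold_median = out["per_fold"]["mae"].median()
        assert per_test_median == pytest.approx(0.2)
        assert per_fold_median == pytest.approx(0.25)
        assert per_test_median != per_fold_median

    def test_empty_overlap_raises(self):
        a = pd.DataFrame({"v": [1.0]}, index=[0])
        b = pd.DataFrame({"v": [1.0]}, index=[5])
        with pytest.raises(ValueError):
            parameter_errors(a, b, "v")


class _ConstantPipeline:
    def run(self, item):
        return item * 2


class TestGroupedCrossValidation:
    dataset = list(range(20))
    groups = [i % 10 for i in range(20)]  # 10 participants, 2 items each

    @staticmethod
    def scorer(pipeline, item):
        return float(pipeline.run(item))

    def test_every_group_in_exactly_one_test_fold(self):
        res = grouped_cross_validation(
            _ConstantPipeline(), self.dataset, self.groups, 5, self.scorer,
            seed=3,
        )
        seen = res.per_item.groupby("group")["fold"].nunique()
        assert (seen == 1).all()
        assert set(res.per_item["fold"]) == set(range(5))
        assert len(res.per_item) == len(self.dataset)

    def test_untunable_pipeline_scores_match_direct_run(self):
        res = grouped_cross_validation(
            _ConstantPipeline(), self.dataset, self.groups, 5, self.scorer,
            seed=3,
        )
        for _, row in res.per_item.iterrows():
            assert row["score"] == self.dataset[int(row["item"])] * 2

    def test_same_seed_reproduces_fold_assignment(self):
        a = grouped_cross_validation(_ConstantPipeline(), self.dataset,
                                     self.groups, 5, self.scorer, seed=42)
        b = grouped_cross_validation(_ConstantPipeline(), self.dataset,
                                     self.groups, 5, self.scorer, seed=42)
        assert a.fold_assignment == b.fold_assignment
        assert a.per_item.equals(b.per_item)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            grouped_cross_validation(_ConstantPipeline(), self.dataset,
                                     self.groups, 11, self.scorer)
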