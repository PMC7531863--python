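import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nucleoseg import (
    ConfusionCounts,
    accuracy,
    confusion,
    iqr_summary,
    jaccard,
    per_slice_curves,
)

from oracles import per_pixel_confusion

counts_st = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 10_000),
    tn=st.integers(0, 10_000),
    fp=st.integers(0, 10_000),
    fn=st.integers(0, 10_000),
)


class TestConfusion:
    def test_all_true_agreement(self):
        c = confusion(np.ones((2, 2), bool), np.ones((2, 2), bool))
        assert (c.tp, c.tn, c.fp, c.fn) == (4, 0, 0, 0)

    def test_all_false_agreement(self):
        c = confusion(np.zeros(10, bool), np.zeros(10, bool))
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 10, 0, 0)

    def test_hand_enumerated_two_by_two(self):
        pred = np.array([[1, 1], [0, 0]], dtype=bool)   # rows
        truth = np.array([[1, 0], [1, 0]], dtype=bool)  # columns
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2), bool), np.zeros((2, 3), bool))

    def test_counts_sum_to_pixel_total_and_match_oracle(self, rng):
        for _ in range(20):
            pred = rng.random((16, 16)) < 0.5
            truth = rng.random((16, 16)) < 0.5
            c = confusion(pred, truth)
            assert c.total == 256
            assert (c.tp, c.tn, c.fp, c.fn) == per_pixel_confusion(pred, truth)


class TestScalarMetrics:
    def test_balanced_counts_give_half_accuracy(self):
        assert accuracy(ConfusionCounts(1, 1, 1, 1)) == 0.5

    def test_perfect_prediction(self):
        assert accuracy(ConfusionCounts(3, 5, 0, 0)) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_jaccard_one_third(self):
        assert jaccard(ConfusionCounts(1, 0, 1, 1)) == pytest.approx(1 / 3)

    def test_jaccard_zero_when_no_true_positives(self):
        assert jaccard(ConfusionCounts(0, 5, 2, 3)) == 0.0

    def test_jaccard_both_empty_convention(self):
        assert jaccard(ConfusionCounts(0, 9, 0, 0)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    @given(counts_st)
    def test_accuracy_dominates_jaccard(self, c):
        """TN can only help accuracy, never Jaccard."""
        if c.total == 0:
            return
        assert accuracy(c) >= jaccard(c)
        assert 0.0 <= jaccard(c) <= 1.0
        assert 0.0 <= accuracy(c) <= 1.0

    @given(counts_st)
    def test_swap_symmetry_pred_truth(self, c):
        """Swapping prediction and truth swaps FP and FN only."""
        swapped = ConfusionCounts(tp=c.tp, tn=c.tn, fp=c.fn, fn=c.fp)
        if c.total > 0:
            assert accuracy(c) == accuracy(swapped)
        assert jaccard(c) == jaccard(swapped)

    def test_complement_pair_swaps_counts(self, rng):
        pred = rng.random((12, 12)) < 0.3
        truth = rng.random((12, 12)) < 0.3
        c = confusion(pred, truth)
        cc = confusion(~pred, ~truth)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (c.tn, c.tp, c.fn, c.fp)


class TestCurves:
    def test_identical_stacks_score_one_everywhere(self, rng):
        stack = rng.random((5, 16, 16)) < 0.4
        curves = per_slice_curves(stack, stack)
        assert (curves["accuracy"] == 1.0).all()
        assert (curves["jaccard"] == 1.0).all()

    def test_single_corrupted_slice_is_the_only_departure(self, rng):
        truth = rng.random((6, 16, 16)) < 0.4
        pred = truth.copy()
        pred[3] = ~pred[3]
        curves = per_slice_curves(pred, truth)
        bad = curves[curves["accuracy"] < 1.0]
        assert list(bad["slice"]) == [3]

    def test_label_stack_binarized_by_class_name(self, rng):
        truth = rng.integers(0, 4, size=(3, 8, 8)).astype(np.uint8)
        curves = per_slice_curves(truth, truth, class_of_interest="nucleus")
        assert (curves["jaccard"] == 1.0).all()

    def test_empty_prediction_on_empty_pole_slice_beats_bad_central(self):
        """TN-domination: an empty slice predicted empty scores perfect
        accuracy, above any imperfect central slice."""
        truth = np.zeros((2, 32, 32), bool)
        truth[1, 8:24, 8:24] = True
        pred = np.zeros_like(truth)
        pred[1, 8:20, 8:20] = True
        curves = per_slice_curves(pred, truth)
        assert curves.loc[0, "accuracy"] >= curves.loc[1, "accuracy"]
        assert curves.loc[0, "jaccard"] == 1.0

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            per_slice_curves(np.zeros((2, 8, 8), bool), np.zeros((3, 8, 8), bool))


class TestIqrSummary:
    def test_constant_curves_summarize_to_constant(self):
        curves = pd.DataFrame(
            {"slice": range(20), "accuracy": [0.9] * 20, "jaccard": [0.9] * 20}
        )
        summary = iqr_summary(curves)
        assert (summary.to_numpy() == 0.9).all()

    def test_default_band_covers_central_quartiles_of_300(self):
        curves = pd.DataFrame(
            {"slice": range(300), "accuracy": [1.0] * 300, "jaccard": [1.0] * 300}
        )
        n = len(curves)
        lo, hi = int(round(0.25 * n)), int(round(0.75 * n))
        assert (lo, hi) == (75, 225)
        sel = curves[(curves["slice"] >= lo) & (curves["slice"] <= hi)]
        assert len(sel) == 151

    def test_matches_recompute_from_rows_oracle(self, rng):
        curves = pd.DataFrame(
            {
                "slice": range(40),
                "accuracy": rng.random(40),
                "jaccard": rng.random(40),
            }
        )
        summary = iqr_summary(curves)
        sel = curves[(curves["slice"] >= 10) & (curves["slice"] <= 30)]
        for metric in ("accuracy", "jaccard"):
            vals = sel[metric].to_numpy()
            assert summary.loc[metric, "mean"] == pytest.approx(vals.mean())
            assert summary.loc[metric, "median"] == pytest.approx(np.median(vals))
            assert summary.loc[metric, "min"] == vals.min()
            assert summary.loc[metric, "max"] == vals.max()

    def test_empty_selection_rejected(self):
        curves = pd.DataFrame({"slice": [0], "accuracy": [1.0], "jaccard": [1.0]})
        with pytest.raises(ValueError):
            iqr_summary(curves, 0.9, 0.95)
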