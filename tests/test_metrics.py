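"""The five evaluation measures and dataset aggregation."""

import itertools

import numpy as np
import pytest

from promptfuse import (
    BinaryMask,
    MaskValidationError,
    dice,
    emeasure,
    evaluate_pairs,
    iou,
    mae,
    weighted_fmeasure,
)

from oracles import (
    dice_sets,
    emeasure_reference,
    iou_sets,
    mae_pixels,
    wfm_reference,
)


def _mask(arr):
    return BinaryMask(np.asarray(arr, dtype=np.uint8))


def _random_pair(rng, n=16):
    return (
        _mask((rng.random((n, n)) < rng.uniform(0.1, 0.9)).astype(np.uint8)),
        _mask((rng.random((n, n)) < rng.uniform(0.1, 0.9)).astype(np.uint8)),
    )


class TestOverlapMetrics:
    def test_worked_example(self):
        # T covers 4 pixels, P covers 2 of them plus 1 extra
        T = np.zeros((3, 3), dtype=np.uint8)
        T[0, 0] = T[0, 1] = T[1, 0] = T[1, 1] = 1
        P = np.zeros((3, 3), dtype=np.uint8)
        P[0, 0] = P[0, 1] = P[2, 2] = 1
        assert iou(_mask(P), _mask(T)) == pytest.approx(0.4)
        assert dice(_mask(P), _mask(T)) == pytest.approx(4 / 7)

    def test_perfect_and_disjoint(self):
        a = _mask([[1, 0], [0, 0]])
        b = _mask([[0, 0], [0, 1]])
        assert iou(a, a) == dice(a, a) == 1.0
        assert iou(a, b) == dice(a, b) == 0.0

    def test_both_empty_is_perfect(self):
        e = _mask(np.zeros((4, 4)))
        assert iou(e, e) == dice(e, e) == 1.0
        assert mae(e, e) == 0.0

    def test_mae_is_mismatch_fraction(self):
        P = _mask([[1, 0], [0, 0]])
        T = _mask([[0, 0], [0, 0]])
        assert mae(P, T) == 0.25

    def test_dice_iou_identity_and_ordering(self, rng):
        for _ in range(200):
            P, T = _random_pair(rng)
            i, d = iou(P, T), dice(P, T)
            assert 0.0 <= i <= d <= 1.0
            assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(MaskValidationError):
            iou(_mask(np.zeros((2, 2))), _mask(np.zeros((3, 3))))


class TestWeightedFmeasure:
    def test_perfect_prediction(self):
        T = np.zeros((8, 8), dtype=np.uint8)
        T[2:5, 2:5] = 1
        assert weighted_fmeasure(_mask(T), _mask(T)) == pytest.approx(1.0)

    def test_far_disjoint_prediction_scores_near_zero(self):
        # interior T: the smoothing window sees only true misses, so the
        # weighted recall collapses and the score is essentially zero
        T = np.zeros((16, 16), dtype=np.uint8)
        T[7:9, 7:9] = 1
        P = np.zeros((16, 16), dtype=np.uint8)
        P[14:16, 14:16] = 1
        assert weighted_fmeasure(_mask(P), _mask(T)) < 0.05

    def test_boundary_false_positive_cheaper_than_distant_one(self):
        """The distance-dependent weighting makes an error hugging the true
        object less costly than the same-size error far away."""
        T = np.zeros((8, 8), dtype=np.uint8)
        T[2:5, 2:5] = 1
        near = T.copy()
        near[2, 5] = 1  # adjacent to the object
        far = T.copy()
        far[7, 7] = 1  # isolated corner
        assert weighted_fmeasure(_mask(near), _mask(T)) > weighted_fmeasure(
            _mask(far), _mask(T)
        )

    def test_empty_ground_truth_convention(self):
        e = _mask(np.zeros((5, 5)))
        p = _mask(np.eye(5, dtype=np.uint8))
        assert weighted_fmeasure(e, e) == 1.0
        assert weighted_fmeasure(p, e) == 0.0


class TestEmeasure:
    def test_perfect_mixed_prediction(self):
        T = np.zeros((6, 6), dtype=np.uint8)
        T[1:4, 1:4] = 1
        assert emeasure(_mask(T), _mask(T)) == 1.0

    def test_complement_on_balanced_mask(self):
        T = np.zeros((4, 4), dtype=np.uint8)
        T[:, :2] = 1
        P = 1 - T
        assert emeasure(_mask(P), _mask(T)) <= 0.25

    def test_perfect_prediction_is_unique_maximum(self):
        """Exhaustive over all 2^9 predictions on a 3x3 ground truth: only
        the exact match attains the maximal score of 1.

        (Flipping a single mismatched pixel to match is *not* guaranteed to
        raise the score: the alignment is computed on mean-centered maps, so
        one flip shifts the prediction mean and can lower the alignment
        elsewhere.  Only the global optimum is characterized.)
        """
        T = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=np.uint8)
        for bits in itertools.product((0, 1), repeat=9):
            P = np.array(bits, dtype=np.uint8).reshape(3, 3)
            score = emeasure(_mask(P), _mask(T))
            if np.array_equal(P, T):
                assert score == 1.0
            else:
                assert score < 1.0


class TestOracleEquivalence:
    def test_all_five_match_reference_implementations(self, rng):
        for _ in range(30):
            P, T = _random_pair(rng, n=int(rng.integers(4, 33)))
            p, t = P.as_bool(), T.as_bool()
            assert iou(P, T) == iou_sets(p, t)
            assert dice(P, T) == dice_sets(p, t)
            assert mae(P, T) == pytest.approx(mae_pixels(p, t), abs=1e-15)
            assert weighted_fmeasure(P, T) == pytest.approx(wfm_reference(p, t), abs=1e-9)
            assert emeasure(P, T) == pytest.approx(emeasure_reference(p, t), abs=1e-9)


class TestSymmetryInvariance:
    def test_all_metrics_invariant_under_shared_flips_and_transpose(self, rng):
        P, T = _random_pair(rng, 12)
        metrics = (iou, dice, mae, weighted_fmeasure, emeasure)
        base = [m(P, T) for m in metrics]
        for op in (np.flipud, np.fliplr, np.transpose):
            Pt, Tt = _mask(op(P.labels)), _mask(op(T.labels))
            assert [m(Pt, Tt) for m in metrics] == pytest.approx(base, abs=1e-12)


class TestEvaluatePairs:
    def test_aggregate_is_column_mean(self, rng):
        pairs = [(*_random_pair(rng, 10), f"img{i}") for i in range(5)]
        report = evaluate_pairs(pairs)
        assert report.n_images == 5
        for col in ("iou", "dice", "mae", "wfm", "emeasure"):
            assert report.aggregate[col] == pytest.approx(report.per_image[col].mean())

    def test_perfect_pair(self):
        T = np.zeros((6, 6), dtype=np.uint8)
        T[2:4, 2:4] = 1
        report = evaluate_pairs([(_mask(T), _mask(T), "a")])
        agg = report.aggregate
        assert agg["iou"] == agg["dice"] == agg["wfm"] == agg["emeasure"] == 1.0
        assert agg["mae"] == 0.0

    def test_bad_pair_counted_not_aggregated(self):
        good = (_mask(np.eye(4, dtype=np.uint8)), _mask(np.eye(4, dtype=np.uint8)), "ok")
        bad = (_mask(np.zeros((2, 2))), _mask(np.zeros((3, 3))), "broken")
        report = evaluate_pairs([good, bad])
        assert report.n_images == 1 and report.n_errors == 1

    def test_csv_has_aggregate_footer(self, tmp_path, rng):
        report = evaluate_pairs([(*_random_pair(rng, 8), "x")])
        out = tmp_path / "r.csv"
        report.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[-1].startswith("AGGREGATE")
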