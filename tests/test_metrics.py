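import numpy as np
import pytest

from ipcc_ar.errors import ParameterError
from ipcc_ar.metrics import (
    ConfusionTable,
    confusion_counts,
    evaluate_masks,
    metrics_from_confusion,
    registration_dice,
)
from ipcc_ar.transform import SimilarityTransform


class TestConfusionCounts:
    def test_perfect_prediction(self):
        m = np.ones((2, 2), dtype=np.uint8)
        c = confusion_counts(m, m)
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 0)

    def test_complement_prediction(self):
        t = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        c = confusion_counts(1 - t, t)
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_matches_nested_loop_tally(self, rng):
        pred = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        truth = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        c = confusion_counts(pred, truth)
        tp = fp = fn = tn = 0
        for y in range(16):
            for x in range(16):
                if pred[y, x] and truth[y, x]:
                    tp += 1
                elif pred[y, x]:
                    fp += 1
                elif truth[y, x]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_dimension_mismatch(self):
        with pytest.raises(ParameterError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMetricsFromConfusion:
    def test_perfect_table(self):
        r = metrics_from_confusion(ConfusionTable(4, 0, 0, 0))
        assert r.dice == 1.0 and r.jaccard == 1.0

    def test_uniform_table_hand_computed(self):
        # TP=FP=FN=TN=1: dice 0.5, jaccard 1/3, accuracy 0.5, kappa 0
        r = metrics_from_confusion(ConfusionTable(1, 1, 1, 1))
        assert r.dice == pytest.approx(0.5)
        assert r.jaccard == pytest.approx(1 / 3)
        assert r.accuracy == pytest.approx(0.5)
        assert r.cohen_kappa == pytest.approx(0.0)

    def test_f1_equals_dice_and_iou_equals_jaccard(self, rng):
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(0, 50, size=4)
            if tp + fp + fn + tn == 0:
                continue
            r = metrics_from_confusion(ConfusionTable(int(tp), int(fp), int(fn), int(tn)))
            assert r.f1 == r.dice
            assert r.iou == r.jaccard

    def test_against_sklearn_oracle(self, rng):
        from sklearn.metrics import cohen_kappa_score, f1_score, jaccard_score

        pred = (rng.random(400) > 0.4).astype(int)
        truth = (rng.random(400) > 0.6).astype(int)
        r = evaluate_masks(pred.reshape(20, 20), truth.reshape(20, 20))
        assert r.f1 == pytest.approx(f1_score(truth, pred))
        assert r.jaccard == pytest.approx(jaccard_score(truth, pred))
        assert r.cohen_kappa == pytest.approx(cohen_kappa_score(truth, pred))
        assert r.accuracy == pytest.approx((pred == truth).mean())

    def test_degenerate_ratios_are_zero(self):
        r = metrics_from_confusion(ConfusionTable(0, 0, 0, 5))
        assert r.dice == 0.0 and r.precision == 0.0 and r.recall == 0.0

    def test_bounds_and_kappa_extremes(self, rng):
        for _ in range(100):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 20, size=4))
            if tp + fp + fn + tn == 0:
                continue
            r = metrics_from_confusion(ConfusionTable(tp, fp, fn, tn))
            vals = [r.dice, r.accuracy, r.precision, r.recall, r.jaccard, r.specificity]
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert -1.0 <= r.cohen_kappa <= 1.0
            if fp == 0 and fn == 0 and tp > 0 and tn > 0:
                assert r.cohen_kappa == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            metrics_from_confusion(ConfusionTable(0, 0, 0, 0))


class TestRegistrationDice:
    def test_identity_on_same_mask_is_one(self, vessel_skeleton):
        d = registration_dice(
            vessel_skeleton, vessel_skeleton, SimilarityTransform.identity()
        )
        assert d == pytest.approx(1.0)

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((32, 32), dtype=np.uint8)
        b = np.zeros((32, 32), dtype=np.uint8)
        a[5, 5:10] = 1
        b[20, 5:10] = 1
        assert registration_dice(a, b, SimilarityTransform.identity()) == 0.0

    def test_true_transform_beats_identity(self, small_fixture_pairs):
        A, B, truth = small_fixture_pairs[2]
        d_true = registration_dice(A, B, truth)
        d_id = registration_dice(A, B, SimilarityTransform.identity())
        assert d_true >= d_id


def test_self_dice_is_one_for_any_nonempty_mask(vessel_tree):
    assert evaluate_masks(vessel_tree, vessel_tree).dice == 1.0
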