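import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trichoscan.datamodel import Circle
from trichoscan.detect import FollicleDetection
from trichoscan.evaluate import (
    ConfusionMatrix,
    MatchResult,
    UndefinedMetricError,
    average_precision,
    circle_iou,
    circle_iou_raster,
    classification_metrics,
    evaluate_detections,
    match_detections,
    mean_ap,
    weighted_misclassification_rate,
)


class TestCircleIoU:
    def test_identical_circles(self):
        c = Circle(10, 20, 7)
        assert circle_iou(c, c) == pytest.approx(1.0)

    def test_disjoint_circles(self):
        assert circle_iou(Circle(0, 0, 3), Circle(10, 0, 3)) == 0.0

    def test_unit_circles_at_distance_one(self):
        # lens area 2*acos(1/2) - (1/2)*sqrt(3); union = 2*pi - lens
        lens = 2 * math.acos(0.5) - 0.5 * math.sqrt(3)
        expected = lens / (2 * math.pi - lens)
        got = circle_iou(Circle(0, 0, 1), Circle(1, 0, 1))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.2430, abs=1e-4)

    def test_contained_circle(self):
        assert circle_iou(Circle(0, 0, 10), Circle(1, 0, 5)) == pytest.approx(0.25)

    @given(
        st.floats(-50, 50), st.floats(-50, 50), st.floats(1, 30),
        st.floats(-50, 50), st.floats(-50, 50), st.floats(1, 30),
    )
    def test_symmetric_bounded_scale_invariant(self, ax, ay, ar, bx, by, br):
        a, b = Circle(ax, ay, ar), Circle(bx, by, br)
        iou = circle_iou(a, b)
        assert 0.0 <= iou <= 1.0 + 1e-12
        assert iou == pytest.approx(circle_iou(b, a), abs=1e-12)
        s = 3.7
        scaled = circle_iou(
            Circle(ax * s, ay * s, ar * s), Circle(bx * s, by * s, br * s)
        )
        assert iou == pytest.approx(scaled, abs=1e-9)

    def test_closed_form_agrees_with_raster(self, rng):
        for _ in range(100):
            a = Circle(rng.uniform(0, 50), rng.uniform(0, 50), rng.uniform(5, 25))
            b = Circle(
                a.cx + rng.uniform(-30, 30), a.cy + rng.uniform(-30, 30),
                rng.uniform(5, 25),
            )
            assert abs(circle_iou(a, b) - circle_iou_raster(a, b)) < 0.01


class TestMatching:
    def test_single_true_positive(self):
        m = match_detections([Circle(10, 10, 5)], [0.9], [Circle(10.5, 10, 5)], 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_detection_without_truth_is_fp(self):
        m = match_detections([Circle(10, 10, 5)], [0.9], [], 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 0)

    def test_greedy_higher_score_wins_shared_truth(self):
        dets = [Circle(10, 10, 5), Circle(11, 10, 5)]
        m = match_detections(dets, [0.7, 0.9], [Circle(10.5, 10, 5)], 0.5)
        assert (m.tp, m.fp) == (1, 1)
        assert m.pairs[0][0] == 1  # index of the 0.9-score detection

    def test_below_threshold_not_matched(self):
        m = match_detections([Circle(0, 0, 5)], [0.9], [Circle(7, 0, 5)], 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)


def ap_oracle(flags, n_truths):
    """Naive all-point-interpolated AP from score-ordered TP/FP flags."""
    tp = fp = 0
    points = []
    for is_tp in flags:
        tp += is_tp
        fp += not is_tp
        points.append((tp / n_truths, tp / (tp + fp)))
    ap, prev_r = 0.0, 0.0
    for r, _ in points:
        p_env = max(p for rr, p in points if rr >= r - 1e-12)
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


def match_from_flags(flags, n_truths, tau=0.5):
    scores = tuple(0.9 - 0.1 * i for i in range(len(flags)))
    pairs = tuple(
        (i, ti, 0.9)
        for ti, i in enumerate(i for i, f in enumerate(flags) if f)
    )
    return MatchResult(scores=scores, n_truths=n_truths, pairs=pairs, tau=tau)


class TestAveragePrecision:
    def test_perfect_detection(self):
        m = match_from_flags([True, True], 2)
        assert average_precision([m]) == 1.0

    def test_no_detections(self):
        m = match_from_flags([], 3)
        assert average_precision([m]) == 0.0

    def test_hand_traced_case(self):
        # scores .9 TP, .8 FP, .7 TP over 2 truths -> 0.5*1 + 0.5*(2/3)
        m = match_from_flags([True, False, True], 2)
        assert average_precision([m]) == pytest.approx(5 / 6)

    def test_zero_truths_distinct_from_zero_ap(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([match_from_flags([False], 0)])

    def test_matches_bruteforce_enumeration_up_to_six_detections(self):
        for n in range(0, 7):
            for flags in itertools.product([True, False], repeat=n):
                n_tp = sum(flags)
                for n_truths in range(max(n_tp, 1), 7):
                    m = match_from_flags(list(flags), n_truths)
                    assert average_precision([m]) == pytest.approx(
                        ap_oracle(flags, n_truths), abs=1e-12
                    )

    def test_pools_across_images(self):
        m1 = match_from_flags([True], 1)
        m2 = match_from_flags([False], 1)
        assert average_precision([m1, m2]) == pytest.approx(0.5)


class TestConfusionMetrics:
    def test_identity_matrix_perfect_scores(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int) * 10)
        metrics = classification_metrics(cm)
        assert metrics["accuracy"] == 1.0
        for label in cm.labels:
            assert metrics["per_class"][label] == {
                "precision": 1.0, "recall": 1.0, "f1": 1.0
            }

    def test_uniform_matrix_accuracy_third(self):
        cm = ConfusionMatrix(np.full((3, 3), 4, dtype=int))
        assert classification_metrics(cm)["accuracy"] == pytest.approx(1 / 3)

    def test_hand_counted_matrix(self):
        cm = ConfusionMatrix(np.array([[8, 2, 0], [1, 7, 2], [0, 3, 7]]))
        metrics = classification_metrics(cm)
        assert metrics["accuracy"] == pytest.approx(22 / 30)
        assert metrics["per_class"]["severe"]["recall"] == pytest.approx(0.8)

    def test_zero_column_flagged_not_crashing(self):
        cm = ConfusionMatrix(np.array([[5, 0, 0], [5, 0, 0], [0, 0, 5]]))
        metrics = classification_metrics(cm)
        assert metrics["per_class"]["normal"]["precision"] == 0.0
        assert "normal:precision" in metrics["zero_division"]

    def test_from_pairs_counts(self):
        cm = ConfusionMatrix.from_pairs(
            ["severe", "severe", "healthy"], ["severe", "normal", "healthy"]
        )
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1 and cm.counts[2, 2] == 1
        assert cm.class_support == {"severe": 2, "normal": 0, "healthy": 1}


class TestWeightedMisclassification:
    def test_zero_errors(self):
        assert weighted_misclassification_rate(
            {"severe": 0.0, "normal": 0.0, "healthy": 0.0},
            {"severe": 10, "normal": 10, "healthy": 10},
        ) == 0.0

    def test_zero_support_rejected(self):
        with pytest.raises(ValueError):
            weighted_misclassification_rate({"severe": 0.5}, {"severe": 0})

    @given(st.lists(st.integers(0, 50), min_size=9, max_size=9))
    def test_complements_accuracy_from_same_matrix(self, cells):
        counts = np.array(cells).reshape(3, 3)
        if counts.sum() == 0 or (counts.sum(axis=1) == 0).any():
            return  # metrics need every true class populated
        cm = ConfusionMatrix(counts)
        rate = weighted_misclassification_rate(cm.per_class_error(), cm.class_support)
        accuracy = classification_metrics(cm)["accuracy"]
        assert rate == pytest.approx(1.0 - accuracy, abs=1e-12)


class TestEndToEndEvaluation:
    def test_ground_truth_against_itself_is_perfect(self, small_sim):
        _, ann_set, _ = small_sim
        dets_by_image = {
            image_id: [
                FollicleDetection(image_id, a.circle, 1.0, a.label)
                for a in ann_set.by_image(image_id)
            ]
            for image_id in ann_set.image_ids
        }
        summary = evaluate_detections(dets_by_image, ann_set)
        assert summary["mAP50"] == pytest.approx(1.0)
        assert summary["mAP"] == pytest.approx(1.0)
        assert summary["detection"]["precision"] == 1.0
        assert summary["detection"]["recall"] == 1.0
        assert summary["classification"]["accuracy"] == 1.0

    def test_mean_ap_class_agnostic_without_labels(self, small_sim):
        _, ann_set, _ = small_sim
        dets_by_image = {
            image_id: [
                FollicleDetection(image_id, a.circle, 1.0)
                for a in ann_set.by_image(image_id)
            ]
            for image_id in ann_set.image_ids
        }
        summary = mean_ap(dets_by_image, ann_set)
        assert summary["mAP50"] == pytest.approx(1.0)
        assert set(summary["per_class_AP50"]) == {"all"}
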