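"""Matching, interrater agreement, consensus, AP, baselines, field selection."""

import numpy as np
import pandas as pd
import pytest

from plaquekit.evaluation import (
    ap_sweep,
    average_precision,
    build_consensus,
    expert_baseline,
    interrater_accuracy,
    match_boxes,
    select_fields,
)
from plaquekit.geometry import Box, BoxSet, iou
from plaquekit.synthetic import make_annotators
from conftest import brute_force_ap, random_boxset


def boxset(*boxes, image_id="img", size=1536):
    return BoxSet(image_id, size, size, list(boxes))


class TestMatchBoxes:
    def test_identical_sets_fully_match(self):
        bs = boxset(Box("cored", 0, 0, 10, 10), Box("cored", 50, 50, 80, 80))
        res = match_boxes(bs, bs, 0.5, "cored")
        assert res.n_matched == 2 and not res.unmatched_labels

    def test_greedy_prefers_highest_iou(self):
        label = Box("cored", 0, 0, 100, 100)
        d1 = Box("cored", 0, 0, 100, 80, confidence=0.1)   # iou 0.8
        d2 = Box("cored", 0, 0, 100, 60, confidence=0.9)   # iou 0.6
        res = match_boxes(boxset(label), boxset(d1, d2), 0.5, "cored")
        assert res.pairs == [(label, d1, pytest.approx(0.8))]
        assert res.unmatched_detections == [d2]

    def test_threshold_is_inclusive(self):
        # iou exactly 0.50 forms a congruous pair
        label = Box("cored", 0, 0, 100, 100)
        det = Box("cored", 0, 0, 100, 50)
        assert iou(label, det) == 0.5
        assert match_boxes(boxset(label), boxset(det), 0.5, "cored").n_matched == 1

    def test_one_to_one_constraint(self):
        label = Box("cored", 0, 0, 100, 100)
        dets = boxset(
            Box("cored", 0, 0, 100, 90), Box("cored", 0, 10, 100, 100)
        )
        res = match_boxes(boxset(label), dets, 0.5, "cored")
        assert res.n_matched == 1 and len(res.unmatched_detections) == 1

    def test_class_labels_must_agree(self):
        res = match_boxes(
            boxset(Box("cored", 0, 0, 10, 10)),
            boxset(Box("CAA", 0, 0, 10, 10)),
            0.5,
            "cored",
        )
        assert res.n_matched == 0


class TestInterraterAccuracy:
    """Five hand-enumerated agreement cases plus symmetry."""

    def test_identical_sets(self):
        a = boxset(*[Box("cored", 100 * i, 0, 100 * i + 50, 50) for i in range(3)])
        res = interrater_accuracy(a, a, "cored")
        assert (res.overlaps, res.total, res.accuracy) == (3, 3, 1.0)

    def test_disjoint_sets(self):
        a = boxset(Box("cored", 0, 0, 50, 50), Box("cored", 200, 0, 250, 50))
        b = boxset(Box("cored", 500, 500, 550, 550))
        res = interrater_accuracy(a, b, "cored")
        assert (res.overlaps, res.total, res.accuracy) == (0, 3, 0.0)

    def test_two_vs_two_with_one_pair(self):
        a = boxset(Box("cored", 0, 0, 100, 100), Box("cored", 300, 300, 400, 400))
        b = boxset(Box("cored", 0, 0, 100, 90), Box("cored", 800, 800, 900, 900))
        res = interrater_accuracy(a, b, "cored")
        assert (res.overlaps, res.total) == (1, 3)
        assert res.accuracy == pytest.approx(1 / 3)

    def test_subset_annotator(self):
        a = boxset(Box("cored", 0, 0, 100, 100), Box("cored", 300, 300, 400, 400))
        b = boxset(Box("cored", 0, 0, 100, 100))
        res = interrater_accuracy(a, b, "cored")
        assert (res.overlaps, res.total, res.accuracy) == (1, 2, 0.5)

    def test_double_overlap_counts_once(self):
        # two of A's boxes overlap one of B's; only one congruous pair forms
        a = boxset(Box("cored", 0, 0, 100, 90), Box("cored", 0, 10, 100, 100))
        b = boxset(Box("cored", 0, 0, 100, 100))
        res = interrater_accuracy(a, b, "cored")
        assert (res.overlaps, res.total, res.accuracy) == (1, 2, 0.5)

    def test_symmetry_on_random_sets(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            a = random_boxset(rng, size=400)
            b = random_boxset(rng, size=400)
            for cls in ("cored", "CAA"):
                ra = interrater_accuracy(a, b, cls)
                rb = interrater_accuracy(b, a, cls)
                assert ra.accuracy == rb.accuracy
                assert ra.overlaps == rb.overlaps

    def test_raw_sum_denominator_option(self):
        a = boxset(Box("cored", 0, 0, 100, 100))
        res = interrater_accuracy(a, a, "cored", denominator="sum")
        assert (res.total, res.accuracy) == (2, 0.5)

    def test_mismatched_images_rejected(self):
        a = boxset(image_id="x")
        b = boxset(image_id="y")
        with pytest.raises(ValueError):
            interrater_accuracy(a, b, "cored")


class TestBuildConsensus:
    def make_sets(self, per_annotator):
        return [
            boxset(*boxes, image_id="img")
            for boxes in per_annotator
        ]

    def test_unanimous_identical_box(self):
        b = Box("cored", 10, 10, 60, 60)
        sets = self.make_sets([[b]] * 4)
        out = build_consensus(sets, "cored")
        assert len(out) == 1
        assert (out.boxes[0].x_min, out.boxes[0].y_max) == (10, 60)

    def test_single_annotator_box_has_no_support(self):
        sets = self.make_sets([[Box("cored", 10, 10, 60, 60)], [], [], []])
        assert len(build_consensus(sets, "cored")) == 0

    def test_two_annotator_cluster_is_coordinate_mean(self):
        b1 = Box("cored", 0, 0, 100, 100)
        b2 = Box("cored", 10, 10, 110, 110)  # iou ~0.68
        sets = self.make_sets([[b1], [b2], [], []])
        out = build_consensus(sets, "cored")
        assert len(out) == 1
        c = out.boxes[0]
        assert (c.x_min, c.y_min, c.x_max, c.y_max) == (5, 5, 105, 105)

    def test_no_cross_support_means_empty(self):
        rng = np.random.default_rng(17)
        sets = [random_boxset(rng, size=4000, n=3) for _ in range(4)]
        # verify premise: no cross-annotator pair reaches iou 0.5
        for i in range(4):
            for j in range(i + 1, 4):
                for a in sets[i].boxes:
                    for b in sets[j].boxes:
                        if iou(a, b) >= 0.5:
                            return  # premise violated for this seed; vacuous
        assert len(build_consensus(sets, "cored")) == 0
        assert len(build_consensus(sets, "CAA")) == 0

    def test_recovers_planted_truth_from_jittered_annotators(self):
        rng = np.random.default_rng(23)
        truth = boxset(
            *[
                Box("cored", 200 * i + 10, 200 * i + 10, 200 * i + 90, 200 * i + 90)
                for i in range(4)
            ]
        )
        for seed in range(20):
            sets = make_annotators(truth, k=4, recall=1.0, fp_rate=0.0, jitter=4, seed=seed)
            out = build_consensus(sets, "cored")
            assert len(out) == len(truth.boxes)
            for t in truth.boxes:
                assert max(iou(t, c) for c in out.boxes) >= 0.5

    def test_duplicate_annotator_ids_rejected(self):
        a = boxset(Box("cored", 0, 0, 10, 10, source="A1"))
        b = boxset(Box("cored", 0, 0, 10, 10, source="A1"))
        with pytest.raises(ValueError, match="duplicate"):
            build_consensus([a, b], "cored")


class TestAveragePrecision:
    def test_perfect_detections_give_ap_one(self):
        labels = boxset(Box("cored", 0, 0, 50, 50), Box("cored", 100, 100, 160, 160))
        dets = boxset(
            Box("cored", 0, 0, 50, 50, confidence=0.3),
            Box("cored", 100, 100, 160, 160, confidence=0.7),
        )
        assert average_precision(labels, dets, "cored", 0.5).ap == 1.0

    def test_no_detections_give_ap_zero(self):
        labels = boxset(Box("cored", 0, 0, 50, 50))
        curve = average_precision(labels, boxset(), "cored", 0.5)
        assert curve.ap == 0.0

    def test_duplicate_detections_of_one_label(self):
        # highest-confidence detection is the TP, the second is a FP,
        # so precision walks (1, 0.5) while recall reaches 1 immediately
        labels = boxset(Box("cored", 0, 0, 100, 100))
        dets = boxset(
            Box("cored", 0, 0, 100, 95, confidence=0.9),
            Box("cored", 0, 0, 100, 90, confidence=0.8),
        )
        curve = average_precision(labels, dets, "cored", 0.5)
        assert list(curve.precision) == [1.0, 0.5]
        assert list(curve.recall) == [1.0, 1.0]
        assert curve.ap == 1.0

    def test_confidence_required(self):
        labels = boxset(Box("cored", 0, 0, 100, 100))
        with pytest.raises(ValueError, match="confidence"):
            average_precision(labels, boxset(Box("cored", 0, 0, 100, 100)), "cored", 0.5)

    def test_matches_brute_force_oracle(self):
        """AP equals an independent ranked-confusion-table enumeration on
        random instances."""
        rng = np.random.default_rng(77)
        for _ in range(300):
            labels = random_boxset(rng, size=300, n=int(rng.integers(1, 9)))
            dets = random_boxset(rng, size=300, n=int(rng.integers(0, 9)),
                                 with_confidence=True)
            for cls in ("cored", "CAA"):
                for thr in (0.3, 0.5):
                    got = average_precision(labels, dets, cls, thr).ap
                    expect = brute_force_ap(labels, dets, cls, thr)
                    assert got == pytest.approx(expect, abs=1e-12)

    def test_recall_sequence_is_non_decreasing(self):
        rng = np.random.default_rng(42)
        labels = random_boxset(rng, size=300, n=6)
        dets = random_boxset(rng, size=300, n=8, with_confidence=True)
        curve = average_precision(labels, dets, "cored", 0.5)
        assert (np.diff(curve.recall) >= 0).all()


class TestApSweep:
    THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)

    def test_perfect_detector_all_thresholds(self):
        labels = boxset(Box("cored", 0, 0, 50, 50))
        dets = boxset(Box("cored", 0, 0, 50, 50, confidence=0.9))
        for curve in ap_sweep(labels, dets, "cored", self.THRESHOLDS + (1.0,)):
            assert curve.ap == 1.0

    def test_threshold_crossing(self):
        label = Box("cored", 0, 0, 100, 100)
        det = Box("cored", 0, 0, 100, 55, confidence=0.9)  # iou 0.55
        curves = ap_sweep(boxset(label), boxset(det), "cored", (0.5, 0.6))
        assert curves[0].ap > 0 and curves[1].ap == 0.0

    def test_ap_non_increasing_in_threshold(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            labels = random_boxset(rng, size=300, n=int(rng.integers(1, 9)))
            dets = random_boxset(rng, size=300, n=int(rng.integers(1, 9)),
                                 with_confidence=True)
            aps = [c.ap for c in ap_sweep(labels, dets, "cored", self.THRESHOLDS)]
            assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))


class TestExpertBaseline:
    def test_identical_annotators(self):
        bs = boxset(Box("cored", 0, 0, 50, 50), Box("cored", 100, 100, 150, 150))
        sets = [
            boxset(*[Box("cored", b.x_min, b.y_min, b.x_max, b.y_max, source=f"A{i}")
                     for b in bs.boxes])
            for i in range(1, 5)
        ]
        res = expert_baseline(sets, "cored")
        assert res["mean_precision"] == 1.0 and res["sd_precision"] == 0.0

    def test_four_annotators_give_twelve_comparisons(self):
        rng = np.random.default_rng(3)
        sets = [random_boxset(rng, n=4) for _ in range(4)]
        assert len(expert_baseline(sets, "cored")["per_pair"]) == 12

    def test_half_matching_candidate_scores_half(self):
        truth = boxset(Box("cored", 0, 0, 50, 50))
        cand = boxset(Box("cored", 0, 0, 50, 50), Box("cored", 500, 500, 550, 550))
        res = expert_baseline([truth, cand], "cored")
        by_pair = {(r["truth"], r["candidate"]): r["precision"] for r in res["per_pair"]}
        assert by_pair[("annotator1", "annotator2")] == 0.5


class TestSelectFields:
    def make_table(self, rows):
        return pd.DataFrame(
            rows, columns=["wsi_id", "field_id", "model_caa", "human_caa", "model_cored"]
        )

    def test_distinct_maximizers_give_four_distinct_fields(self):
        table = self.make_table(
            [
                ("w", "f1", 9, 0, 0),
                ("w", "f2", 0, 9, 0),
                ("w", "f3", 0, 0, 9),
                ("w", "f4", 0, 0, 8),
                ("w", "f5", 0, 0, 1),
            ]
        )
        out = select_fields(table)
        assert list(out["field_id"]) == ["f1", "f2", "f3", "f4"]

    def test_one_field_maximizing_everything_is_selected_once(self):
        table = self.make_table(
            [
                ("w", "f1", 9, 9, 9),
                ("w", "f2", 0, 0, 5),
                ("w", "f3", 0, 0, 4),
                ("w", "f4", 0, 0, 3),
            ]
        )
        out = select_fields(table)
        assert list(out["field_id"]) == ["f1", "f2", "f3", "f4"]
        assert list(out["criterion"]) == [
            "max_model_caa", "top_cored", "top_cored", "top_cored"
        ]

    def test_all_zero_counts_tie_break_by_field_order(self):
        table = self.make_table(
            [("w", f"f{i}", 0, 0, 0) for i in range(1, 6)]
        )
        out = select_fields(table)
        assert list(out["field_id"]) == ["f1", "f2", "f3", "f4"]

    def test_too_few_fields_warns(self):
        table = self.make_table([("w", "f1", 1, 2, 3), ("w", "f2", 3, 2, 1)])
        with pytest.warns(UserWarning, match="candidate fields"):
            out = select_fields(table)
        assert set(out["field_id"]) == {"f1", "f2"}
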