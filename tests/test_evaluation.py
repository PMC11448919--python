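"""Classification metrics, IoU, matching and COCO-style average precision.

The mAP micro-benchmark values are frozen from a hand evaluation of the
101-point interpolation formula on a 2-image, 2-class case (worked out in
the comments), independent of the implementation.
"""

import numpy as np
import pytest
from scipy import ndimage

from dropsight.annotations import InstanceAnnotation
from dropsight.evaluation import (
    COCO_THRESHOLDS,
    ConfusionCounts,
    average_precision,
    classification_report,
    confusion_counts,
    detection_as_classification,
    f1,
    iou,
    match_detections,
    mean_ap,
    precision,
    recall,
)
from dropsight.geometry import BinaryMask, BoundingBox, bbox_from_mask
from dropsight.synthetic import mock_predictor, scene_annotations
from dropsight.targeting import Detection


def box_mask(h, w, box: BoundingBox) -> BinaryMask:
    arr = np.zeros((h, w), dtype=bool)
    arr[box.ymin : box.ymax, box.xmin : box.xmax] = True
    return BinaryMask(arr)


def gt(image_id, box, h=60, w=60, category="crystal"):
    mask = box_mask(h, w, box)
    return InstanceAnnotation(
        image_id=image_id, category=category, mask=mask, bbox=bbox_from_mask(mask)
    )


def det(box, probability, h=60, w=60, category="crystal"):
    return Detection(category=category, probability=probability, mask=box_mask(h, w, box))


class TestConfusionAndScalarMetrics:
    def test_perfect_two_of_three(self):
        c = confusion_counts(["C", "C", "P"], ["C", "C", "P"], "C")
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 1)

    def test_swapped_labels(self):
        c = confusion_counts(["C", "P"], ["P", "C"], "C")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 1, 1, 0)

    def test_counts_conserve_total(self, rng):
        truth = rng.choice(list("ABC"), size=200).tolist()
        pred = rng.choice(list("ABC"), size=200).tolist()
        assert confusion_counts(truth, pred, "A").total == 200

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(["A"], ["A", "B"], "A")

    def test_precision_recall_examples(self):
        assert precision(ConfusionCounts(3, 1, 0, 0)) == 0.75
        assert recall(ConfusionCounts(0, 0, 0, 5)) == 0.0  # degenerate
        both = ConfusionCounts(5, 0, 0, 0)
        assert precision(both) == recall(both) == 1.0

    def test_f1_worked_example(self):
        # printed detector-evaluation cell: P=0.4177, R=0.9448 -> F1=0.5793
        assert f1(0.4177, 0.9448) == pytest.approx(0.5793, abs=5e-5)

    def test_f1_degenerate_and_fixed_point(self):
        assert f1(1.0, 0.0) == 0.0
        for x in (0.1, 0.5, 0.93):
            assert f1(x, x) == pytest.approx(x)

    def test_f1_equals_harmonic_mean_on_count_grid(self):
        """f1(precision(c), recall(c)) matches 2TP/(2TP+FP+FN) exhaustively."""
        for tp in range(0, 21, 4):
            for fp in range(0, 21, 4):
                for fn in range(0, 21, 4):
                    c = ConfusionCounts(tp, fp, fn, 0)
                    got = f1(precision(c), recall(c))
                    want = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
                    assert got == pytest.approx(want)


class TestClassificationReport:
    def test_perfect_predictions(self):
        labels = ["A", "B", "C", "A"]
        report = classification_report(labels, labels, ["A", "B", "C"])
        assert report.macro_f1 == 1.0
        assert all(m.f1 == 1.0 for m in report.per_class.values())

    def test_absent_class_excluded_from_macro_mean(self):
        report = classification_report(["A", "A"], ["A", "A"], ["A", "B"])
        assert report.per_class["B"] is None
        assert report.macro_f1 == 1.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            classification_report(["A"], ["Z"], ["A", "B"])

    def test_macro_mean_is_unweighted(self):
        truth = ["A"] * 8 + ["B"] * 2
        pred = ["A"] * 8 + ["A"] * 2  # B always missed
        report = classification_report(truth, pred, ["A", "B"])
        f1_a = report.per_class["A"].f1
        assert report.macro_f1 == pytest.approx((f1_a + 0.0) / 2)


class TestIoU:
    def test_identical_masks(self, small_scene):
        assert iou(small_scene.drop_mask, small_scene.drop_mask) == 1.0

    def test_disjoint_masks(self):
        a = box_mask(10, 10, BoundingBox(0, 0, 3, 3))
        b = box_mask(10, 10, BoundingBox(5, 5, 9, 9))
        assert iou(a, b) == 0.0

    def test_box_overlap_one_third(self):
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(1, 0, 3, 2)) == pytest.approx(
            1 / 3
        )

    def test_symmetry(self, rng):
        for _ in range(20):
            a = BinaryMask(rng.uniform(size=(8, 8)) < 0.5)
            b = BinaryMask(rng.uniform(size=(8, 8)) < 0.5)
            if a.is_empty() and b.is_empty():
                continue
            assert iou(a, b) == iou(b, a)

    def test_both_empty_is_error(self):
        empty = BinaryMask(np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            iou(empty, empty)

    def test_mixed_kinds_rejected(self):
        with pytest.raises(TypeError):
            iou(BoundingBox(0, 0, 1, 1), BinaryMask(np.ones((2, 2), dtype=bool)))


class TestMatchDetections:
    def test_perfect_detections_all_tp(self):
        gts = [gt("i", BoundingBox(0, 0, 10, 10)), gt("i", BoundingBox(20, 20, 40, 40))]
        dets = [det(g.bbox, 0.9) for g in gts]
        res = match_detections(gts, dets, 0.5)
        assert all(res.det_is_tp) and all(res.gt_matched)

    def test_double_detection_single_gt(self):
        gts = [gt("i", BoundingBox(0, 0, 10, 10))]
        dets = [det(BoundingBox(0, 0, 10, 10), 0.9), det(BoundingBox(0, 0, 10, 9), 0.8)]
        res = match_detections(gts, dets, 0.5)
        assert res.det_is_tp == (True, False)

    def test_category_must_match(self):
        gts = [gt("i", BoundingBox(0, 0, 10, 10), category="drop")]
        dets = [det(BoundingBox(0, 0, 10, 10), 0.9, category="crystal")]
        res = match_detections(gts, dets, 0.5)
        assert res.det_is_tp == (False,)

    def test_greedy_assignment_matches_bruteforce_oracle(self):
        """3-GT / 4-detection case vs an explicit greedy replay on box IoU."""
        boxes_gt = [
            BoundingBox(0, 0, 10, 10),
            BoundingBox(12, 0, 22, 10),
            BoundingBox(30, 30, 50, 50),
        ]
        gts = [gt("i", b) for b in boxes_gt]
        det_specs = [
            (BoundingBox(1, 0, 11, 10), 0.95),
            (BoundingBox(0, 0, 10, 10), 0.90),
            (BoundingBox(13, 0, 21, 10), 0.85),
            (BoundingBox(31, 31, 49, 49), 0.80),
        ]
        dets = [det(b, p) for b, p in det_specs]
        res = match_detections(gts, dets, 0.5, geometry="box")

        # oracle: process in descending probability, assign best unmatched GT
        taken = set()
        expected = []
        for box, _p in det_specs:  # already sorted by probability
            best, best_iou = None, 0.0
            for j, gbox in enumerate(boxes_gt):
                if j in taken:
                    continue
                inter = box.intersection_area(gbox)
                val = inter / (box.area + gbox.area - inter)
                if val > best_iou:
                    best, best_iou = j, val
            if best is not None and best_iou >= 0.5:
                taken.add(best)
                expected.append(True)
            else:
                expected.append(False)
        assert list(res.det_is_tp) == expected
        # the first (highest-probability) detection steals GT 0; the exact
        # duplicate at 0.90 is left unmatched
        assert res.det_is_tp == (True, False, True, True)


class TestAveragePrecision:
    def test_all_found_no_fp(self):
        assert average_precision([(0.9, True), (0.8, True)], 2) == 1.0

    def test_no_detections(self):
        assert average_precision([], 3) == 0.0

    def test_undefined_without_ground_truth(self):
        assert average_precision([(0.9, False)], 0) is None

    def test_hand_computed_interpolation(self):
        # 1 GT; FP at 0.9 then TP at 0.8: precision at full recall is 0.5 and
        # the interpolated envelope is 0.5 on the whole grid -> AP = 0.5
        assert average_precision([(0.9, False), (0.8, True)], 1) == 0.5

    def test_invariant_to_image_partitioning(self, rng):
        pooled = [(float(rng.uniform()), bool(rng.uniform() < 0.6)) for _ in range(40)]
        n_gt = 25
        whole = average_precision(pooled, n_gt)
        shuffled = pooled[17:] + pooled[:17]
        assert average_precision(shuffled, n_gt) == whole


class TestMeanAP:
    def _perfect_setup(self, n_scenes=8):
        from dropsight.synthetic import SceneSpec, generate_scene

        gt_map, det_map = {}, {}
        for seed in range(n_scenes):
            spec = SceneSpec(
                image_height=96,
                image_width=112,
                drop_axes=(44.0, 36.0),
                crystal_count_range=(1, 4),
                crystal_size_range=(6.0, 20.0),
                seed=seed,
            )
            scene = generate_scene(spec)
            image_id = f"s{seed}"
            gt_map[image_id] = scene_annotations(scene, image_id)
            det_map[image_id] = mock_predictor(scene, score_law=1.0, seed=seed)
        return gt_map, det_map

    def test_perfect_predictions_give_map_one(self):
        gt_map, det_map = self._perfect_setup()
        result = mean_ap(gt_map, det_map, geometry="mask")
        assert result.map_all == 1.0
        for value in result.ap.values():
            assert value is None or value == 1.0

    def test_eroded_masks_nonincreasing_in_threshold(self):
        gt_map, det_map = self._perfect_setup()
        eroded = {
            image_id: [
                Detection(
                    category=d.category,
                    probability=d.probability,
                    mask=BinaryMask(
                        ndimage.binary_erosion(d.mask.array, iterations=2)
                    ),
                )
                for d in dets
                if ndimage.binary_erosion(d.mask.array, iterations=2).any()
            ]
            for image_id, dets in det_map.items()
        }
        result = mean_ap(gt_map, eroded, geometry="mask")
        lo = result.mean(thresholds=[0.5], size_bin="all")
        hi = result.mean(thresholds=[0.95], size_bin="all")
        assert hi <= lo

    def test_removing_a_tp_never_increases_ap(self):
        gt_map, det_map = self._perfect_setup(n_scenes=4)
        full = mean_ap(gt_map, det_map, thresholds=[0.5], geometry="mask")
        pruned_dets = {k: list(v) for k, v in det_map.items()}
        first = sorted(pruned_dets)[0]
        pruned_dets[first] = pruned_dets[first][1:]
        pruned = mean_ap(gt_map, pruned_dets, thresholds=[0.5], geometry="mask")
        for key, value in pruned.ap.items():
            if value is not None and full.ap[key] is not None:
                assert value <= full.ap[key] + 1e-12

    def test_micro_benchmark_matches_hand_computed_values(self):
        """2 images, 2 classes; AP frozen from manual 101-point evaluation.

        crystal class, threshold 0.5: ranked detections are TP, TP, FP, TP
        over 3 GTs -> recall/precision (1/3,1), (2/3,1), (2/3,2/3), (1,3/4);
        envelope 1 up to recall 2/3 then 3/4 -> AP = (67 + 34*0.75)/101.
        At threshold 0.9 the near-miss box (IoU 9/11) becomes FP -> ranked
        TP, FP, FP, TP -> envelope 1 | 0.5 | 0 over thirds ->
        AP = (34 + 33*0.5)/101 = 0.5.  The drop class is exact -> AP 1.
        """
        gts = {
            "img1": [
                gt("img1", BoundingBox(0, 0, 10, 10)),
                gt("img1", BoundingBox(20, 20, 30, 30)),
                gt("img1", BoundingBox(0, 0, 50, 50), category="drop"),
            ],
            "img2": [gt("img2", BoundingBox(0, 0, 10, 10))],
        }
        dets = {
            "img1": [
                det(BoundingBox(0, 0, 10, 10), 0.9),
                det(BoundingBox(21, 20, 31, 30), 0.8),  # IoU 9/11 with GT
                det(BoundingBox(0, 0, 50, 50), 0.95, category="drop"),
            ],
            "img2": [
                det(BoundingBox(40, 40, 50, 50), 0.7),  # FP
                det(BoundingBox(0, 0, 10, 10), 0.6),
            ],
        }
        result = mean_ap(gts, dets, thresholds=[0.5, 0.9], geometry="box")
        ap = result.ap
        assert ap[("crystal", 0.5, "all")] == pytest.approx((67 + 34 * 0.75) / 101)
        assert ap[("crystal", 0.9, "all")] == pytest.approx(0.5)
        assert ap[("drop", 0.5, "all")] == 1.0
        assert ap[("drop", 0.9, "all")] == 1.0
        assert result.mean(thresholds=[0.5], size_bin="all") == pytest.approx(
            ((67 + 34 * 0.75) / 101 + 1.0) / 2
        )

    def test_default_thresholds_are_coco_sweep(self):
        assert COCO_THRESHOLDS[0] == 0.5 and COCO_THRESHOLDS[-1] == 0.95
        assert len(COCO_THRESHOLDS) == 10


class TestCollapseConsistency:
    def test_image_level_recall_follows_mock_corruption(self):
        """Collapsing detections to image labels reproduces the recall implied
        by the mock detector's per-crystal miss rate (within 3 SE)."""
        from dropsight.synthetic import SceneSpec, generate_scene

        drop_prob = 0.3
        det_map, truth, expected_probs = {}, {}, []
        for seed in range(300):
            spec = SceneSpec(
                image_height=96,
                image_width=112,
                drop_axes=(44.0, 36.0),
                crystal_count_range=(1, 3),
                crystal_size_range=(6.0, 18.0),
                seed=seed,
            )
            scene = generate_scene(spec)
            image_id = f"s{seed}"
            det_map[image_id] = mock_predictor(
                scene, drop_prob=drop_prob, score_law=0.9,
                include_drop=False, seed=seed + 5000,
            )
            truth[image_id] = "Crystals"
            k = len(scene.crystal_masks)
            expected_probs.append(1 - drop_prob**k)
        predicted = detection_as_classification(det_map, 0.6)
        observed = np.mean([predicted[i] == "Crystals" for i in truth])
        expected = float(np.mean(expected_probs))
        var = float(np.mean([p * (1 - p) for p in expected_probs]) / len(truth))
        assert abs(observed - expected) < 3 * np.sqrt(var)


class TestDetectionAsClassification:
    def test_crystal_above_threshold(self):
        dets = {"a": [det(BoundingBox(0, 0, 5, 5), 0.7)]}
        assert detection_as_classification(dets, 0.6) == {"a": "Crystals"}

    def test_empty_and_drop_only(self):
        dets = {
            "empty": [],
            "droponly": [det(BoundingBox(0, 0, 9, 9), 0.99, category="drop")],
            "weak": [det(BoundingBox(0, 0, 5, 5), 0.5)],
        }
        out = detection_as_classification(dets, 0.6)
        assert out == {
            "empty": "NoCrystals",
            "droponly": "NoCrystals",
            "weak": "NoCrystals",
        }
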