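"""Detection metrics: IoU, matching, precision/recall, AP@0.5."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import box as shapely_box

from wormsynth.annotations import BBox, Detection
from wormsynth.metrics import (
    PRCurve,
    average_precision,
    evaluate_dataset,
    iou,
    match_detections,
    precision,
    recall,
)

SHAPE = (100, 100)


def det(cx, cy, w, h, conf):
    return Detection(BBox(cx, cy, w, h), conf)


def ap_oracle(flags, n_gt):
    """Independent AP: for each recall level j/n_gt, the best precision among
    prefixes achieving at least j true positives; zero for unreached levels."""
    if n_gt == 0 or not flags:
        return 0.0
    prefix_tp = np.cumsum(flags)
    total = 0.0
    for j in range(1, n_gt + 1):
        ks = [k for k in range(1, len(flags) + 1) if prefix_tp[k - 1] >= j]
        if ks:
            total += max(prefix_tp[k - 1] / k for k in ks)
    return total / n_gt


def match_oracle(detections, ground_truths, shape, thr=0.5):
    """Independent greedy matcher using shapely polygon areas for IoU."""
    boxes_gt = [shapely_box(*g.to_corners(shape)) for g in ground_truths]
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].confidence, i))
    taken = set()
    flags = []
    for i in order:
        d = shapely_box(*detections[i].bbox.to_corners(shape))
        best, best_iou = None, thr
        for j, g in enumerate(boxes_gt):
            if j in taken:
                continue
            inter = d.intersection(g).area
            union = d.union(g).area
            v = inter / union
            if v > best_iou or (v == best_iou and v >= thr and best is None):
                best, best_iou = j, v
        if best is not None:
            taken.add(best)
            flags.append(True)
        else:
            flags.append(False)
    return flags


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0

    def test_half_overlap(self):
        assert iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            iou((0, 0, 0, 10), (0, 0, 10, 10))


class TestMatching:
    def test_perfect_one_to_one(self):
        gts = [BBox(0.2, 0.2, 0.1, 0.1), BBox(0.7, 0.7, 0.1, 0.1)]
        dets = [det(0.2, 0.2, 0.1, 0.1, 0.9), det(0.7, 0.7, 0.1, 0.1, 0.8)]
        m = match_detections(dets, gts, SHAPE)
        assert m.tp == 2 and m.fp == 0 and m.fn == 0

    def test_two_detections_one_ground_truth(self):
        gts = [BBox(0.5, 0.5, 0.2, 0.2)]
        dets = [det(0.5, 0.5, 0.2, 0.2, 0.9), det(0.5, 0.5, 0.2, 0.2, 0.8)]
        m = match_detections(dets, gts, SHAPE)
        assert m.tp == 1 and m.fp == 1 and m.fn == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            match_detections([], [], SHAPE, iou_threshold=0.0)

    def test_matches_shapely_oracle_on_random_small_instances(self, rng):
        for trial in range(60):
            n_gt = int(rng.integers(0, 6))
            n_det = int(rng.integers(0, 7))
            gts = [
                BBox(rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8),
                     rng.uniform(0.05, 0.3), rng.uniform(0.05, 0.3))
                for _ in range(n_gt)
            ]
            dets = [
                det(rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8),
                    rng.uniform(0.05, 0.3), rng.uniform(0.05, 0.3),
                    round(float(rng.uniform(0.1, 1.0)), 3))
                for _ in range(n_det)
            ]
            m = match_detections(dets, gts, SHAPE)
            oracle_flags = match_oracle(dets, gts, SHAPE)
            assert m.tp_flags.tolist() == oracle_flags, f"trial {trial}"


class TestPrecisionRecall:
    def test_values(self):
        assert precision(8, 2) == 0.8
        assert recall(8, 8) == 0.5

    def test_degenerate_flagged(self):
        p = precision(0, 0)
        assert p == 0.0 and p.degenerate
        r = recall(0, 0)
        assert r == 0.0 and r.degenerate
        assert not precision(1, 0).degenerate


class TestAveragePrecision:
    def test_single_true_positive(self):
        curve = PRCurve.from_flags(np.array([True]), n_gt=1)
        assert average_precision(curve) == 1.0

    def test_worked_example_tp_fp_tp(self):
        # 2 GTs; confidence-ordered flags TP, FP, TP -> envelope 1 on [0, .5],
        # 2/3 on (.5, 1] -> AP = 5/6
        curve = PRCurve.from_flags(np.array([True, False, True]), n_gt=2)
        assert average_precision(curve) == pytest.approx(1 / 2 + 1 / 3, abs=1e-12)
        assert average_precision(curve) == pytest.approx(ap_oracle([1, 0, 1], 2), abs=1e-12)

    def test_no_detections(self):
        assert average_precision(PRCurve.from_flags(np.array([], bool), n_gt=3)) == 0.0

    @given(
        flags=st.lists(st.booleans(), max_size=10),
        extra_gt=st.integers(0, 4),
    )
    def test_equals_brute_force_oracle_up_to_ten_detections(self, flags, extra_gt):
        n_gt = sum(flags) + extra_gt
        curve = PRCurve.from_flags(np.array(flags, bool), n_gt=n_gt)
        assert average_precision(curve) == pytest.approx(ap_oracle(flags, n_gt), abs=1e-12)

    def test_101_point_close_to_exact_on_dense_curve(self, rng):
        # interpolated AP approximates the exact envelope only once the
        # curve has many operating points, as real detector output does
        flags = rng.random(400) < np.linspace(0.95, 0.3, 400)
        curve = PRCurve.from_flags(flags, n_gt=int(flags.sum()) + 20)
        exact = average_precision(curve)
        interp = average_precision(curve, interpolation="101-point")
        assert abs(exact - interp) < 0.03


class TestDatasetEvaluation:
    def _perfect(self, rng, n_images=5):
        labels, dets = {}, {}
        for i in range(n_images):
            boxes = [
                BBox(rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8), 0.1, 0.1)
                for _ in range(int(rng.integers(1, 4)))
            ]
            labels[f"im{i}"] = boxes
            dets[f"im{i}"] = [Detection(b, float(rng.uniform(0.5, 1))) for b in boxes]
        return dets, labels

    def test_perfect_detections_give_unit_metrics(self, rng):
        dets, labels = self._perfect(rng)
        r = evaluate_dataset(dets, labels, SHAPE)
        assert float(r.precision) == 1.0 and float(r.recall) == 1.0
        assert r.ap == pytest.approx(1.0, abs=1e-12)

    def test_empty_detections_nonempty_labels(self):
        r = evaluate_dataset({}, {"a": [BBox(0.5, 0.5, 0.1, 0.1)]}, SHAPE)
        assert r.precision.degenerate and float(r.recall) == 0.0 and r.ap == 0.0

    def test_unknown_image_id_rejected(self):
        with pytest.raises(ValueError, match="unknown image ids"):
            evaluate_dataset({"ghost": []}, {"a": []}, SHAPE)

    def test_pooled_ap_matches_independent_oracle_on_random_scenes(self, rng):
        labels, dets = {}, {}
        for i in range(20):
            boxes = [
                BBox(rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8),
                     rng.uniform(0.05, 0.2), rng.uniform(0.05, 0.2))
                for _ in range(int(rng.integers(0, 4)))
            ]
            labels[f"im{i}"] = boxes
            image_dets = []
            for b in boxes:
                if rng.random() < 0.8:  # jittered hit
                    image_dets.append(
                        Detection(
                            BBox(b.cx + rng.uniform(-0.01, 0.01),
                                 b.cy + rng.uniform(-0.01, 0.01), b.w, b.h),
                            round(float(rng.uniform(0.2, 1.0)), 4),
                        )
                    )
            if rng.random() < 0.4:  # spurious detection
                image_dets.append(det(rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8),
                                      0.05, 0.05, round(float(rng.uniform(0.05, 1.0)), 4)))
            dets[f"im{i}"] = image_dets
        r = evaluate_dataset(dets, labels, SHAPE)
        # oracle: shapely matcher per image, global confidence pooling
        pooled = []
        n_gt = 0
        for image_id in labels:
            flags = match_oracle(dets[image_id], labels[image_id], SHAPE)
            confs = sorted((d.confidence for d in dets[image_id]), reverse=True)
            pooled += list(zip(confs, flags))
            n_gt += len(labels[image_id])
        pooled.sort(key=lambda t: -t[0])
        assert r.ap == pytest.approx(ap_oracle([f for _, f in pooled], n_gt), abs=1e-12)


class TestAPProperties:
    def _curve(self, flags, n_gt):
        return PRCurve.from_flags(np.array(flags, bool), n_gt)

    def test_invariant_under_monotone_confidence_transform(self, rng):
        gts = [BBox(0.3, 0.3, 0.1, 0.1), BBox(0.7, 0.7, 0.1, 0.1)]
        dets = [det(0.3, 0.3, 0.1, 0.1, 0.9), det(0.1, 0.8, 0.05, 0.05, 0.6),
                det(0.7, 0.7, 0.1, 0.1, 0.4)]
        squashed = [Detection(d.bbox, d.confidence**3 / 2) for d in dets]
        r1 = evaluate_dataset({"a": dets}, {"a": gts}, SHAPE)
        r2 = evaluate_dataset({"a": squashed}, {"a": gts}, SHAPE)
        assert r1.ap == r2.ap

    @given(st.lists(st.booleans(), min_size=1, max_size=10))
    def test_appending_lowest_confidence_fp_never_increases_ap(self, flags):
        n_gt = max(sum(flags), 1)
        before = average_precision(self._curve(flags, n_gt))
        after = average_precision(self._curve(flags + [False], n_gt))
        assert after <= before + 1e-12

    @given(st.lists(st.booleans(), min_size=2, max_size=10))
    def test_removing_an_fp_never_decreases_ap(self, flags):
        if not any(not f for f in flags):
            return
        n_gt = max(sum(flags), 1)
        idx = flags.index(False)
        before = average_precision(self._curve(flags, n_gt))
        after = average_precision(self._curve(flags[:idx] + flags[idx + 1 :], n_gt))
        assert after >= before - 1e-12
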