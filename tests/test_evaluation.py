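"""Detection metrics: IoU, matching, AP integration, aggregation."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from pestfsod.boxes import BoxSet, iou_matrix, xywh_to_xyxy
from pestfsod.detector import Detection
from pestfsod.episodes import ClassSplit
from pestfsod.evaluation import (average_precision, confusion_matrix,
                                 evaluate_detections, iou, match_detections,
                                 read_results_json, split_map,
                                 write_results_json)


def det(box, cid=0, score=0.9, img=0):
    return Detection(img, np.asarray(box, dtype=float), cid, score)


class TestIoU:
    def test_identical(self):
        assert iou([0, 0, 5, 5], [0, 0, 5, 5]) == 1.0

    def test_disjoint(self):
        assert iou([0, 0, 5, 5], [10, 10, 15, 15]) == 0.0

    def test_pixel_grid_brute_force(self):
        a, b = [0, 0, 10, 10], [5, 0, 15, 10]
        # rasterised oracle on a unit grid
        grid = np.zeros((20, 20, 2), dtype=bool)
        for k, (x1, y1, x2, y2) in enumerate([a, b]):
            grid[y1:y2, x1:x2, k] = True
        inter = (grid[..., 0] & grid[..., 1]).sum()
        union = (grid[..., 0] | grid[..., 1]).sum()
        assert iou(a, b) == pytest.approx(inter / union, abs=1e-12)
        assert iou(a, b) == pytest.approx(1 / 3, abs=1e-9)


class TestMatching:
    def test_single_true_positive(self):
        gts = BoxSet(np.array([[0, 0, 10, 10]]), [0])
        tp, fn = match_detections([det([0, 0, 10, 10])], gts)
        assert tp.tolist() == [True] and fn == 0

    def test_one_to_one_rule(self):
        gts = BoxSet(np.array([[0, 0, 10, 10]]), [0])
        dets = [det([0, 0, 10, 10], score=0.9), det([0, 0, 10, 10], score=0.8)]
        tp, fn = match_detections(dets, gts)
        assert tp.sum() == 1 and tp[0] and fn == 0

    def test_class_mismatch_is_fp(self):
        gts = BoxSet(np.array([[0, 0, 10, 10]]), [1])
        tp, fn = match_detections([det([0, 0, 10, 10], cid=0)], gts)
        assert tp.sum() == 0 and fn == 1

    def test_greedy_vs_bruteforce_assignment(self):
        """Greedy TP never exceeds the optimal assignment; equality holds
        on 200 random small instances unless IoUs genuinely conflict."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_d = int(rng.integers(1, 10))
            n_g = int(rng.integers(1, 10))
            dets = [det(xywh_to_xyxy(np.concatenate(
                        [rng.uniform(0, 30, 2), rng.uniform(3, 15, 2)]))[0],
                        score=float(rng.random()))
                    for _ in range(n_d)]
            gts = BoxSet(np.column_stack([rng.uniform(0, 30, n_g).T,
                                          rng.uniform(0, 30, n_g).T,
                                          rng.uniform(3, 15, n_g).T,
                                          rng.uniform(3, 15, n_g).T]),
                         np.zeros(n_g, dtype=int))
            tp, fn = match_detections(dets, gts)
            elig = iou_matrix(np.stack([d.box for d in dets]), gts.xyxy) > 0.5
            optimal = int((maximum_bipartite_matching(
                csr_matrix(elig.astype(int)), perm_type="column") >= 0).sum())
            assert tp.sum() <= optimal
            assert tp.sum() + fn == len(gts)


class TestAveragePrecision:
    def test_single_perfect_detection(self):
        ap, _, _ = average_precision(np.array([True]), 1)
        assert ap == 1.0

    def test_hand_worked_envelope(self):
        ap, _, _ = average_precision(np.array([True, False, True]), 2)
        assert ap == pytest.approx(1 * 0.5 + (2 / 3) * 0.5, abs=1e-12)
        assert ap == pytest.approx(0.8333, abs=1e-4)

    def test_all_false_positives(self):
        ap, _, _ = average_precision(np.array([False, False]), 3)
        assert ap == 0.0

    def test_zero_gt_rejected(self):
        with pytest.raises(ValueError):
            average_precision(np.array([True]), 0)


class TestSplitMap:
    def test_all_equal(self):
        split = ClassSplit([1, 2, 3], [1, 2], [3])
        b, n, m = split_map({1: 0.7, 2: 0.7, 3: 0.7}, split)
        for v in (b, n, m):
            assert v == pytest.approx(0.7)

    def test_missing_class_named(self):
        split = ClassSplit([1, 2], [1], [2])
        with pytest.raises(KeyError, match="2"):
            split_map({1: 0.5}, split)

    def test_consistency_identity(self, rng):
        ids = list(range(20))
        split = ClassSplit(ids, ids[:15], ids[15:])
        aps = {c: float(rng.random()) for c in ids}
        b, n, m = split_map(aps, split)
        assert abs((15 * b + 5 * n) / 20 - m) <= 1e-9


class TestEvaluateDetections:
    def test_perfect_run_is_map_one(self):
        """End-to-end plumbing oracle: detections copied from ground truth
        (a perfect detector) must score mAP exactly 1."""
        rng = np.random.default_rng(1)
        gts_by_image, dets_by_image = {}, {}
        for img in range(4):
            n = int(rng.integers(1, 4))
            boxes = np.column_stack([rng.uniform(0, 50, n), rng.uniform(0, 50, n),
                                     rng.uniform(5, 20, n), rng.uniform(5, 20, n)])
            labels = rng.integers(0, 3, n)
            gts_by_image[img] = BoxSet(boxes, labels, image_id=img)
            dets_by_image[img] = [det(b, cid=int(c), score=0.99, img=img)
                                  for b, c in zip(xywh_to_xyxy(boxes), labels)]
        rep = evaluate_detections(dets_by_image, gts_by_image, [0, 1, 2])
        assert rep.mAP == pytest.approx(1.0)

    def test_rank_only_score_dependence(self):
        gts = {0: BoxSet(np.array([[0, 0, 10, 10], [20, 20, 10, 10]]), [0, 0],
                         image_id=0)}
        base = [det([0, 0, 10, 10], score=0.9), det([50, 50, 60, 60], score=0.6),
                det([20, 20, 30, 30], score=0.3)]
        rep1 = evaluate_detections({0: base}, gts, [0])
        squashed = [det(d.box, score=d.score**3) for d in base]
        rep2 = evaluate_detections({0: squashed}, gts, [0])
        assert rep1.per_class_ap[0] == pytest.approx(rep2.per_class_ap[0])

    def test_zero_gt_class_excluded(self):
        gts = {0: BoxSet(np.array([[0, 0, 10, 10]]), [0], image_id=0)}
        with pytest.warns(UserWarning, match="class 1"):
            rep = evaluate_detections({0: []}, gts, [0, 1])
        assert 1 not in rep.per_class_ap


class TestConfusionMatrix:
    def test_perfect_detector_diagonal(self):
        gts = BoxSet(np.array([[0, 0, 10, 10], [20, 20, 10, 10]]), [0, 1])
        dets = [det([0, 0, 10, 10], cid=0), det([20, 20, 30, 30], cid=1)]
        M = confusion_matrix(dets, gts, [0, 1])
        assert np.array_equal(M, np.diag([1, 1, 0]))

    def test_no_detections_all_background(self):
        gts = BoxSet(np.array([[0, 0, 10, 10], [20, 20, 10, 10]]), [0, 1])
        M = confusion_matrix([], gts, [0, 1])
        assert M[0, 2] == 1 and M[1, 2] == 1 and M.sum() == 2

    def test_row_sums_equal_gt_counts(self, rng):
        n = 6
        boxes = np.column_stack([rng.uniform(0, 80, n), rng.uniform(0, 80, n),
                                 rng.uniform(5, 15, n), rng.uniform(5, 15, n)])
        labels = rng.integers(0, 3, n)
        gts = BoxSet(boxes, labels)
        dets = [det(b, cid=int(rng.integers(0, 3)), score=0.9)
                for b in xywh_to_xyxy(boxes)[: n // 2]]
        M = confusion_matrix(dets, gts, [0, 1, 2])
        for c in range(3):
            assert M[c, :].sum() == (labels == c).sum()

    def test_row_normalized_view(self):
        gts = BoxSet(np.array([[0, 0, 10, 10]]), [0])
        M = confusion_matrix([det([0, 0, 10, 10], cid=0)], gts, [0],
                             normalize=True)
        assert M[0, 0] == 1.0


def test_results_json_roundtrip(tmp_path):
    dets = {0: [det([1, 2, 11, 22], cid=3, score=0.5, img=0)],
            1: [det([0, 0, 5, 5], cid=0, score=0.25, img=1)]}
    path = tmp_path / "res.json"
    write_results_json(dets, path)
    back = read_results_json(path)
    assert back[0][0].category_id == 3
    assert np.allclose(back[0][0].box, [1, 2, 11, 22])
    assert back[1][0].score == 0.25
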