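"""Detector pipeline: target assignment, training smoke, checkpoints, NMS."""

import numpy as np
import pytest

from pestfsod.boxes import BoxSet, iou_matrix
from pestfsod.detector import (Detector, ModelConfig, TrainConfig,
                               assign_targets, evaluate_checkpoint, finetune,
                               load_checkpoint, predict, save_checkpoint,
                               train_base)
from pestfsod.episodes import ShotConfig, make_split, sample_kshot

FAST = TrainConfig(iters_base=40, iters_finetune=20, eval_interval=0,
                   lr_finetune=0.01, seed=0)


@pytest.fixture(scope="module")
def trained(request):
    """One shared base checkpoint on a small separable dataset."""
    import warnings

    import pestfsod as pf

    spec = pf.SceneSpec(image_size=(96, 96), n_classes=6, size_range_px=(12, 36),
                        objects_per_image=(1, 2), overlap_max_iou=0.2)
    rng = np.random.default_rng(11)
    man = pf.generate_dataset(spec, {c: 8 for c in range(6)}, None, rng)
    train_m, test_m = pf.split_train_test(man, 0.8, rng)
    split = make_split(list(range(6)), 4, 0)
    cfg = TrainConfig(iters_base=120, iters_finetune=60, eval_interval=0,
                      lr_finetune=0.01, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ckpt = train_base(train_m, split.base_classes, ModelConfig(), cfg)
    return ckpt, train_m, test_m, split, cfg


class TestAssignTargets:
    def test_exact_match_positive_zero_target(self):
        gts = BoxSet(np.array([[0, 0, 10, 10]]), [2])
        labels, tgts, pos = assign_targets(np.array([[0, 0, 10, 10]]), gts, 0.6)
        assert pos[0] and labels[0] == 2
        assert np.allclose(tgts[0], 0)

    def test_low_iou_background(self):
        gts = BoxSet(np.array([[5, 0, 10, 10]]), [1])  # xywh -> [5,0,15,10]
        labels, _, pos = assign_targets(np.array([[0, 0, 10, 10]]), gts, 0.6)
        assert not pos[0] and labels[0] == -1

    def test_tie_breaks_to_lower_gt_index(self):
        gts = BoxSet(np.array([[0, 0, 10, 10], [0, 0, 10, 10]]), [3, 4])
        labels, _, pos = assign_targets(np.array([[0, 0, 10, 10]]), gts, 0.5)
        assert pos[0] and labels[0] == 3

    def test_no_gts_all_background(self):
        labels, _, pos = assign_targets(np.array([[0, 0, 5, 5]]),
                                        BoxSet.empty(), 0.5)
        assert not pos.any() and (labels == -1).all()

    def test_agrees_with_double_loop(self, rng):
        for _ in range(5):
            n_p, n_g = int(rng.integers(1, 50)), int(rng.integers(1, 10))
            props = np.column_stack([rng.uniform(0, 50, n_p), rng.uniform(0, 50, n_p),
                                     rng.uniform(5, 60, n_p), rng.uniform(5, 60, n_p)])
            props[:, 2:] += props[:, :2]
            gts = BoxSet(np.column_stack([rng.uniform(0, 50, n_g).T,
                                          rng.uniform(0, 50, n_g).T,
                                          rng.uniform(5, 20, n_g).T,
                                          rng.uniform(5, 20, n_g).T]),
                         rng.integers(0, 4, n_g))
            labels, _, pos = assign_targets(props, gts, 0.5)
            ious = iou_matrix(props, gts.xyxy)
            for i in range(n_p):
                best = max(range(n_g), key=lambda j: ious[i, j])
                if ious[i, best] >= 0.5:
                    assert pos[i] and labels[i] == gts.labels[best]
                else:
                    assert not pos[i] and labels[i] == -1

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            assign_targets(np.zeros((1, 4)), BoxSet.empty(), 1.5)


class TestTraining:
    def test_one_iteration_smoke(self, tiny_dataset, tmp_path):
        train_m, _, split = tiny_dataset
        cfg = TrainConfig(iters_base=1, eval_interval=0, seed=0)
        ckpt = train_base(train_m, split.base_classes, ModelConfig(), cfg)
        assert len(ckpt.history) == 1
        assert np.isfinite(ckpt.history[0]["total"])
        save_checkpoint(ckpt, tmp_path / "c.ckpt")
        assert (tmp_path / "c.ckpt").exists()

    def test_deterministic_loss_trajectory(self, tiny_dataset):
        train_m, _, split = tiny_dataset
        cfg = TrainConfig(iters_base=10, eval_interval=0, seed=3)
        h1 = train_base(train_m, split.base_classes, ModelConfig(), cfg).history
        h2 = train_base(train_m, split.base_classes, ModelConfig(), cfg).history
        assert [r["total"] for r in h1] == [r["total"] for r in h2]

    def test_separable_two_class_reaches_high_train_map(self):
        """Sanity ceiling: large distinct-colour objects, 2 classes."""
        import warnings

        import pestfsod as pf

        spec = pf.SceneSpec(image_size=(96, 96), n_classes=2,
                            size_range_px=(24, 40), objects_per_image=(1, 1))
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            man = pf.generate_dataset(spec, {0: 10, 1: 10}, None, rng)
            cfg = TrainConfig(iters_base=300, eval_interval=0, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ckpt = train_base(man, [0, 1], ModelConfig(), cfg)
                rep = evaluate_checkpoint(ckpt, man)
            hits += rep.mAP >= 0.9
        assert hits >= 2

    def test_checkpoint_roundtrip_identical_predictions(self, trained, tmp_path):
        ckpt, _, test_m, _, _ = trained
        images = {im["id"]: test_m.image_array(im["id"]) for im in test_m.images[:3]}
        before = predict(ckpt, images)
        save_checkpoint(ckpt, tmp_path / "d.ckpt")
        after = predict(load_checkpoint(tmp_path / "d.ckpt"), images)
        for k in images:
            assert len(before[k]) == len(after[k])
            for a, b in zip(before[k], after[k]):
                assert a.category_id == b.category_id
                assert a.score == b.score
                assert np.array_equal(a.box, b.box)


class TestFinetune:
    def test_missing_novel_class_errors(self, trained):
        ckpt, train_m, _, split, cfg = trained
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kshot = sample_kshot(train_m, split, 3, 0)
        kshot.annotations = [a for a in kshot.annotations
                             if a["category_id"] != split.novel_classes[0]]
        with pytest.raises(ValueError, match="absent"):
            finetune(ckpt, kshot, split, ShotConfig(K=3), cfg)

    @pytest.mark.parametrize("use_fam, use_scl, use_agg",
                             [(False, False, False), (True, False, False),
                              (False, True, False), (True, False, True),
                              (True, True, True)])
    def test_ablation_grid_trains(self, trained, use_fam, use_scl, use_agg):
        """Every ablation arm must train to finite losses and a usable
        checkpoint (the flag grid never breaks optimisation)."""
        import warnings

        ckpt, train_m, test_m, split, _ = trained
        cfg = TrainConfig(iters_base=1, iters_finetune=15, eval_interval=0,
                          lr_finetune=0.01, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kshot = sample_kshot(train_m, split, 5, 0)
            ft = finetune(ckpt, kshot, split, ShotConfig(K=5), cfg,
                          use_fam=use_fam, use_scl=use_scl, use_agg_loss=use_agg)
        assert all(np.isfinite(r["total"]) for r in ft.history[len(ckpt.history):])
        assert set(ft.detector.class_ids) == set(split.all_classes)

    def test_plain_arm_matches_tfa_shape(self, trained):
        """lambda1 = lambda2 = 0 with FAM/SCL off reduces to plain
        fine-tuning: agg and scl components stay exactly zero."""
        import warnings

        ckpt, train_m, _, split, _ = trained
        cfg = TrainConfig(iters_base=1, iters_finetune=10, eval_interval=0,
                          lr_finetune=0.01, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kshot = sample_kshot(train_m, split, 3, 0)
            ft = finetune(ckpt, kshot, split, ShotConfig(K=3), cfg,
                          use_fam=False, use_scl=False)
        new = ft.history[len(ckpt.history):]
        assert all(r["agg"] == 0.0 and r["scl"] == 0.0 for r in new)

    def test_support_bank_built_and_persistent(self, trained):
        import warnings

        ckpt, train_m, _, split, _ = trained
        cfg = TrainConfig(iters_base=1, iters_finetune=5, eval_interval=0, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kshot = sample_kshot(train_m, split, 3, 0)
            ft = finetune(ckpt, kshot, split, ShotConfig(K=3), cfg)
        det = ft.detector
        assert det.support_features is not None and len(det.support_features) > 0
        assert det.fam_enabled
        assert set(np.unique(det.support_labels)) <= set(split.all_classes)


class TestPredict:
    def test_blank_background_no_strong_detections(self, trained):
        ckpt, _, _, _, _ = trained
        blank = np.full((96, 96, 3), 120, dtype=np.uint8)
        dets = predict(ckpt, {0: blank})
        assert all(d.score < 0.9 for d in dets[0])

    def test_duplicate_images_identical_detections(self, trained):
        ckpt, _, test_m, _, _ = trained
        img = test_m.image_array(test_m.images[0]["id"])
        dets = predict(ckpt, {0: img, 1: img.copy()})
        assert len(dets[0]) == len(dets[1])
        for a, b in zip(dets[0], dets[1]):
            assert np.array_equal(a.box, b.box) and a.score == b.score

    def test_groundtruth_proposals_require_explicit_boxes(self, trained):
        ckpt, _, test_m, _, _ = trained
        import copy

        cp = copy.deepcopy(ckpt)
        cp.detector.cfg = ModelConfig(proposal_source="groundtruth")
        img_id = test_m.images[0]["id"]
        img = test_m.image_array(img_id)
        with pytest.raises(ValueError, match="explicit proposals"):
            predict(cp, {img_id: img})
        gts = test_m.boxset(img_id)
        dets = predict(cp, {img_id: img}, proposals={img_id: gts.xyxy})
        assert isinstance(dets[img_id], list)
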