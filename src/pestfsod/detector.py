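"""Desk-scale two-stage few-shot detector.

A small frozen convolutional pyramid with FPN levels P2-P6 provides
multi-scale feature maps; RoI-Align pools each region to a 7x7 grid that
is average-pooled to a D-vector.  Trainable parts are the RPN-lite heads
(objectness + box deltas over a square anchor grid), the RoI
classification/regression MLPs, the feature aggregation module (FAM) and
the contrastive projection head.  Training follows the two-stage
few-shot protocol: base training on abundant base-class data with
focal + smooth-L1 losses, then K-shot fine-tuning over base+novel
classes with the full multi-task objective

    L_total = L_cls + L_reg + lambda1 * L_agg + lambda2 * L_SCL

where the FAM consumes a support bank of pooled K-shot RoI features that
also serves as the permanent support set at inference time.

Freezing the randomly initialised backbone is a deliberate desk-scale
choice: random convolutional pyramids retain colour and coarse shape
information, which is sufficient for the procedural scenes, and it keeps
every gradient analytic and cheap.  A deeper trainable backbone can be
swapped in behind the same config surface.
"""

from __future__ import annotations

import copy
import pickle
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._nn import MLP, Param, SGDMomentum, avgpool2, conv2d, kaiming, roi_align, softmax_rows, upsample2
from .boxes import BoxSet, decode_deltas, encode_deltas, iou_matrix, nms, xywh_to_xyxy
from .contrastive import ProjectionHead, SclConfig, embed_backward, embed_normalize, supcon_loss_grad
from .episodes import ClassSplit, ShotConfig
from .evaluation import evaluate_detections
from .feature_aggregation import FamParams, fam_backward, fam_forward
from .losses import (FocalConfig, aggregation_loss_grad, focal_loss_grad,
                     inverse_frequency_alpha, smooth_l1_grad, total_loss)
from .synthetic_scenes import DatasetManifest

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "Detection",
    "Detector",
    "assign_targets",
    "train_base",
    "finetune",
    "predict",
    "evaluate_checkpoint",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture knobs for the desk-scale detector."""

    backbone_channels: tuple[int, ...] = (12, 24, 48, 64)  # C2..C5
    feature_dim: int = 64  # FPN channel width
    roi_size: int = 7
    roi_pool_grid: int = 3  # 7x7 RoI grid pooled to this spatial grid
    head_hidden: int = 96
    fpn_levels: tuple[int, ...] = (2, 3, 4, 5, 6)
    canonical_size: float = 48.0  # RoI-to-level assignment scale
    proposal_source: str = "rpn"  # rpn | groundtruth | jittered_groundtruth
    anchor_scales: tuple[float, ...] = (10.0, 14.0, 20.0, 28.0, 38.0)
    rpn_level: int = 3
    score_threshold: float = 0.35
    nms_iou: float = 0.35
    refine_passes: int = 2  # regression refinement iterations at predict
    dropout: float = 0.1
    d_k: int | None = None  # FAM head dim; None -> feature_dim

    def __post_init__(self):
        if self.roi_size < 1 or not self.fpn_levels:
            raise ValueError("roi_size must be >= 1 and fpn_levels non-empty")
        if self.proposal_source not in ("rpn", "groundtruth", "jittered_groundtruth"):
            raise ValueError(f"unknown proposal_source {self.proposal_source!r}")

    @property
    def roi_feat_dim(self) -> int:
        """RoI descriptor length: pooled spatial grid x FPN channels."""
        return self.roi_pool_grid**2 * self.feature_dim


@dataclass
class TrainConfig:
    """Optimisation schedule; defaults mirror the published protocol."""

    lr_base: float = 0.02
    lr_finetune: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 4
    iters_base: int = 18000
    iters_finetune: int = 1500
    eval_interval: int = 3000
    lr_schedule: str = "step"  # step (x0.1 at 2/3 of iters) | cosine
    seed: int = 0
    base_iou_pos: float = 0.5
    focal_gamma: float = 2.0
    fam_in_base: bool = False  # base stage is plain two-stage training
    scl_in_base: bool = False

    def __post_init__(self):
        if self.lr_base <= 0 or self.lr_finetune <= 0:
            raise ValueError("learning rates must be positive")
        if self.iters_base < 1 or self.iters_finetune < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.lr_schedule not in ("step", "cosine"):
            raise ValueError("lr_schedule must be 'step' or 'cosine'")


@dataclass
class Detection:
    """One predicted instance: corner-form box, class id, score."""

    image_id: int
    box: np.ndarray  # (4,) x1, y1, x2, y2
    category_id: int
    score: float

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).ravel()
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")
        if self.box[2] < self.box[0] or self.box[3] < self.box[1]:
            raise ValueError("invalid box")


# regression-target scaling (standard Faster-R-CNN practice): amplifies
# the centre-offset components so smooth-L1 gradients on small deltas are
# not vanishingly weak
_DELTA_SCALE = np.array([10.0, 10.0, 5.0, 5.0])


def assign_targets(
    proposals_xyxy: np.ndarray, gts: BoxSet, iou_pos: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label proposals against ground truth at one IoU threshold.

    A proposal is positive iff its maximum IoU over GTs is at least
    ``iou_pos``; it takes the class of the argmax GT (ties resolved to
    the lower GT index).  Returns (labels with -1 for background,
    regression deltas toward the matched GT, positive mask).
    """
    if not (0 < iou_pos < 1):
        raise ValueError("iou_pos must lie in (0, 1)")
    P = np.asarray(proposals_xyxy, dtype=float).reshape(-1, 4)
    n = len(P)
    labels = np.full(n, -1, dtype=int)
    targets = np.zeros((n, 4))
    pos = np.zeros(n, dtype=bool)
    if len(gts) == 0 or n == 0:
        return labels, targets, pos
    ious = iou_matrix(P, gts.xyxy)
    best = np.argmax(ious, axis=1)
    best_iou = ious[np.arange(n), best]
    pos = best_iou >= iou_pos
    labels[pos] = gts.labels[best[pos]]
    targets[pos] = encode_deltas(P[pos], gts.xyxy[best[pos]])
    return labels, targets, pos


# ---------------------------------------------------------------------------
# Backbone + FPN (frozen) and RoI feature extraction
# ---------------------------------------------------------------------------


class _Backbone:
    """Fixed random convolutional pyramid with an FPN on top."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        ch = cfg.backbone_channels
        D = cfg.feature_dim
        self.cfg = cfg
        self.stage_w = []
        c_in = 3
        for c_out in ch:
            self.stage_w.append(kaiming(rng, 9 * c_in, (3, 3, c_in, c_out)))
            c_in = c_out
        self.lateral_w = [kaiming(rng, c, (1, 1, c, D)) for c in ch]
        self.smooth_w = [kaiming(rng, 9 * D, (3, 3, D, D)) for _ in ch]

    def pyramid(self, img: np.ndarray) -> dict[int, np.ndarray]:
        """P2..P6 feature maps for one HxWx3 image (uint8 or float)."""
        x = np.asarray(img, dtype=float)
        if x.max() > 1.5:
            x = x / 255.0
        x = x - x.mean(axis=(0, 1), keepdims=True)
        feats = []  # C2..C5 at strides 4, 8, 16, 32
        x = avgpool2(x)  # stride 2 stem
        for w in self.stage_w:
            x = np.maximum(conv2d(x, w), 0.0)
            x = avgpool2(x)
            feats.append(x)
        # top-down FPN
        P: dict[int, np.ndarray] = {}
        levels = [2, 3, 4, 5]
        top = None
        for lvl, c, lat_w, sm_w in zip(
            reversed(levels), reversed(feats), reversed(self.lateral_w), reversed(self.smooth_w)
        ):
            lat = conv2d(c, lat_w)
            if top is not None:
                lat = lat + upsample2(top, lat.shape[:2])
            top = lat
            P[lvl] = conv2d(lat, sm_w)
        P[6] = avgpool2(P[5]) if min(P[5].shape[:2]) >= 2 else P[5]
        return P


def _standardize(v: np.ndarray) -> np.ndarray:
    """Per-row standardisation of pooled RoI vectors (parameter-free)."""
    mu = v.mean(axis=-1, keepdims=True)
    sd = v.std(axis=-1, keepdims=True)
    return (v - mu) / np.maximum(sd, 1e-6)


def _roi_level(cfg: ModelConfig, box_xyxy: np.ndarray) -> int:
    w = max(box_xyxy[2] - box_xyxy[0], 1e-3)
    h = max(box_xyxy[3] - box_xyxy[1], 1e-3)
    k = 4 + np.log2(np.sqrt(w * h) / cfg.canonical_size)
    return int(np.clip(np.floor(k), min(cfg.fpn_levels), max(cfg.fpn_levels)))


def _roi_features(cfg: ModelConfig, pyramid: dict[int, np.ndarray], boxes_xyxy: np.ndarray) -> np.ndarray:
    """Pooled, standardised RoI descriptors for a set of boxes.

    The 7x7 RoI-Align grid is average-pooled to a coarse
    ``roi_pool_grid`` x ``roi_pool_grid`` spatial grid and flattened;
    keeping a little spatial structure is what lets the box regressor
    see where an object sits inside its proposal.
    """
    B = np.asarray(boxes_xyxy, dtype=float).reshape(-1, 4)
    out = np.zeros((len(B), cfg.roi_feat_dim))
    if len(B) == 0:
        return out
    g = cfg.roi_pool_grid
    S = cfg.roi_size
    # overlapping pooling windows covering the 7x7 grid
    edges = np.linspace(0, S, g + 1)
    wins = [(int(np.floor(edges[i])), int(np.ceil(edges[i + 1]))) for i in range(g)]
    levels = np.array([_roi_level(cfg, b) for b in B])
    for lvl in np.unique(levels):
        sel = np.flatnonzero(levels == lvl)
        grids = roi_align(pyramid[lvl], B[sel], S, 1.0 / (2**lvl))
        pooled = np.stack(
            [
                grids[:, ya:yb, xa:xb].mean(axis=(1, 2))
                for ya, yb in wins
                for xa, xb in wins
            ],
            axis=1,
        )  # (n, g*g, C)
        out[sel] = pooled.reshape(len(sel), -1)
    return _standardize(out)


# ---------------------------------------------------------------------------
# The detector
# ---------------------------------------------------------------------------


class Detector:
    """Two-stage detector with optional FAM/SCL branches."""

    def __init__(self, model_cfg: ModelConfig, class_ids: list[int], seed: int = 0):
        self.cfg = model_cfg
        self.class_ids = list(class_ids)
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.backbone = _Backbone(model_cfg, rng)
        Dr, H = model_cfg.roi_feat_dim, model_cfg.head_hidden
        D = model_cfg.feature_dim
        C = len(self.class_ids)
        self.cls_head = MLP(rng, [Dr, H, C + 1])
        self.reg_head = MLP(rng, [Dr, H, 4])
        nA = len(model_cfg.anchor_scales)
        self.rpn_obj = MLP(rng, [D, nA])
        self.rpn_reg = MLP(rng, [D, 4 * nA])
        self.fam = FamParams(Dr, model_cfg.d_k or D, rng=rng)
        self.scl_cfg = SclConfig(hidden_dim=H, embed_dim=64)
        self.proj_head = ProjectionHead(rng, Dr, self.scl_cfg)
        self.support_features: np.ndarray | None = None  # (N_s, D) bank
        self.support_labels: np.ndarray | None = None
        self.fam_enabled = False
        self._pyramid_cache: dict[int, dict[int, np.ndarray]] = {}

    # -- parameters ------------------------------------------------------

    def trainable_params(self, include_fam: bool, include_scl: bool) -> list[Param]:
        ps = self.cls_head.params() + self.reg_head.params()
        ps += self.rpn_obj.params() + self.rpn_reg.params()
        if include_fam:
            ps += self.fam.params()
        if include_scl:
            ps += self.proj_head.params()
        return ps

    def background_index(self) -> int:
        return len(self.class_ids)

    # -- features --------------------------------------------------------

    def pyramid_for(self, image_id: int, img: np.ndarray) -> dict[int, np.ndarray]:
        if image_id not in self._pyramid_cache:
            self._pyramid_cache[image_id] = self.backbone.pyramid(img)
        return self._pyramid_cache[image_id]

    def clear_cache(self) -> None:
        self._pyramid_cache.clear()

    # -- RPN-lite --------------------------------------------------------

    def _anchor_grid(self, image_hw: tuple[int, int]) -> tuple[np.ndarray, tuple[int, int]]:
        stride = 2**self.cfg.rpn_level
        Hf = image_hw[0] // stride
        Wf = image_hw[1] // stride
        ys, xs = np.mgrid[0:Hf, 0:Wf]
        cx = (xs.ravel() + 0.5) * stride
        cy = (ys.ravel() + 0.5) * stride
        anchors = []
        for s in self.cfg.anchor_scales:
            anchors.append(
                np.stack([cx - s / 2, cy - s / 2, cx + s / 2, cy + s / 2], axis=1)
            )
        return np.concatenate(anchors, axis=0), (Hf, Wf)  # (A*Hf*Wf, 4)

    def _rpn_location_features(self, pyramid: dict[int, np.ndarray]) -> np.ndarray:
        fm = pyramid[self.cfg.rpn_level]
        v = fm.reshape(-1, fm.shape[-1])
        return _standardize(v)

    def rpn_proposals(
        self, pyramid: dict[int, np.ndarray], image_hw: tuple[int, int],
        pre_nms: int = 150, post_nms: int = 50,
    ) -> np.ndarray:
        anchors, (Hf, Wf) = self._anchor_grid(image_hw)
        loc = self._rpn_location_features(pyramid)[: Hf * Wf]
        obj, _ = self.rpn_obj.forward(loc)  # (HW, A)
        reg, _ = self.rpn_reg.forward(loc)  # (HW, 4A)
        nA = len(self.cfg.anchor_scales)
        scores = 1.0 / (1.0 + np.exp(-obj.T.ravel()))  # anchor-major
        deltas = reg.reshape(-1, nA, 4).transpose(1, 0, 2).reshape(-1, 4)
        boxes = decode_deltas(anchors, deltas / _DELTA_SCALE)
        H, W = image_hw
        boxes[:, [0, 2]] = np.clip(boxes[:, [0, 2]], 0, W)
        boxes[:, [1, 3]] = np.clip(boxes[:, [1, 3]], 0, H)
        ok = (boxes[:, 2] - boxes[:, 0] > 2) & (boxes[:, 3] - boxes[:, 1] > 2)
        boxes, scores = boxes[ok], scores[ok]
        top = np.argsort(-scores, kind="stable")[:pre_nms]
        keep = nms(boxes[top], scores[top], iou_thr=0.65)[:post_nms]
        return boxes[top][keep]

    def _rpn_loss_and_step_grads(
        self, pyramid, image_hw, gts: BoxSet, rng: np.random.Generator
    ) -> float:
        """Accumulate RPN gradients for one image; returns the RPN loss."""
        anchors, (Hf, Wf) = self._anchor_grid(image_hw)
        loc = self._rpn_location_features(pyramid)[: Hf * Wf]
        nA = len(self.cfg.anchor_scales)
        obj, obj_cache = self.rpn_obj.forward(loc)
        reg, reg_cache = self.rpn_reg.forward(loc)
        logits = obj.T.ravel()
        if len(gts) == 0:
            labels = np.zeros(len(anchors), dtype=bool)
        else:
            ious = iou_matrix(anchors, gts.xyxy)
            best = ious.max(axis=1)
            labels = best >= 0.5
            labels[np.argmax(ious, axis=0)] = True  # best anchor per GT
            neg = best < 0.3
        pos_idx = np.flatnonzero(labels)
        if len(gts) == 0:
            neg_idx = np.flatnonzero(np.ones(len(anchors), dtype=bool))
        else:
            neg_idx = np.flatnonzero(neg & ~labels)
        if len(neg_idx) > 32:
            neg_idx = neg_idx[rng.choice(len(neg_idx), 32, replace=False)]
        if len(pos_idx) > 32:
            pos_idx = pos_idx[rng.choice(len(pos_idx), 32, replace=False)]
        sel = np.concatenate([pos_idx, neg_idx])
        if sel.size == 0:
            return 0.0
        y = np.zeros(len(sel))
        y[: len(pos_idx)] = 1.0
        z = logits[sel]
        p = 1.0 / (1.0 + np.exp(-z))
        bce = float(np.mean(-(y * np.log(np.clip(p, 1e-12, 1)) + (1 - y) * np.log(np.clip(1 - p, 1e-12, 1)))))
        dlogit_sel = (p - y) / len(sel)
        grad_obj = np.zeros_like(logits)
        grad_obj[sel] = dlogit_sel
        self.rpn_obj.backward(grad_obj.reshape(nA, -1).T, obj_cache)
        # regression on positives
        l_reg = 0.0
        grad_reg_full = np.zeros_like(reg)
        if len(pos_idx) and len(gts):
            ious = iou_matrix(anchors[pos_idx], gts.xyxy)
            match = np.argmax(ious, axis=1)
            tgt = encode_deltas(anchors[pos_idx], gts.xyxy[match]) * _DELTA_SCALE
            a_of = pos_idx // (Hf * Wf)
            l_of = pos_idx % (Hf * Wf)
            pred = reg.reshape(-1, nA, 4)[l_of, a_of]
            l_reg, g = smooth_l1_grad(pred, tgt)
            gfull = grad_reg_full.reshape(-1, nA, 4)
            gfull[l_of, a_of] = g
        self.rpn_reg.backward(grad_reg_full, reg_cache)
        return bce + l_reg


def _jittered_proposals(gts: BoxSet, image_hw: tuple[int, int], rng: np.random.Generator,
                        per_gt: int = 4, n_bg: int = 8) -> np.ndarray:
    """GT boxes plus controlled noise, plus random background boxes."""
    H, W = image_hw
    out = [gts.xyxy] if len(gts) else []
    for b in gts.xyxy:
        w, h = b[2] - b[0], b[3] - b[1]
        for _ in range(per_gt):
            sc = rng.uniform(0.65, 1.5, size=2)
            sh = rng.uniform(-0.3, 0.3, size=2) * [w, h]
            cx, cy = (b[0] + b[2]) / 2 + sh[0], (b[1] + b[3]) / 2 + sh[1]
            nw, nh = w * sc[0], h * sc[1]
            out.append(np.array([[cx - nw / 2, cy - nh / 2, cx + nw / 2, cy + nh / 2]]))
    for _ in range(n_bg):
        s = rng.uniform(8, max(9, min(H, W) / 2))
        x = rng.uniform(0, W - s)
        y = rng.uniform(0, H - s)
        out.append(np.array([[x, y, x + s, y + s]]))
    P = np.concatenate(out, axis=0) if out else np.zeros((0, 4))
    P[:, [0, 2]] = np.clip(P[:, [0, 2]], 0, W)
    P[:, [1, 3]] = np.clip(P[:, [1, 3]], 0, H)
    return P


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _manifest_items(manifest: DatasetManifest, class_filter: set[int] | None = None):
    """(image_id, pixels, BoxSet) triples, optionally restricted to classes.

    With a class filter, images whose annotations are all outside the
    filter are dropped, as are annotations of filtered-out classes.
    """
    items = []
    for im in manifest.images:
        bset = manifest.boxset(im["id"])
        if class_filter is not None:
            keep = np.isin(bset.labels, list(class_filter))
            if not keep.any():
                continue
            bset = bset.select(np.flatnonzero(keep))
        items.append((im["id"], manifest.image_array(im["id"]), bset))
    return items


def _lr_at(cfg: TrainConfig, base_lr: float, it: int, total: int) -> float:
    if cfg.lr_schedule == "cosine":
        return base_lr * 0.5 * (1 + np.cos(np.pi * it / max(total, 1)))
    return base_lr * (0.1 if it >= (2 * total) // 3 else 1.0)


class Checkpoint:
    """Weights + optimizer state + learning rate + config, one archive."""

    def __init__(self, detector: Detector, train_cfg: TrainConfig,
                 optimizer_state=None, lr: float | None = None,
                 history: list[dict] | None = None):
        self.detector = detector
        self.train_cfg = train_cfg
        self.optimizer_state = optimizer_state
        self.lr = lr
        self.history = history or []


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    det = ckpt.detector
    cache, det._pyramid_cache = det._pyramid_cache, {}
    try:
        with open(path, "wb") as fh:
            pickle.dump(ckpt, fh)
    finally:
        det._pyramid_cache = cache


def load_checkpoint(path: str | Path) -> Checkpoint:
    with open(path, "rb") as fh:
        return pickle.load(fh)


def _detector_state(det: Detector) -> list[np.ndarray]:
    return [p.value.copy() for p in det.trainable_params(True, True)]


def _restore_state(det: Detector, state: list[np.ndarray]) -> None:
    for p, v in zip(det.trainable_params(True, True), state):
        p.value[...] = v


def _train_loop(
    det: Detector,
    items: list,
    cfg: TrainConfig,
    *,
    lr: float,
    iters: int,
    iou_pos: float,
    scl_iou_pos: float | None = None,
    use_fam: bool,
    use_scl: bool,
    lambda1: float,
    lambda2: float,
    tau: float,
    alpha_t,
    val_items: list | None,
    eval_interval: int,
    support_counts: dict[int, int] | None = None,
) -> tuple[list[dict], list[np.ndarray] | None, float]:
    """Shared optimisation loop for base training and fine-tuning.

    Returns (loss history, best-by-val-mAP parameter snapshot or None,
    final learning rate).  Aborts on NaN losses, keeping the last good
    snapshot.
    """
    rng = np.random.default_rng(cfg.seed)
    params = det.trainable_params(use_fam, use_scl)
    opt = SGDMomentum(params, lr, cfg.momentum, cfg.weight_decay)
    focal_cfg = FocalConfig(gamma=cfg.focal_gamma, alpha_t=alpha_t)
    cls_index = {c: i for i, c in enumerate(det.class_ids)}
    bg = det.background_index()
    history: list[dict] = []
    best_state, best_map = None, -1.0
    last_good = _detector_state(det)

    for it in range(iters):
        opt.lr = _lr_at(cfg, lr, it, iters)
        opt.zero_grad()
        pick = rng.choice(len(items), size=min(cfg.batch_size, len(items)), replace=False)
        feats_list, labels_list, tgts_list, pos_list, iou_list = [], [], [], [], []
        rpn_loss = 0.0
        for bi in pick:
            img_id, img, gts = items[bi]
            pyr = det.pyramid_for(img_id, img)
            hw = img.shape[:2]
            if det.cfg.proposal_source == "rpn":
                rpn_loss += det._rpn_loss_and_step_grads(pyr, hw, gts, rng)
                # jittered GTs for positives + current RPN output as hard
                # examples (mirrors sampling from live proposals)
                rp = det.rpn_proposals(pyr, hw, post_nms=16)
                props = np.concatenate([_jittered_proposals(gts, hw, rng), rp])
            elif det.cfg.proposal_source == "groundtruth":
                props = gts.xyxy
            else:
                props = _jittered_proposals(gts, hw, rng)
            if len(props) == 0:
                continue
            labels, tgts, pos = assign_targets(props, gts, iou_pos)
            if len(gts):
                best_iou = iou_matrix(props, gts.xyxy).max(axis=1)
            else:
                best_iou = np.zeros(len(props))
            feats_list.append(_roi_features(det.cfg, pyr, props))
            labels_list.append(labels)
            tgts_list.append(tgts)
            pos_list.append(pos)
            iou_list.append(best_iou)
        if not feats_list:
            continue
        F = np.concatenate(feats_list)
        labels = np.concatenate(labels_list)
        tgts = np.concatenate(tgts_list)
        pos = np.concatenate(pos_list)
        best_iou = np.concatenate(iou_list)
        # contrastive membership uses the shot-specific IoU threshold
        scl_pos = pos & (best_iou >= (scl_iou_pos if scl_iou_pos is not None else iou_pos))

        # FAM
        l_agg = 0.0
        fam_cache = None
        grad_s = grad_A = None
        if use_fam and det.support_features is not None and len(det.support_features):
            att, fam_cache = fam_forward(F, det.support_features, det.fam)
            Fe = att.F_enhanced
            if lambda1 != 0.0:
                _, _, l_agg, gs, gA = aggregation_loss_grad(att.scores, att.weights)
                grad_s, grad_A = lambda1 * gs, lambda1 * gA
        else:
            Fe = F

        # dropout on head input (training only)
        if det.cfg.dropout > 0:
            keep = rng.random(Fe.shape) >= det.cfg.dropout
            Fe_in = Fe * keep / (1.0 - det.cfg.dropout)
        else:
            keep = None
            Fe_in = Fe

        y = np.array([cls_index[c] if c >= 0 else bg for c in labels])
        logits, cls_cache = det.cls_head.forward(Fe_in)
        p = softmax_rows(logits)
        l_cls, dP = focal_loss_grad(p, y, focal_cfg)
        dlogits = p * (dP - np.sum(dP * p, axis=1, keepdims=True))
        grad_Fe = det.cls_head.backward(dlogits, cls_cache)

        reg_out, reg_cache = det.reg_head.forward(Fe_in)
        if pos.any():
            l_reg, g_reg = smooth_l1_grad(reg_out[pos], tgts[pos] * _DELTA_SCALE)
            g_full = np.zeros_like(reg_out)
            g_full[pos] = g_reg
        else:
            l_reg, g_full = 0.0, np.zeros_like(reg_out)
        grad_Fe = grad_Fe + det.reg_head.backward(g_full, reg_cache)
        if keep is not None:
            grad_Fe = grad_Fe * keep / (1.0 - det.cfg.dropout)

        # SCL over high-IoU RoIs
        l_scl = 0.0
        if use_scl and scl_pos.sum() >= 2 and lambda2 != 0.0:
            counts = support_counts or {
                int(c): int(n) for c, n in zip(*np.unique(labels[scl_pos], return_counts=True))
            }
            try:
                batch, emb_cache = embed_normalize(
                    Fe[scl_pos], det.proj_head, labels[scl_pos], counts
                )
                scl_cfg = replace(det.scl_cfg, tau=tau, weighted=True)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    l_scl, gz = supcon_loss_grad(batch, scl_cfg)
                gF_scl = embed_backward(emb_cache, lambda2 * gz)
                grad_Fe[scl_pos] += gF_scl
            except FloatingPointError:
                l_scl = 0.0

        if fam_cache is not None:
            fam_backward(fam_cache, grad_Fe, grad_scores=grad_s, grad_weights=grad_A)

        bundle = total_loss(l_cls, l_reg, l_agg, l_scl, lambda1, lambda2)
        if not np.isfinite(bundle.l_total):
            warnings.warn("training diverged (non-finite loss); reverting to last "
                          "good state", stacklevel=2)
            _restore_state(det, last_good)
            break
        opt.step()
        rec = bundle.as_dict()
        rec.update({"iter": it, "rpn": rpn_loss, "lr": opt.lr})
        history.append(rec)
        last_good = _detector_state(det)

        if val_items is not None and eval_interval > 0 and (
            (it + 1) % eval_interval == 0 or it + 1 == iters
        ):
            rep = _evaluate_on(det, val_items)
            history[-1]["val_mAP"] = rep.mAP
            if np.isnan(rep.mAP) or rep.mAP >= best_map:
                best_map = rep.mAP if not np.isnan(rep.mAP) else best_map
                best_state = _detector_state(det)
    return history, best_state, opt.lr


def _evaluate_on(det: Detector, items: list, split: ClassSplit | None = None):
    dets_by_image = {}
    gts_by_image = {}
    for img_id, img, gts in items:
        dets_by_image[img_id] = _predict_one(det, img_id, img)
        gts_by_image[img_id] = BoxSet(gts.boxes, gts.labels, image_id=img_id)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluate_detections(dets_by_image, gts_by_image, det.class_ids, split)


def _predict_one(det: Detector, image_id: int, img: np.ndarray,
                 proposals: np.ndarray | None = None) -> list[Detection]:
    pyr = det.pyramid_for(image_id, img)
    hw = img.shape[:2]
    if proposals is None:
        if det.cfg.proposal_source == "rpn":
            props = det.rpn_proposals(pyr, hw)
        else:
            raise ValueError("non-RPN proposal sources need explicit proposals")
    else:
        props = np.asarray(proposals, dtype=float).reshape(-1, 4)
    if len(props) == 0:
        return []
    H, W = hw
    bg = det.background_index()

    def head_pass(boxes_in: np.ndarray):
        F = _roi_features(det.cfg, pyr, boxes_in)
        if det.fam_enabled and det.support_features is not None and len(det.support_features):
            att, _ = fam_forward(F, det.support_features, det.fam)
            F = att.F_enhanced
        logits, _ = det.cls_head.forward(F)
        p = softmax_rows(logits)
        reg, _ = det.reg_head.forward(F)
        refined = decode_deltas(boxes_in, reg / _DELTA_SCALE)
        refined[:, [0, 2]] = np.clip(refined[:, [0, 2]], 0, W)
        refined[:, [1, 3]] = np.clip(refined[:, [1, 3]], 0, H)
        return p, refined

    boxes = props
    for _ in range(max(det.cfg.refine_passes, 1)):
        p, boxes = head_pass(boxes)
    cls_best = np.argmax(p[:, :bg], axis=1)
    score = p[np.arange(len(p)), cls_best]
    keep = (score >= det.cfg.score_threshold) & (np.argmax(p, axis=1) != bg)
    if not keep.any():
        return []
    boxes = boxes[keep]
    cls_k = cls_best[keep]
    score_k = score[keep]
    out: list[Detection] = []
    for ci in np.unique(cls_k):
        sel = np.flatnonzero(cls_k == ci)
        kept = nms(boxes[sel], score_k[sel], det.cfg.nms_iou)
        for j in sel[kept]:
            out.append(
                Detection(image_id, boxes[j], det.class_ids[int(ci)], float(score_k[j]))
            )
    out.sort(key=lambda d: -d.score)
    return out


def train_base(
    manifest: DatasetManifest,
    base_classes: list[int],
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    val_manifest: DatasetManifest | None = None,
) -> Checkpoint:
    """Stage 1: train on all base-class data with L_cls + L_reg.

    Evaluates on the validation manifest every ``cfg.eval_interval``
    iterations and returns the best-by-validation-mAP checkpoint (the
    final state if no validation set is given).
    """
    base_set = set(base_classes)
    items = _manifest_items(manifest, base_set)
    if not items:
        raise ValueError("no base-class training data")
    det = Detector(model_cfg, sorted(base_set), seed=cfg.seed)
    counts: dict[int, int] = {}
    for _, _, gts in items:
        for c in gts.labels:
            counts[int(c)] = counts.get(int(c), 0) + 1
    alpha = np.ones(len(det.class_ids) + 1)
    alpha[: len(det.class_ids)] = inverse_frequency_alpha(
        {det.class_ids.index(c): n for c, n in counts.items()}, len(det.class_ids)
    )
    val_items = _manifest_items(val_manifest, base_set) if val_manifest is not None else None
    history, best, lr = _train_loop(
        det, items, cfg,
        lr=cfg.lr_base, iters=cfg.iters_base, iou_pos=cfg.base_iou_pos,
        use_fam=cfg.fam_in_base, use_scl=cfg.scl_in_base,
        lambda1=0.0, lambda2=0.0, tau=0.2, alpha_t=alpha,
        val_items=val_items, eval_interval=cfg.eval_interval,
    )
    if best is not None:
        _restore_state(det, best)
    det.clear_cache()
    return Checkpoint(det, cfg, lr=lr, history=history)


def _extend_classifier(det: Detector, all_classes: list[int], rng: np.random.Generator) -> None:
    """Grow the classifier to base+novel classes, keeping learned weights."""
    old_ids = det.class_ids
    new_ids = list(all_classes)
    last = det.cls_head.layers[-1]
    H = last.W.value.shape[0]
    C_new = len(new_ids)
    W = kaiming(rng, H, (H, C_new + 1)) * 0.1
    b = np.zeros(C_new + 1)
    for i, c in enumerate(old_ids):
        j = new_ids.index(c)
        W[:, j] = last.W.value[:, i]
        b[j] = last.b.value[i]
    W[:, C_new] = last.W.value[:, len(old_ids)]  # background column
    b[C_new] = last.b.value[len(old_ids)]
    last.W = Param(W)
    last.b = Param(b)
    det.class_ids = new_ids


def _build_support_bank(det: Detector, kshot: DatasetManifest) -> None:
    feats, labs = [], []
    for im in kshot.images:
        img = kshot.image_array(im["id"])
        gts = kshot.boxset(im["id"])
        if len(gts) == 0:
            continue
        pyr = det.backbone.pyramid(img)
        feats.append(_roi_features(det.cfg, pyr, gts.xyxy))
        labs.append(gts.labels)
    det.support_features = np.concatenate(feats) if feats else np.zeros((0, det.cfg.roi_feat_dim))
    det.support_labels = np.concatenate(labs) if labs else np.zeros(0, dtype=int)


def finetune(
    ckpt: Checkpoint,
    kshot: DatasetManifest,
    split: ClassSplit,
    shot_cfg: ShotConfig,
    cfg: TrainConfig | None = None,
    use_fam: bool = True,
    use_scl: bool = True,
    use_agg_loss: bool = True,
    val_manifest: DatasetManifest | None = None,
) -> Checkpoint:
    """Stage 2: K-shot fine-tuning over base + novel classes.

    Extends the classifier to the novel classes, builds the FAM support
    bank from the K-shot set (kept as the permanent support set at
    inference), and optimises the full multi-task objective with the
    shot-specific IoU threshold, temperature and loss weights.  With
    ``use_fam=use_scl=False`` and zero lambdas this reduces to plain
    fine-tuning.
    """
    cfg = cfg or ckpt.train_cfg
    det = copy.deepcopy(ckpt.detector)
    det.clear_cache()
    present = {a["category_id"] for a in kshot.annotations}
    missing = [c for c in split.novel_classes if c not in present]
    if missing:
        raise ValueError(f"novel classes absent from K-shot set: {missing}")
    rng = np.random.default_rng(cfg.seed + 1)
    _extend_classifier(det, split.base_classes + split.novel_classes, rng)
    _build_support_bank(det, kshot)
    det.fam_enabled = use_fam

    items = _manifest_items(kshot)
    support_counts = {int(c): int(n) for c, n in
                      zip(*np.unique(det.support_labels, return_counts=True))}
    alpha = np.ones(len(det.class_ids) + 1)
    alpha[: len(det.class_ids)] = inverse_frequency_alpha(
        {det.class_ids.index(c): n for c, n in support_counts.items() if c in det.class_ids},
        len(det.class_ids),
    )
    val_items = _manifest_items(val_manifest) if val_manifest is not None else None
    lam1 = shot_cfg.lambda1 if (use_fam and use_agg_loss) else 0.0
    lam2 = shot_cfg.lambda2 if use_scl else 0.0
    history, best, lr = _train_loop(
        det, items, cfg,
        lr=cfg.lr_finetune, iters=cfg.iters_finetune,
        iou_pos=cfg.base_iou_pos, scl_iou_pos=shot_cfg.iou_pos_threshold,
        use_fam=use_fam, use_scl=use_scl,
        lambda1=lam1, lambda2=lam2, tau=shot_cfg.tau, alpha_t=alpha,
        val_items=val_items, eval_interval=cfg.eval_interval,
        support_counts=support_counts,
    )
    if best is not None:
        _restore_state(det, best)
    det.clear_cache()
    out = Checkpoint(det, cfg, lr=lr, history=ckpt.history + history)
    return out


def predict(
    ckpt: Checkpoint,
    images: dict[int, np.ndarray],
    proposals: dict[int, np.ndarray] | None = None,
) -> dict[int, list[Detection]]:
    """Detections per image: score threshold + class-wise NMS applied.

    Deterministic given weights and inputs.  ``proposals`` overrides the
    proposal source (required for groundtruth/jittered modes).
    """
    det = ckpt.detector
    out = {}
    for img_id, img in images.items():
        pr = None if proposals is None else proposals.get(img_id)
        out[img_id] = _predict_one(det, img_id, img, pr)
    det.clear_cache()
    return out


def evaluate_checkpoint(
    ckpt: Checkpoint, manifest: DatasetManifest, split: ClassSplit | None = None
):
    """Convenience: run prediction over a manifest and score it."""
    items = _manifest_items(manifest)
    rep = _evaluate_on(ckpt.detector, items, split)
    ckpt.detector.clear_cache()
    return rep
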