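"""Matching-based detection metrics: PR curves, AP, bAP/nAP/mAP.

A predicted box is a true positive when its IoU with an unmatched
ground-truth box of the same class exceeds 0.5 (strictly, by default);
matching is greedy in descending score and one-to-one.  AP is the area
under the precision-recall curve using all-points interpolation (the
monotone precision envelope integrated over recall).  bAP, nAP and mAP
are unweighted means of per-class AP over base, novel and all evaluated
classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .boxes import BoxSet, iou_matrix
from .episodes import ClassSplit

__all__ = [
    "EvalReport",
    "iou",
    "match_detections",
    "average_precision",
    "evaluate_detections",
    "split_map",
    "confusion_matrix",
    "published_ap_table",
    "write_results_json",
    "read_results_json",
]


def iou(a_xyxy, b_xyxy) -> float:
    """IoU of two corner-form boxes (degenerate boxes give 0)."""
    return float(iou_matrix(np.asarray(a_xyxy)[None, :], np.asarray(b_xyxy)[None, :])[0, 0])


def match_detections(
    dets: list,
    gts: BoxSet,
    iou_thr: float = 0.5,
    strict: bool = True,
) -> tuple[np.ndarray, int]:
    """Greedy one-to-one matching of detections to ground truth.

    ``dets`` are Detection-like objects (``box`` xyxy, ``category_id``,
    ``score``).  Processing in descending score, each detection claims the
    unmatched same-class GT of highest IoU if that IoU passes the
    threshold (> with ``strict``, >= otherwise), else it is a false
    positive.  Returns TP flags aligned with the input order and the
    count of unmatched GTs (false negatives).
    """
    n = len(dets)
    tp = np.zeros(n, dtype=bool)
    matched = np.zeros(len(gts), dtype=bool)
    order = sorted(range(n), key=lambda i: (-dets[i].score, i))
    gt_xyxy = gts.xyxy
    for i in order:
        d = dets[i]
        cand = np.flatnonzero((gts.labels == d.category_id) & ~matched)
        if cand.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ious = iou_matrix(np.asarray(d.box)[None, :], gt_xyxy[cand])[0]
        j = int(np.argmax(ious))
        ok = ious[j] > iou_thr if strict else ious[j] >= iou_thr
        if ok:
            tp[i] = True
            matched[cand[j]] = True
    return tp, int((~matched).sum())


def average_precision(tp_flags: np.ndarray, n_gt: int) -> tuple[float, np.ndarray, np.ndarray]:
    """All-points interpolated AP from score-ranked TP/FP flags.

    Returns (AP, precision points, recall points).  Undefined for
    ``n_gt == 0`` (raises); callers exclude such classes from means.
    """
    if n_gt <= 0:
        raise ValueError("AP undefined for a class with zero ground truth")
    flags = np.asarray(tp_flags, dtype=bool)
    if flags.size == 0:
        return 0.0, np.zeros(0), np.zeros(0)
    cum_tp = np.cumsum(flags)
    cum_fp = np.cumsum(~flags)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # monotone precision envelope (right-to-left running max)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - prev_r) * envelope))
    return ap, precision, recall


@dataclass
class EvalReport:
    """Per-class AP, base/novel/mean aggregates, PR curves and counts."""

    per_class_ap: dict[int, float]
    bAP: float
    nAP: float
    mAP: float
    pr_curves: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    counts: dict[int, dict[str, int]] = field(default_factory=dict)
    iou_threshold: float = 0.5

    def to_json(self, path: str | Path) -> None:
        d = {
            "per_class_ap": {str(k): v for k, v in self.per_class_ap.items()},
            "bAP": self.bAP, "nAP": self.nAP, "mAP": self.mAP,
            "counts": {str(k): v for k, v in self.counts.items()},
            "iou_threshold": self.iou_threshold,
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    def per_class_csv(self, path: str | Path) -> None:
        rows = [{"class_id": c, "ap": ap} for c, ap in sorted(self.per_class_ap.items())]
        pd.DataFrame(rows).to_csv(path, index=False)


def split_map(
    per_class_ap: dict[int, float], split: ClassSplit
) -> tuple[float, float, float]:
    """Unweighted means of per-class AP over base, novel and all classes."""
    for c in split.all_classes:
        if c not in per_class_ap:
            raise KeyError(f"class {c} missing from per-class AP table")
    bap = float(np.mean([per_class_ap[c] for c in split.base_classes]))
    nap = float(np.mean([per_class_ap[c] for c in split.novel_classes]))
    m = float(np.mean([per_class_ap[c] for c in split.all_classes]))
    return bap, nap, m


def evaluate_detections(
    dets_by_image: dict[int, list],
    gts_by_image: dict[int, BoxSet],
    class_ids: list[int],
    split: ClassSplit | None = None,
    iou_thr: float = 0.5,
    strict: bool = True,
) -> EvalReport:
    """Score a detection run against ground truth at one IoU threshold.

    Per class, detections are ranked by score across all images and
    matched greedily per image; classes with zero ground truth anywhere
    are excluded from the means (with a warning).
    """
    per_class_ap: dict[int, float] = {}
    pr_curves = {}
    counts = {}
    for c in class_ids:
        entries = []  # (score, image_id, det)
        n_gt = 0
        for img_id, gts in gts_by_image.items():
            n_gt += int((gts.labels == c).sum())
        for img_id, dets in dets_by_image.items():
            for d in dets:
                if d.category_id == c:
                    entries.append((d.score, img_id, d))
        if n_gt == 0:
            warnings.warn(f"class {c} has no ground truth; excluded from means",
                          stacklevel=2)
            continue
        entries.sort(key=lambda e: -e[0])
        # per-image unmatched-GT bookkeeping
        matched: dict[int, np.ndarray] = {
            img_id: np.zeros(len(g), dtype=bool) for img_id, g in gts_by_image.items()
        }
        flags = np.zeros(len(entries), dtype=bool)
        for k, (_, img_id, d) in enumerate(entries):
            gts = gts_by_image.get(img_id)
            if gts is None or len(gts) == 0:
                continue
            cand = np.flatnonzero((gts.labels == c) & ~matched[img_id])
            if cand.size == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ious = iou_matrix(np.asarray(d.box)[None, :], gts.xyxy[cand])[0]
            j = int(np.argmax(ious))
            ok = ious[j] > iou_thr if strict else ious[j] >= iou_thr
            if ok:
                flags[k] = True
                matched[img_id][cand[j]] = True
        ap, prec, rec = average_precision(flags, n_gt)
        per_class_ap[c] = ap
        pr_curves[c] = (prec, rec)
        counts[c] = {
            "tp": int(flags.sum()),
            "fp": int((~flags).sum()),
            "fn": n_gt - int(flags.sum()),
        }
    evaluated = sorted(per_class_ap)
    if split is not None:
        b = [c for c in split.base_classes if c in per_class_ap]
        n = [c for c in split.novel_classes if c in per_class_ap]
    else:
        b, n = evaluated, []
    bap = float(np.mean([per_class_ap[c] for c in b])) if b else float("nan")
    nap = float(np.mean([per_class_ap[c] for c in n])) if n else float("nan")
    m = float(np.mean([per_class_ap[c] for c in evaluated])) if evaluated else float("nan")
    return EvalReport(per_class_ap, bap, nap, m, pr_curves, counts, iou_thr)


def confusion_matrix(
    dets: list,
    gts: BoxSet,
    class_ids: list[int],
    iou_thr: float = 0.5,
    score_thr: float = 0.5,
    normalize: bool = False,
) -> np.ndarray:
    """(C+1) x (C+1) confusion counts; last index is background.

    Each ground truth is assigned the class of its best-IoU unused
    detection above the IoU threshold (class-agnostic matching);
    unmatched GTs count as (true class, background) and unused detections
    as (background, predicted class).  ``normalize`` divides rows by
    their sums (zero rows left as zero).
    """
    C = len(class_ids)
    idx = {c: i for i, c in enumerate(class_ids)}
    M = np.zeros((C + 1, C + 1))
    strong = [d for d in dets if d.score >= score_thr]
    used = np.zeros(len(strong), dtype=bool)
    gt_xyxy = gts.xyxy
    for g in range(len(gts)):
        best_j, best_iou = -1, iou_thr
        for j, d in enumerate(strong):
            if used[j]:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = iou_matrix(np.asarray(d.box)[None, :], gt_xyxy[g][None, :])[0, 0]
            if v > best_iou:
                best_iou, best_j = v, j
        ti = idx[int(gts.labels[g])]
        if best_j >= 0:
            used[best_j] = True
            M[ti, idx[strong[best_j].category_id]] += 1
        else:
            M[ti, C] += 1
    for j, d in enumerate(strong):
        if not used[j]:
            M[C, idx[d.category_id]] += 1
    if normalize:
        sums = M.sum(axis=1, keepdims=True)
        M = np.divide(M, sums, out=np.zeros_like(M), where=sums > 0)
    return M


def published_ap_table() -> pd.DataFrame:
    """Per-class AP values published for the PestDet20 benchmark
    (columns: method, shot, class_id, ap; AP on the 0-100 scale)."""
    ref = resources.files("pestfsod").joinpath("data/pestdet20_per_class_ap.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def write_results_json(dets_by_image: dict[int, list], path: str | Path) -> None:
    """COCO results format (category ids written 1-based, bbox xywh)."""
    out = []
    for img_id in sorted(dets_by_image):
        for d in dets_by_image[img_id]:
            x1, y1, x2, y2 = [float(v) for v in d.box]
            out.append(
                {"image_id": int(img_id), "category_id": int(d.category_id) + 1,
                 "bbox": [x1, y1, x2 - x1, y2 - y1], "score": float(d.score)}
            )
    Path(path).write_text(json.dumps(out, indent=1))


def read_results_json(path: str | Path) -> dict[int, list]:
    from .detector import Detection

    by_img: dict[int, list] = {}
    for r in json.loads(Path(path).read_text()):
        x, y, w, h = r["bbox"]
        det = Detection(
            image_id=r["image_id"],
            box=np.array([x, y, x + w, y + h]),
            category_id=r["category_id"] - 1,
            score=r["score"],
        )
        by_img.setdefault(r["image_id"], []).append(det)
    return by_img
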