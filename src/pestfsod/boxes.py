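"""Axis-aligned bounding-box containers and geometry.

Boxes are stored COCO-style as ``(x, y, w, h)`` in pixel units (0-based,
floats).  All geometric computations convert internally to corner form
``(x1, y1, x2, y2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoxSet",
    "xywh_to_xyxy",
    "xyxy_to_xywh",
    "iou_matrix",
    "nms",
    "encode_deltas",
    "decode_deltas",
]


def xywh_to_xyxy(boxes: np.ndarray) -> np.ndarray:
    """Convert (N, 4) boxes from (x, y, w, h) to (x1, y1, x2, y2)."""
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    out = boxes.copy()
    out[:, 2] = boxes[:, 0] + boxes[:, 2]
    out[:, 3] = boxes[:, 1] + boxes[:, 3]
    return out


def xyxy_to_xywh(boxes: np.ndarray) -> np.ndarray:
    """Convert (N, 4) boxes from (x1, y1, x2, y2) to (x, y, w, h)."""
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    out = boxes.copy()
    out[:, 2] = boxes[:, 2] - boxes[:, 0]
    out[:, 3] = boxes[:, 3] - boxes[:, 1]
    return out


def iou_matrix(a_xyxy: np.ndarray, b_xyxy: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union between two corner-form box sets.

    Degenerate (zero-area) boxes get IoU 0 against everything (with a
    warning), matching the evaluation convention.
    """
    a = np.asarray(a_xyxy, dtype=float).reshape(-1, 4)
    b = np.asarray(b_xyxy, dtype=float).reshape(-1, 4)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    if (a.size and (area_a == 0).any()) or (b.size and (area_b == 0).any()):
        warnings.warn("zero-area box encountered; IoU set to 0", stacklevel=2)
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return iou


def nms(boxes_xyxy: np.ndarray, scores: np.ndarray, iou_thr: float = 0.5) -> np.ndarray:
    """Greedy non-maximum suppression; returns indices of kept boxes.

    Ties in score are broken by original index (lower index wins), making
    the result deterministic.
    """
    boxes_xyxy = np.asarray(boxes_xyxy, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float).ravel()
    order = np.lexsort((np.arange(len(scores)), -scores))
    keep: list[int] = []
    suppressed = np.zeros(len(scores), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        iou = iou_matrix(boxes_xyxy, boxes_xyxy)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        suppressed |= iou[i] > iou_thr
    return np.array(keep, dtype=int)


def encode_deltas(proposals_xyxy: np.ndarray, gts_xyxy: np.ndarray) -> np.ndarray:
    """Standard (dx, dy, dw, dh) log-space regression targets.

    dx, dy are centre offsets normalised by the proposal size; dw, dh are
    log size ratios.  Inverse of :func:`decode_deltas`.
    """
    p = np.asarray(proposals_xyxy, dtype=float).reshape(-1, 4)
    g = np.asarray(gts_xyxy, dtype=float).reshape(-1, 4)
    pw = np.clip(p[:, 2] - p[:, 0], 1e-6, None)
    ph = np.clip(p[:, 3] - p[:, 1], 1e-6, None)
    px = p[:, 0] + 0.5 * pw
    py = p[:, 1] + 0.5 * ph
    gw = np.clip(g[:, 2] - g[:, 0], 1e-6, None)
    gh = np.clip(g[:, 3] - g[:, 1], 1e-6, None)
    gx = g[:, 0] + 0.5 * gw
    gy = g[:, 1] + 0.5 * gh
    return np.stack(
        [(gx - px) / pw, (gy - py) / ph, np.log(gw / pw), np.log(gh / ph)], axis=1
    )


def decode_deltas(proposals_xyxy: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    p = np.asarray(proposals_xyxy, dtype=float).reshape(-1, 4)
    d = np.asarray(deltas, dtype=float).reshape(-1, 4)
    pw = np.clip(p[:, 2] - p[:, 0], 1e-6, None)
    ph = np.clip(p[:, 3] - p[:, 1], 1e-6, None)
    px = p[:, 0] + 0.5 * pw
    py = p[:, 1] + 0.5 * ph
    cx = px + d[:, 0] * pw
    cy = py + d[:, 1] * ph
    w = pw * np.exp(np.clip(d[:, 2], -8, 8))
    h = ph * np.exp(np.clip(d[:, 3], -8, 8))
    return np.stack([cx - 0.5 * w, cy - 0.5 * h, cx + 0.5 * w, cy + 0.5 * h], axis=1)


@dataclass
class BoxSet:
    """Per-image instances: boxes (COCO xywh), labels, optional scores."""

    boxes: np.ndarray  # (N, 4) float, (x, y, w, h)
    labels: np.ndarray  # (N,) int category ids
    scores: np.ndarray | None = None  # (N,) float in [0, 1]
    image_id: int | None = None

    def __post_init__(self) -> None:
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if len(self.boxes) != len(self.labels):
            raise ValueError("boxes and labels length mismatch")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float).ravel()
            if len(self.scores) != len(self.boxes):
                raise ValueError("scores length mismatch")
            if self.scores.size and (
                self.scores.min() < 0 or self.scores.max() > 1
            ):
                raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.boxes)

    @property
    def xyxy(self) -> np.ndarray:
        return xywh_to_xyxy(self.boxes)

    @classmethod
    def empty(cls, image_id: int | None = None) -> "BoxSet":
        return cls(np.zeros((0, 4)), np.zeros(0, dtype=int), image_id=image_id)

    def select(self, idx) -> "BoxSet":
        idx = np.asarray(idx)
        return BoxSet(
            self.boxes[idx],
            self.labels[idx],
            None if self.scores is None else self.scores[idx],
            image_id=self.image_id,
        )
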