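"""Base/novel class splits and K-shot fine-tuning set construction.

A few-shot detection episode starts from a class split (base classes with
abundant data, novel classes with only K shots) and a K-shot sample: for
every class, K training images that contain at least one instance of it.
The three published 15/5 splits of the PestDet20 benchmark ship as
packaged YAML fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .synthetic_scenes import DatasetManifest

__all__ = ["ClassSplit", "ShotConfig", "make_split", "sample_kshot", "load_split",
           "packaged_split", "LAMBDA2_BY_SHOT", "IOU_POS_BY_SHOT"]

# Published shot-dependent hyperparameters: positive-sample IoU threshold
# and contrastive-loss weight for 3/5/10-shot fine-tuning.
IOU_POS_BY_SHOT: dict[int, float] = {3: 0.6, 5: 0.7, 10: 0.8}
LAMBDA2_BY_SHOT: dict[int, float] = {3: 0.2, 5: 0.5, 10: 0.5}


@dataclass
class ClassSplit:
    """An ordered universe of class ids partitioned into base and novel."""

    all_classes: list[int]
    base_classes: list[int]
    novel_classes: list[int]
    seed: int | None = None

    def __post_init__(self):
        a, b, n = map(list, (self.all_classes, self.base_classes, self.novel_classes))
        if len(set(a)) != len(a):
            raise ValueError("duplicate class ids in split")
        if set(b) | set(n) != set(a) or set(b) & set(n):
            raise ValueError("base/novel must partition the class universe")
        if len(b) + len(n) != len(a):
            raise ValueError("split sizes inconsistent")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "all": [int(c) for c in self.all_classes],
                    "base": [int(c) for c in self.base_classes],
                    "novel": [int(c) for c in self.novel_classes],
                    "seed": self.seed,
                },
                fh,
                sort_keys=False,
            )


@dataclass
class ShotConfig:
    """Shot-dependent fine-tuning knobs.

    K is the number of support images per class; ``iou_pos_threshold``
    gates which RoIs count as positives (0.6/0.7/0.8 for 3/5/10 shots);
    ``tau`` is the contrastive temperature (0.2 for all shots); lambda1
    and lambda2 weight the aggregation regulariser and contrastive loss.
    """

    K: int
    iou_pos_threshold: float | None = None
    tau: float = 0.2
    lambda1: float = 0.5
    lambda2: float | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.iou_pos_threshold is None:
            self.iou_pos_threshold = IOU_POS_BY_SHOT.get(self.K, 0.6)
        if self.lambda2 is None:
            self.lambda2 = LAMBDA2_BY_SHOT.get(self.K, 0.5)
        if not (0 < self.iou_pos_threshold < 1):
            raise ValueError("iou_pos_threshold must lie in (0, 1)")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


def make_split(class_ids: list[int], n_base: int, seed: int) -> ClassSplit:
    """Deterministic shuffle of the class universe; first ``n_base`` are base."""
    ids = [int(c) for c in class_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate class ids")
    if not (0 < n_base < len(ids)):
        raise ValueError("n_base must be in (0, n_classes)")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    return ClassSplit(order, order[:n_base], order[n_base:], seed=seed)


def load_split(path: str | Path) -> ClassSplit:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ClassSplit(d["all"], d["base"], d["novel"], seed=d.get("seed"))


def packaged_split(index: int) -> ClassSplit:
    """Load one of the three published PestDet20 splits (index 1, 2 or 3)."""
    ref = resources.files("pestfsod").joinpath(f"data/splits/split{index}.yaml")
    with resources.as_file(ref) as path:
        return load_split(path)


def sample_kshot(
    manifest: DatasetManifest,
    split: ClassSplit,
    K: int,
    seed: int,
) -> DatasetManifest:
    """Select K support images per class (base and novel alike).

    For each class in the split, K images containing at least one instance
    of that class are drawn without replacement (all of them, with a
    warning, if fewer than K exist).  Images shared between classes are
    included once; the result carries all annotations of the selected
    images.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {c: [] for c in split.all_classes}
    seen: dict[int, set[int]] = {c: set() for c in split.all_classes}
    for a in manifest.annotations:
        c = a["category_id"]
        if c in by_class and a["image_id"] not in seen[c]:
            by_class[c].append(a["image_id"])
            seen[c].add(a["image_id"])
    chosen: set[int] = set()
    for c in split.base_classes + split.novel_classes:
        imgs = sorted(by_class[c])
        if not imgs:
            raise ValueError(f"class {c} has no images in the manifest")
        if len(imgs) < K:
            warnings.warn(
                f"class {c} has only {len(imgs)} images (< K={K}); taking all",
                stacklevel=2,
            )
            chosen.update(imgs)
        else:
            pick = rng.choice(len(imgs), size=K, replace=False)
            chosen.update(imgs[i] for i in pick)
    return DatasetManifest(
        images=[im for im in manifest.images if im["id"] in chosen],
        annotations=[a for a in manifest.annotations if a["image_id"] in chosen],
        categories=[dict(c) for c in manifest.categories],
        pixels={k: v for k, v in manifest.pixels.items() if k in chosen},
        root=manifest.root,
    )
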