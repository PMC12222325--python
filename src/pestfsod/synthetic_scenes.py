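"""Procedural detection-scene generator with pest-benchmark statistics.

Renders cluttered scenes of small, multi-scale procedural "pests"
(ellipses, rectangles, triangles, star-convex blobs with per-class colour
and texture signatures) on textured backgrounds, and writes them as PNG
images with COCO JSON annotations.  The default 20-class image-count
profile mirrors the published PestDet20 benchmark (92-400 training images
per class, heavy class imbalance), so the full few-shot pipeline can be
exercised without the original photographs.
"""

from __future__ import annotations

import json
import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxes import BoxSet, iou_matrix, xywh_to_xyxy

__all__ = [
    "SceneSpec",
    "ShapeStyle",
    "Background",
    "DatasetManifest",
    "generate_scene",
    "generate_dataset",
    "split_train_test",
    "auto_palette",
    "PESTDET20_CLASSES",
    "PESTDET20_TRAIN_IMAGES",
    "PESTDET20_TEST_IMAGES",
    "PESTDET20_TRAIN_BOXES",
    "PESTDET20_TEST_BOXES",
    "pestdet20_profile",
]

# Published per-class statistics of the PestDet20 benchmark
# (class id -> name; train/test image and annotation-box counts).
PESTDET20_CLASSES: dict[int, str] = {
    0: "rice leaf roller", 3: "rice stem borer", 14: "grub", 15: "mole cricket",
    16: "wireworm", 21: "red spider", 24: "aphid", 25: "white-spotted flower beetle",
    26: "peach borer", 37: "flea beetle", 39: "beet armyworm", 48: "acridoidea",
    50: "blister beetle", 66: "grape hawkmoth", 67: "cicada", 70: "lycophoridae",
    76: "cotton scale", 95: "brown-margined moth", 99: "spine-chested longhorn beetle",
    101: "cicadidae",
}
PESTDET20_TRAIN_IMAGES: dict[int, int] = {
    0: 131, 3: 126, 14: 331, 15: 400, 16: 325, 21: 125, 24: 400, 25: 145,
    26: 188, 37: 253, 39: 317, 48: 400, 50: 338, 66: 197, 67: 253, 70: 400,
    76: 121, 95: 134, 99: 92, 101: 400,
}
PESTDET20_TEST_IMAGES: dict[int, int] = {
    0: 34, 3: 33, 14: 80, 15: 80, 16: 80, 21: 31, 24: 80, 25: 40, 26: 45,
    37: 65, 39: 81, 48: 80, 50: 85, 66: 53, 67: 63, 70: 80, 76: 28, 95: 33,
    99: 26, 101: 80,
}
PESTDET20_TRAIN_BOXES: dict[int, int] = {
    0: 141, 3: 138, 14: 532, 15: 400, 16: 405, 21: 128, 24: 400, 25: 173,
    26: 199, 37: 285, 39: 322, 48: 400, 50: 366, 66: 197, 67: 253, 70: 400,
    76: 216, 95: 142, 99: 93, 101: 400,
}
PESTDET20_TEST_BOXES: dict[int, int] = {
    0: 38, 3: 34, 14: 108, 15: 80, 16: 104, 21: 36, 24: 80, 25: 46, 26: 47,
    37: 70, 39: 81, 48: 80, 50: 94, 66: 53, 67: 63, 70: 80, 76: 55, 95: 36,
    99: 27, 101: 80,
}


def pestdet20_profile(scale: float = 1.0) -> dict[int, int]:
    """Per-class training-image counts scaled from the published profile.

    Counts are rounded (numpy half-to-even); at scale 0.1 the total lands
    within a couple of images of a tenth of the full 5076.
    """
    return {c: int(np.round(n * scale)) for c, n in PESTDET20_TRAIN_IMAGES.items()}


_SHAPES = ("ellipse", "rectangle", "triangle", "blob")


@dataclass
class ShapeStyle:
    """Per-class procedural appearance: base shape, colour, texture."""

    base: str = "ellipse"
    color: tuple[float, float, float] = (0.8, 0.2, 0.2)  # RGB in [0, 1]
    texture_amp: float = 0.12
    aspect_range: tuple[float, float] = (0.65, 1.0)

    def __post_init__(self):
        if self.base not in _SHAPES:
            raise ValueError(f"unknown base shape {self.base!r}")


def _hsv_to_rgb(h: float, s: float, v: float) -> tuple[float, float, float]:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    return [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]


def auto_palette(n_classes: int) -> list[ShapeStyle]:
    """Deterministic palette: evenly spaced hues, cycling base shapes."""
    styles = []
    for i in range(n_classes):
        hue = (i / n_classes + 0.03 * (i % 3)) % 1.0
        styles.append(
            ShapeStyle(
                base=_SHAPES[i % len(_SHAPES)],
                color=_hsv_to_rgb(hue, 0.85, 0.9),
                texture_amp=0.10 + 0.04 * ((i // len(_SHAPES)) % 3),
            )
        )
    return styles


@dataclass
class Background:
    """Low-frequency textured background: base colour + smooth noise."""

    color: tuple[float, float, float] = (0.42, 0.48, 0.33)  # foliage-ish
    noise_amp: float = 0.12
    noise_cells: int = 6  # low-res noise grid upsampled to image size


@dataclass
class SceneSpec:
    """Configuration of the procedural scene generator."""

    image_size: tuple[int, int] = (128, 128)  # (width, height)
    n_classes: int = 6
    shape_palette: list[ShapeStyle] | None = None
    size_range_px: tuple[int, int] = (10, 40)
    objects_per_image: tuple[int, int] = (1, 3)
    background: Background = field(default_factory=Background)
    overlap_max_iou: float = 0.3
    hard_background: float = 0.0  # blend object colour toward background
    seed: int = 0
    max_place_retries: int = 50

    def __post_init__(self):
        if self.shape_palette is None:
            self.shape_palette = auto_palette(self.n_classes)
        self.validate()

    def validate(self) -> None:
        w, h = self.image_size
        lo, hi = self.size_range_px
        if lo < 4:
            raise ValueError("minimum object size must be >= 4 px")
        if hi > min(w, h):
            raise ValueError("maximum object size exceeds image bounds")
        if not (0 <= self.overlap_max_iou < 1):
            raise ValueError("overlap_max_iou must lie in [0, 1)")
        if len(self.shape_palette) != self.n_classes:
            raise ValueError("palette length must equal n_classes")
        if not (0 <= self.hard_background <= 1):
            raise ValueError("hard_background must lie in [0, 1]")
        a, b = self.objects_per_image
        if a < 0 or b < a:
            raise ValueError("objects_per_image must be a non-negative range")


def _smooth_noise(rng: np.random.Generator, hw: tuple[int, int], cells: int) -> np.ndarray:
    """Bilinear-upsampled low-resolution noise field in [-1, 1]."""
    H, W = hw
    grid = rng.uniform(-1, 1, size=(cells + 1, cells + 1))
    ys = np.linspace(0, cells, H)
    xs = np.linspace(0, cells, W)
    y0 = np.minimum(ys.astype(int), cells - 1)
    x0 = np.minimum(xs.astype(int), cells - 1)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    g = grid
    return (
        g[y0[:, None], x0[None, :]] * (1 - fy) * (1 - fx)
        + g[y0[:, None], x0[None, :] + 1] * (1 - fy) * fx
        + g[y0[:, None] + 1, x0[None, :]] * fy * (1 - fx)
        + g[y0[:, None] + 1, x0[None, :] + 1] * fy * fx
    )


def _shape_mask(style: ShapeStyle, size: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of one object, fitted inside a circle of diameter ``size``."""
    R = size / 2.0
    n = int(math.ceil(size)) + 2
    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = (n - 1) / 2.0
    theta = rng.uniform(0, 2 * math.pi)
    ct, st = math.cos(theta), math.sin(theta)
    x = (xx - cx) * ct + (yy - cy) * st
    y = -(xx - cx) * st + (yy - cy) * ct
    aspect = rng.uniform(*style.aspect_range)
    if style.base == "ellipse":
        mask = (x / R) ** 2 + (y / (R * aspect)) ** 2 <= 1.0
    elif style.base == "rectangle":
        # half-diagonal R so the rotated box stays inside the circle
        a = R / math.hypot(1.0, aspect)
        mask = (np.abs(x) <= a) & (np.abs(y) <= a * aspect)
    elif style.base == "triangle":
        angles = theta + np.array([0.0, 2 * math.pi / 3, 4 * math.pi / 3])
        vx = cx + R * np.cos(angles)
        vy = cy + R * np.sin(angles)
        mask = np.ones((n, n), dtype=bool)
        for i in range(3):
            x1, y1 = vx[i], vy[i]
            x2, y2 = vx[(i + 1) % 3], vy[(i + 1) % 3]
            cross = (x2 - x1) * (yy - y1) - (y2 - y1) * (xx - x1)
            mask &= cross >= 0
    else:  # blob: star-convex radial perturbation, radius in [0.8R, R]
        k = rng.integers(3, 6)
        phi = rng.uniform(0, 2 * math.pi)
        ang = np.arctan2(y, x)
        r_lim = R * (0.8 + 0.2 * (0.5 + 0.5 * np.sin(k * ang + phi)))
        mask = np.hypot(x, y) <= r_lim
    return mask


def generate_scene(
    spec: SceneSpec,
    class_quota: dict[int, int] | np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, BoxSet]:
    """Render one scene containing ``class_quota[c]`` objects of class c.

    Placement uses rejection sampling (``spec.max_place_retries`` tries per
    object) so pairwise same-image IoU stays at or below
    ``spec.overlap_max_iou``; infeasible objects are skipped with a warning.

    Returns the HxWx3 uint8 image and a :class:`BoxSet` with one tight box
    per rendered object (class indices 0..n_classes-1).
    """
    if isinstance(class_quota, dict):
        quota_items = [(c, int(n)) for c, n in sorted(class_quota.items())]
    else:
        quota_items = list(enumerate(np.asarray(class_quota, dtype=int)))
    if any(n < 0 for _, n in quota_items):
        raise ValueError("class quotas must be non-negative")
    W, H = spec.image_size
    bg = spec.background
    img = np.empty((H, W, 3))
    base = np.asarray(bg.color)
    noise = _smooth_noise(rng, (H, W), bg.noise_cells)
    for ch in range(3):
        img[:, :, ch] = base[ch] * (1.0 + bg.noise_amp * noise)
    img += 0.02 * rng.standard_normal((H, W, 3))

    order: list[int] = []
    for c, n in quota_items:
        order.extend([c] * n)
    rng.shuffle(order)

    placed_xyxy: list[np.ndarray] = []
    boxes: list[np.ndarray] = []
    labels: list[int] = []
    for c in order:
        style = spec.shape_palette[c]
        lo, hi = spec.size_range_px
        placed = False
        for _ in range(spec.max_place_retries):
            size = rng.uniform(lo, hi)
            mask = _shape_mask(style, size, rng)
            rows = np.flatnonzero(mask.any(axis=1))
            cols = np.flatnonzero(mask.any(axis=0))
            mh = rows[-1] - rows[0] + 1
            mw = cols[-1] - cols[0] + 1
            if mw > W or mh > H:
                continue
            x0 = int(rng.integers(0, W - mw + 1))
            y0 = int(rng.integers(0, H - mh + 1))
            cand = np.array([x0, y0, x0 + mw, y0 + mh], dtype=float)
            if placed_xyxy:
                ious = iou_matrix(cand[None, :], np.stack(placed_xyxy))
                if ious.max() > spec.overlap_max_iou:
                    continue
            tight = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
            color = np.asarray(style.color)
            if spec.hard_background > 0:
                color = (1 - spec.hard_background) * color + spec.hard_background * base
            tex = style.texture_amp * rng.standard_normal(tight.shape)
            patch = img[y0 : y0 + mh, x0 : x0 + mw]
            shade = np.clip(color[None, None, :] * (1.0 + tex[:, :, None]), 0, 1)
            patch[tight] = shade[tight]
            placed_xyxy.append(cand)
            boxes.append(np.array([x0, y0, mw, mh], dtype=float))
            labels.append(c)
            placed = True
            break
        if not placed:
            warnings.warn(
                f"could not place object of class {c} after "
                f"{spec.max_place_retries} retries; skipping",
                stacklevel=2,
            )
    img8 = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    if boxes:
        bset = BoxSet(np.stack(boxes), np.asarray(labels))
    else:
        bset = BoxSet.empty()
    return img8, bset


# ---------------------------------------------------------------------------
# Dataset manifest and COCO I/O
# ---------------------------------------------------------------------------


@dataclass
class DatasetManifest:
    """A detection dataset: images, annotations, categories, count table.

    ``images``: list of dicts (id, file_name, width, height);
    ``annotations``: list of dicts (id, image_id, category_id, bbox xywh);
    ``categories``: list of dicts (id, name) with 0-based internal ids;
    ``per_class_counts``: category id -> (n_images, n_boxes).
    ``pixels`` optionally holds in-memory image arrays keyed by image id
    (used when no directory is written).
    """

    images: list[dict]
    annotations: list[dict]
    categories: list[dict]
    per_class_counts: dict[int, tuple[int, int]] = field(default_factory=dict)
    pixels: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    root: Path | None = None

    def __post_init__(self):
        if not self.per_class_counts:
            self.per_class_counts = self.recount()

    def recount(self) -> dict[int, tuple[int, int]]:
        """Recompute per-class (image, box) counts from the annotations."""
        counts: dict[int, tuple[set, int]] = {
            c["id"]: (set(), 0) for c in self.categories
        }
        for a in self.annotations:
            s, n = counts[a["category_id"]]
            s.add(a["image_id"])
            counts[a["category_id"]] = (s, n + 1)
        return {c: (len(s), n) for c, (s, n) in counts.items()}

    def validate(self) -> None:
        image_ids = {im["id"] for im in self.images}
        cat_ids = {c["id"] for c in self.categories}
        for a in self.annotations:
            if a["image_id"] not in image_ids:
                raise ValueError(f"annotation {a['id']} references missing image")
            if a["category_id"] not in cat_ids:
                raise ValueError(f"annotation {a['id']} references missing category")
            x, y, w, h = a["bbox"]
            if w <= 0 or h <= 0:
                raise ValueError(f"annotation {a['id']} has non-positive box size")
        if self.per_class_counts != self.recount():
            raise ValueError("per_class_counts inconsistent with annotations")

    @property
    def class_ids(self) -> list[int]:
        return sorted(c["id"] for c in self.categories)

    def n_images(self) -> int:
        return len(self.images)

    def boxset(self, image_id: int) -> BoxSet:
        anns = [a for a in self.annotations if a["image_id"] == image_id]
        if not anns:
            return BoxSet.empty(image_id=image_id)
        return BoxSet(
            np.array([a["bbox"] for a in anns], dtype=float),
            np.array([a["category_id"] for a in anns], dtype=int),
            image_id=image_id,
        )

    def image_array(self, image_id: int) -> np.ndarray:
        if image_id in self.pixels:
            return self.pixels[image_id]
        import imageio.v3 as iio

        rec = next(im for im in self.images if im["id"] == image_id)
        if self.root is None:
            raise ValueError("manifest has no root directory and no in-memory pixels")
        return np.asarray(iio.imread(Path(self.root) / rec["file_name"]))

    # -- COCO JSON (category ids are written 1-based, read back 0-based) --

    def to_coco_dict(self) -> dict:
        return {
            "images": [dict(im) for im in self.images],
            "annotations": [
                {
                    "id": a["id"],
                    "image_id": a["image_id"],
                    "category_id": a["category_id"] + 1,
                    "bbox": [float(v) for v in a["bbox"]],
                    "area": float(a["bbox"][2] * a["bbox"][3]),
                    "iscrowd": 0,
                }
                for a in self.annotations
            ],
            "categories": [
                {"id": c["id"] + 1, "name": c["name"]} for c in self.categories
            ],
        }

    def write_coco(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_coco_dict(), fh, sort_keys=True, indent=1)

    @classmethod
    def from_coco(cls, path: str | Path, root: str | Path | None = None) -> "DatasetManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            images=d["images"],
            annotations=[
                {
                    "id": a["id"],
                    "image_id": a["image_id"],
                    "category_id": a["category_id"] - 1,
                    "bbox": a["bbox"],
                }
                for a in d["annotations"]
            ],
            categories=[
                {"id": c["id"] - 1, "name": c.get("name", str(c["id"] - 1))}
                for c in d["categories"]
            ],
            root=Path(root) if root is not None else Path(path).parent,
        )

    @classmethod
    def from_profile(
        cls,
        image_counts: dict[int, int],
        box_counts: dict[int, int] | None = None,
        names: dict[int, str] | None = None,
    ) -> "DatasetManifest":
        """Skeleton manifest with the requested per-class statistics.

        Builds placeholder image and annotation records (no pixels) so
        count-table arithmetic can be exercised against a stated profile;
        each class's first image absorbs any surplus boxes.
        """
        images, annotations, categories = [], [], []
        img_id, ann_id = 0, 0
        for c in sorted(image_counts):
            n_img = int(image_counts[c])
            n_box = int(box_counts[c]) if box_counts else n_img
            if n_box < n_img:
                raise ValueError(f"class {c}: fewer boxes than images")
            categories.append(
                {"id": c, "name": (names or {}).get(c, f"class_{c}")}
            )
            for j in range(n_img):
                images.append(
                    {"id": img_id, "file_name": f"im_{img_id:06d}.png", "width": 1, "height": 1}
                )
                n_here = 1 + (n_box - n_img if j == 0 else 0)
                for _ in range(n_here):
                    annotations.append(
                        {"id": ann_id, "image_id": img_id, "category_id": c,
                         "bbox": [0.0, 0.0, 1.0, 1.0]}
                    )
                    ann_id += 1
                img_id += 1
        return cls(images=images, annotations=annotations, categories=categories)

    def export_voc(self, out_dir: str | Path) -> None:
        """Write one VOC-style XML annotation file per image."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        names = {c["id"]: c["name"] for c in self.categories}
        for im in self.images:
            root = ET.Element("annotation")
            ET.SubElement(root, "filename").text = im["file_name"]
            size = ET.SubElement(root, "size")
            ET.SubElement(size, "width").text = str(im["width"])
            ET.SubElement(size, "height").text = str(im["height"])
            ET.SubElement(size, "depth").text = "3"
            for a in self.annotations:
                if a["image_id"] != im["id"]:
                    continue
                obj = ET.SubElement(root, "object")
                ET.SubElement(obj, "name").text = names[a["category_id"]]
                bb = ET.SubElement(obj, "bndbox")
                x, y, w, h = a["bbox"]
                ET.SubElement(bb, "xmin").text = str(x)
                ET.SubElement(bb, "ymin").text = str(y)
                ET.SubElement(bb, "xmax").text = str(x + w)
                ET.SubElement(bb, "ymax").text = str(y + h)
            stem = Path(im["file_name"]).stem
            ET.ElementTree(root).write(out_dir / f"{stem}.xml")


def generate_dataset(
    spec: SceneSpec,
    class_profile: dict[int, int] | np.ndarray,
    out_dir: str | Path | None,
    rng: np.random.Generator,
) -> DatasetManifest:
    """Generate a dataset matching a per-class image-count profile.

    Each image contains objects of a single class (count drawn from
    ``spec.objects_per_image``, at least one), so the per-class image
    counts meet the profile exactly and box counts are at least image
    counts.  With ``out_dir=None`` images stay in memory on the manifest.
    """
    if isinstance(class_profile, dict):
        profile = {int(c): int(n) for c, n in sorted(class_profile.items())}
    else:
        profile = dict(enumerate(np.asarray(class_profile, dtype=int)))
    if len(profile) != spec.n_classes:
        raise ValueError("class_profile length must equal spec.n_classes")
    class_list = sorted(profile)
    idx_of = {c: i for i, c in enumerate(class_list)}

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "images").mkdir(exist_ok=True)

    images, annotations = [], []
    pixels: dict[int, np.ndarray] = {}
    img_id, ann_id = 0, 0
    lo, hi = spec.objects_per_image
    W, H = spec.image_size
    for c in class_list:
        for _ in range(profile[c]):
            n_obj = max(1, int(rng.integers(lo, hi + 1)))
            quota = np.zeros(spec.n_classes, dtype=int)
            quota[idx_of[c]] = n_obj
            img, bset = generate_scene(spec, quota, rng)
            fname = f"images/im_{img_id:06d}.png"
            if out_path is not None:
                import imageio.v3 as iio

                iio.imwrite(out_path / fname, img)
            else:
                pixels[img_id] = img
            images.append(
                {"id": img_id, "file_name": fname, "width": W, "height": H}
            )
            for b, lab in zip(bset.boxes, bset.labels):
                annotations.append(
                    {"id": ann_id, "image_id": img_id,
                     "category_id": class_list[int(lab)],
                     "bbox": [float(v) for v in b]}
                )
                ann_id += 1
            img_id += 1
    manifest = DatasetManifest(
        images=images,
        annotations=annotations,
        categories=[{"id": c, "name": f"class_{c}"} for c in class_list],
        pixels=pixels,
        root=out_path,
    )
    if out_path is not None:
        manifest.write_coco(out_path / "annotations.json")
    return manifest


def split_train_test(
    manifest: DatasetManifest, ratio: float, rng: np.random.Generator
) -> tuple[DatasetManifest, DatasetManifest]:
    """Image-level stratified split (per class) at the given train ratio.

    Every image lands with all its annotations on exactly one side; the
    per-class train fraction is within one image of ``ratio``.  Images are
    stratified by their lowest contained class id.  Classes with a single
    image go entirely to the training side (with a warning).
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie strictly between 0 and 1")
    img_class: dict[int, int] = {}
    for a in manifest.annotations:
        c = img_class.get(a["image_id"])
        img_class[a["image_id"]] = a["category_id"] if c is None else min(c, a["category_id"])
    groups: dict[int, list[int]] = {}
    for im in manifest.images:
        key = img_class.get(im["id"], -1)  # background-only images
        groups.setdefault(key, []).append(im["id"])
    train_ids: set[int] = set()
    test_ids: set[int] = set()
    for key in sorted(groups):
        ids = sorted(groups[key])
        if len(ids) < 2:
            if key >= 0:
                warnings.warn(
                    f"class {key} has fewer than 2 images; placing in train",
                    stacklevel=2,
                )
            train_ids.update(ids)
            continue
        perm = rng.permutation(len(ids))
        n_train = int(np.clip(round(ratio * len(ids)), 1, len(ids) - 1))
        for j, p in enumerate(perm):
            (train_ids if j < n_train else test_ids).add(ids[p])

    def subset(keep: set[int]) -> DatasetManifest:
        return DatasetManifest(
            images=[im for im in manifest.images if im["id"] in keep],
            annotations=[a for a in manifest.annotations if a["image_id"] in keep],
            categories=[dict(c) for c in manifest.categories],
            pixels={k: v for k, v in manifest.pixels.items() if k in keep},
            root=manifest.root,
        )

    return subset(train_ids), subset(test_ids)
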