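"""Dataset IO: COCO-dialect manifests, grayscale radiograph loading,
geometric training augmentations and prediction export.

Coordinate convention: pixel units, 0-based, top-left origin, half-open
boxes [x, x+w) x [y, y+h).  Model-space boxes are normalized center format
(cx, cy, w, h) in [0, 1]; the two conversions are exact inverses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .detector import ImageTensor

__all__ = [
    "AnnotationRecord",
    "DatasetManifest",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "load_image",
    "save_image",
    "augment",
    "read_manifest",
    "write_manifest",
    "write_results",
    "read_results",
    "box_xywh_to_normalized",
    "box_normalized_to_xywh",
    "split_dataset",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


class ManifestError(ValueError):
    pass


@dataclass
class AnnotationRecord:
    image_id: int
    category_id: int
    bbox: tuple              # (x, y, w, h) absolute pixels
    group_id: int | None = None

    def __post_init__(self):
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ManifestError(
                f"annotation for image {self.image_id}: nonpositive box "
                f"size {self.bbox}"
            )
        self.bbox = (float(x), float(y), float(w), float(h))


@dataclass
class DatasetManifest:
    images: list             # dicts: id, file, width, height, group_id
    annotations: list        # AnnotationRecord
    categories: dict         # id -> name

    def __post_init__(self):
        ids = {im["id"] for im in self.images}
        for a in self.annotations:
            if a.image_id not in ids:
                raise ManifestError(
                    f"annotation references unknown image_id {a.image_id}"
                )
            if a.category_id not in self.categories:
                raise ManifestError(
                    f"annotation references unknown category_id "
                    f"{a.category_id}"
                )

    def annotations_for(self, image_id: int) -> list:
        return [a for a in self.annotations if a.image_id == image_id]

    def category_histogram(self) -> dict:
        hist = {c: 0 for c in self.categories}
        for a in self.annotations:
            hist[a.category_id] += 1
        return hist


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def load_image(path, mean=IMAGENET_MEAN, std=IMAGENET_STD,
               standardize: bool = True) -> ImageTensor:
    """Load an 8- or 16-bit grayscale PNG/TIFF.

    Pixel values are divided by the dtype maximum into [0, 1], the channel is
    replicated three times, and each channel is standardized with the given
    mean/std.  RGB inputs are converted to luminance with a warning.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        warnings.warn(f"{path}: RGB input converted to grayscale")
        arr = arr.mean(axis=-1).astype(arr.dtype)
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    norm = arr.astype(np.float32) / scale
    chans = np.repeat(norm[None], 3, axis=0)
    if standardize:
        m = np.asarray(mean, dtype=np.float32).reshape(3, 1, 1)
        s = np.asarray(std, dtype=np.float32).reshape(3, 1, 1)
        chans = (chans - m) / s
    return ImageTensor(data=chans, original_size=arr.shape)


def save_image(path, array: np.ndarray, bit_depth: int = 16):
    """Write a [0, 1] float array as 8- or 16-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(array, dtype=np.float64), 0, 1)
    if bit_depth == 16:
        iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))
    elif bit_depth == 8:
        iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))
    else:
        raise ValueError("bit_depth must be 8 or 16")


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------

def _flip_sample(image, boxes):
    w = image.shape[-1]
    out = boxes.copy()
    out[:, 0] = w - boxes[:, 0] - boxes[:, 2]
    return image[..., ::-1].copy(), out


def _resize_sample(image, boxes, new_h, new_w):
    h, w = image.shape[-2:]
    zoom = (new_h / h, new_w / w)
    if image.ndim == 3:
        zoom = (1.0,) + zoom
    resized = ndimage.zoom(image, zoom, order=1)
    sx, sy = new_w / w, new_h / h
    out = boxes * np.array([sx, sy, sx, sy], dtype=np.float32)
    return resized, out


def _crop_sample(image, boxes, labels, y0, x0, ch, cw):
    img = image[..., y0:y0 + ch, x0:x0 + cw]
    out, keep = [], []
    for i, (x, y, w, h) in enumerate(boxes):
        nx0 = max(x - x0, 0.0)
        ny0 = max(y - y0, 0.0)
        nx1 = min(x + w - x0, float(cw))
        ny1 = min(y + h - y0, float(ch))
        if nx1 - nx0 > 0 and ny1 - ny0 > 0:
            out.append((nx0, ny0, nx1 - nx0, ny1 - ny0))
            keep.append(i)
    out = (np.array(out, dtype=np.float32) if out
           else np.zeros((0, 4), dtype=np.float32))
    return img, out, labels[keep]


def augment(sample: dict, ops: dict | None = None,
            seed: int | np.random.Generator = 0) -> dict:
    """Apply training augmentations to a sample dict.

    sample: {"image": (.., H, W) array, "boxes": (G, 4) pixel xywh,
    "labels": (G,)}.  ops keys (all optional):
      hflip: probability of horizontal flip (default 0.5)
      resize_shorter: list of shorter-side targets (default 480..800 step 32)
      max_size: longest-side cap (default 1333)
      crop: (min, max) absolute crop-size range, applied with prob 0.5
    Deterministic under ``seed``.  Boxes are clipped to the image; boxes with
    zero remaining area are dropped.
    """
    ops = dict(ops or {})
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    image = np.asarray(sample["image"], dtype=np.float32)
    boxes = np.asarray(sample["boxes"], dtype=np.float32).reshape(-1, 4)
    labels = np.asarray(sample.get("labels", np.zeros(len(boxes))),
                        dtype=np.int64)
    if rng.random() < ops.get("hflip", 0.5):
        image, boxes = _flip_sample(image, boxes)
    crop_range = ops.get("crop")
    if crop_range and rng.random() < 0.5:
        h, w = image.shape[-2:]
        ch = int(rng.integers(min(crop_range[0], h), min(crop_range[1], h) + 1))
        cw = int(rng.integers(min(crop_range[0], w), min(crop_range[1], w) + 1))
        y0 = int(rng.integers(0, h - ch + 1))
        x0 = int(rng.integers(0, w - cw + 1))
        image, boxes, labels = _crop_sample(image, boxes, labels, y0, x0, ch, cw)
    shorter = ops.get("resize_shorter")
    if shorter:
        h, w = image.shape[-2:]
        target = int(rng.choice(shorter))
        scale = target / min(h, w)
        cap = ops.get("max_size", 1333)
        if max(h, w) * scale > cap:
            scale = cap / max(h, w)
        image, boxes = _resize_sample(image, boxes,
                                      max(1, round(h * scale)),
                                      max(1, round(w * scale)))
    return {"image": image, "boxes": boxes, "labels": labels}


# ---------------------------------------------------------------------------
# Box conversions
# ---------------------------------------------------------------------------

def box_xywh_to_normalized(box, width: int, height: int) -> np.ndarray:
    """Pixel (x, y, w, h) -> normalized (cx, cy, w, h)."""
    x, y, w, h = np.asarray(box, dtype=np.float64)
    return np.array([(x + w / 2) / width, (y + h / 2) / height,
                     w / width, h / height], dtype=np.float64)


def box_normalized_to_xywh(box, width: int, height: int) -> np.ndarray:
    """Normalized (cx, cy, w, h) -> pixel (x, y, w, h)."""
    cx, cy, w, h = np.asarray(box, dtype=np.float64)
    return np.array([cx * width - w * width / 2, cy * height - h * height / 2,
                     w * width, h * height], dtype=np.float64)


# ---------------------------------------------------------------------------
# Manifests and results
# ---------------------------------------------------------------------------

def read_manifest(path) -> DatasetManifest:
    """Read a COCO instances JSON file; tolerates missing optional fields."""
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("images", "annotations", "categories"):
        if key not in raw:
            raise ManifestError(f"$.{key}: missing required section")
    images = []
    for i, im in enumerate(raw["images"]):
        for req in ("id", "width", "height"):
            if req not in im:
                raise ManifestError(f"$.images[{i}].{req}: missing field")
        images.append({"id": im["id"],
                       "file": im.get("file_name", ""),
                       "width": im["width"], "height": im["height"],
                       "group_id": im.get("group_id")})
    categories = {}
    for i, c in enumerate(raw["categories"]):
        if "id" not in c:
            raise ManifestError(f"$.categories[{i}].id: missing field")
        categories[c["id"]] = c.get("name", str(c["id"]))
    annotations = []
    for i, a in enumerate(raw["annotations"]):
        for req in ("image_id", "category_id", "bbox"):
            if req not in a:
                raise ManifestError(f"$.annotations[{i}].{req}: missing field")
        annotations.append(AnnotationRecord(
            image_id=a["image_id"], category_id=a["category_id"],
            bbox=tuple(a["bbox"]), group_id=a.get("group_id")))
    return DatasetManifest(images=images, annotations=annotations,
                           categories=categories)


def write_manifest(manifest: DatasetManifest, path):
    raw = {
        "images": [{"id": im["id"], "file_name": im["file"],
                    "width": im["width"], "height": im["height"],
                    **({"group_id": im["group_id"]}
                       if im.get("group_id") is not None else {})}
                   for im in manifest.images],
        "annotations": [{"id": i, "image_id": a.image_id,
                         "category_id": a.category_id,
                         "bbox": list(a.bbox),
                         "area": a.bbox[2] * a.bbox[3],
                         "iscrowd": 0,
                         **({"group_id": a.group_id}
                            if a.group_id is not None else {})}
                        for i, a in enumerate(manifest.annotations)],
        "categories": [{"id": cid, "name": name}
                       for cid, name in sorted(manifest.categories.items())],
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1)


def write_results(records: list, path):
    """Write detections as a COCO results array."""
    payload = [r.to_json() if hasattr(r, "to_json") else dict(r)
               for r in records]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_results(path) -> list:
    with open(path) as fh:
        raw = json.load(fh)
    for i, r in enumerate(raw):
        for req in ("image_id", "category_id", "bbox", "score"):
            if req not in r:
                raise ManifestError(f"$[{i}].{req}: missing field")
    return raw


def split_dataset(manifest: DatasetManifest, test_fraction: float = 0.15,
                  seed: int = 0, group_aware: bool = False):
    """Random train/test split at image level (default 85/15).

    With ``group_aware`` the split is at group (patient) level so no group
    spans both sides; the default matches plain image-level splitting.
    """
    rng = np.random.default_rng(seed)
    if group_aware:
        groups = sorted({im.get("group_id") for im in manifest.images})
        perm = rng.permutation(len(groups))
        n_test = int(round(len(groups) * test_fraction))
        test_groups = {groups[i] for i in perm[:n_test]}
        test_ids = {im["id"] for im in manifest.images
                    if im.get("group_id") in test_groups}
    else:
        ids = [im["id"] for im in manifest.images]
        perm = rng.permutation(len(ids))
        n_test = int(round(len(ids) * test_fraction))
        test_ids = {ids[i] for i in perm[:n_test]}
    def subset(keep):
        return DatasetManifest(
            images=[im for im in manifest.images if (im["id"] in keep)],
            annotations=[a for a in manifest.annotations
                         if (a.image_id in keep)],
            categories=dict(manifest.categories))
    train_ids = {im["id"] for im in manifest.images} - test_ids
    return subset(train_ids), subset(test_ids)
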