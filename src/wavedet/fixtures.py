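"""Synthetic radiograph-like detection fixtures.

Generates grayscale images that mimic the statistics a wrist X-ray detector
is trained on at desk scale: a dark, noisy background with a handful of
bright, anti-aliased shapes (bars, ellipses, rings, striped "text" blocks),
strong class imbalance presets, optional deliberately overlapping same-class
pairs, and a synthetic patient grouping over images.  Everything is
reproducible from the spec's seed; no download, no binary assets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import AnnotationRecord, DatasetManifest, save_image

__all__ = [
    "FixtureSpec",
    "generate",
    "easy_preset",
    "imbalance_preset",
    "overlap_preset",
]

SHAPE_FAMILIES = ("bar", "ellipse", "ring", "block")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic detection dataset.

    category weights must sum to 1; ``shape_for_class`` cycles through the
    shape families when longer than its explicit entries.  ``overlap_fraction``
    is the probability that an object receives a strongly overlapping
    same-class twin.  ``images_per_group`` emulates multiple images per
    patient for the leakage audit.
    """

    n_images: int = 100
    image_size: tuple = (64, 64)
    categories: list = field(default_factory=lambda: ["bar", "ellipse"])
    weights: list = field(default_factory=lambda: [0.5, 0.5])
    objects_per_image: tuple = (1, 2)
    size_range: tuple = (14, 28)
    intensity_range: tuple = (0.65, 0.95)
    background_level: float = 0.10
    noise_sd: float = 0.02
    overlap_fraction: float = 0.0
    images_per_group: int = 3
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"category weights must sum to 1, got {w.sum()}")
        if len(self.weights) != len(self.categories):
            raise ValueError("categories/weights length mismatch")

    def shape_for_class(self, class_index: int) -> str:
        return SHAPE_FAMILIES[class_index % len(SHAPE_FAMILIES)]


def _render_shape(kind: str, h: int, w: int, cy: float, cx: float,
                  sy: float, sx: float) -> tuple:
    """Render one anti-aliased shape; returns (mask in [0,1], tight box)."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    aa = 0.8   # soft-edge width in pixels
    if kind == "bar":
        dx = np.abs(xx - cx) - sx / 2
        dy = np.abs(yy - cy) - sy / 4        # bars are wide and flat
        mask = np.clip(1 - np.maximum(dx, dy) / aa, 0, 1)
        box = (cx - sx / 2, cy - sy / 4, sx, sy / 2)
    elif kind == "ellipse":
        r = np.sqrt(((xx - cx) / (sx / 2)) ** 2 + ((yy - cy) / (sy / 2)) ** 2)
        mask = np.clip((1 - r) * (sx / 2) / aa + 1, 0, 1) * (r < 1.2)
        box = (cx - sx / 2, cy - sy / 2, sx, sy)
    elif kind == "ring":
        r = np.sqrt(((xx - cx) / (sx / 2)) ** 2 + ((yy - cy) / (sy / 2)) ** 2)
        band = np.abs(r - 0.75)
        mask = np.clip((0.25 - band) * (sx / 2) / aa, 0, 1)
        box = (cx - sx / 2, cy - sy / 2, sx, sy)
    elif kind == "block":
        dx = np.abs(xx - cx) - sx / 2
        dy = np.abs(yy - cy) - sy / 2
        rect = np.clip(1 - np.maximum(dx, dy) / aa, 0, 1)
        stripes = 0.55 + 0.45 * np.cos(yy * np.pi)   # text-like line pattern
        mask = rect * stripes
        box = (cx - sx / 2, cy - sy / 2, sx, sy)
    else:
        raise ValueError(f"unknown shape family {kind!r}")
    return mask, box


def _clip_box(box, h, w):
    x, y, bw, bh = box
    x0, y0 = max(x, 0.0), max(y, 0.0)
    x1, y1 = min(x + bw, float(w)), min(y + bh, float(h))
    return (x0, y0, x1 - x0, y1 - y0)


def generate(spec: FixtureSpec, out_dir=None):
    """Generate a dataset: returns (manifest, images) where ``images`` maps
    image_id -> float array in [0, 1].  If ``out_dir`` is given, 16-bit (or
    8-bit) grayscale PNGs are written there and referenced by the manifest."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    images_meta, annotations, arrays = [], [], {}
    class_ids = np.arange(len(spec.categories))
    for i in range(spec.n_images):
        img = np.full((h, w), spec.background_level, dtype=np.float32)
        img += rng.normal(0, spec.noise_sd, (h, w)).astype(np.float32)
        n_obj = int(rng.integers(spec.objects_per_image[0],
                                 spec.objects_per_image[1] + 1))
        placed = []
        for _ in range(n_obj):
            cls = int(rng.choice(class_ids, p=spec.weights))
            size = rng.uniform(*spec.size_range)
            aspect = rng.uniform(0.7, 1.4)
            sy, sx = size * aspect, size
            cy = rng.uniform(sy / 2 + 1, h - sy / 2 - 1)
            cx = rng.uniform(sx / 2 + 1, w - sx / 2 - 1)
            placed.append((cls, cy, cx, sy, sx))
            if rng.random() < spec.overlap_fraction:
                # strongly overlapping same-class twin
                placed.append((cls, cy + rng.uniform(-0.2, 0.2) * sy,
                               cx + rng.uniform(-0.2, 0.2) * sx, sy, sx))
        for cls, cy, cx, sy, sx in placed:
            kind = spec.shape_for_class(cls)
            mask, _ = _render_shape(kind, h, w, cy, cx, sy, sx)
            intensity = rng.uniform(*spec.intensity_range)
            img = np.maximum(img, mask * intensity)
            # tight box of the shape's own support (half-intensity level set)
            ys, xs = np.where(mask > 0.5)
            if len(ys) == 0:
                continue
            bbox = (float(xs.min()), float(ys.min()),
                    float(xs.max() - xs.min() + 1),
                    float(ys.max() - ys.min() + 1))
            annotations.append(AnnotationRecord(
                image_id=i, category_id=int(cls),
                bbox=_clip_box(bbox, h, w),
                group_id=i // spec.images_per_group))
        img = np.clip(img, 0, 1)
        # quantize to the target bit depth so on-disk and in-memory agree
        levels = 65535 if spec.bit_depth == 16 else 255
        img = np.round(img * levels) / levels
        arrays[i] = img.astype(np.float32)
        images_meta.append({"id": i, "file": f"img_{i:05d}.png",
                            "width": w, "height": h,
                            "group_id": i // spec.images_per_group})
    manifest = DatasetManifest(
        images=images_meta, annotations=annotations,
        categories={int(c): name for c, name in enumerate(spec.categories)})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, arr in arrays.items():
            save_image(out_dir / f"img_{i:05d}.png", arr,
                       bit_depth=spec.bit_depth)
    return manifest, arrays


def easy_preset(n_images: int = 200, seed: int = 0) -> FixtureSpec:
    """Two well-separated classes (bars vs ellipses), low noise, large
    bright shapes: the smoke-training task."""
    return FixtureSpec(
        n_images=n_images, image_size=(64, 64),
        categories=["bar", "ellipse"], weights=[0.5, 0.5],
        objects_per_image=(1, 2), size_range=(16, 28),
        intensity_range=(0.7, 0.95), background_level=0.10,
        noise_sd=0.02, overlap_fraction=0.0, seed=seed)


def imbalance_preset(n_images: int = 100, seed: int = 0) -> FixtureSpec:
    """Nine classes mirroring the reference dataset's imbalance: two dominant
    classes at 50.00% and 38.13% of instances, the remaining seven sharing
    the rest equally."""
    rest = (1.0 - 0.500 - 0.3813) / 7
    weights = [0.500, 0.3813] + [rest] * 7
    names = ["text", "fracture", "boneanomaly", "bonelesion", "foreignbody",
             "metal", "periostealreaction", "pronatorsign", "softtissue"]
    return FixtureSpec(
        n_images=n_images, image_size=(64, 64), categories=names,
        weights=weights, objects_per_image=(2, 4), size_range=(10, 24),
        seed=seed)


def overlap_preset(n_images: int = 100, seed: int = 0) -> FixtureSpec:
    """Frequent strongly overlapping same-class pairs (duplicate-suppression
    stress test)."""
    spec = easy_preset(n_images=n_images, seed=seed)
    spec.overlap_fraction = 0.5
    return spec
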