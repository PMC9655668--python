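"""Synthetic blood-smear scene generator with COCO annotations.

Emulates the class structure of a stained peripheral-smear field: many
medium-sized pale-red erythrocytes (RBC), a few large violet leukocytes (WBC,
rendered as a dark nucleus inside a lighter cytoplasm so they carry some
texture), and a handful of tiny violet platelets, on a pale background with
additive Gaussian noise.  Every object is an ellipse with bounded
eccentricity, placed by rejection sampling against a same-class overlap cap,
and annotated with its tight bounding box.

The generator is a fixture for exercising the detector end to end, not a
model of real smear statistics (no staining variation, no cell clumping or
rouleaux, no focus blur).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data_io import CATEGORIES, DatasetRecord, write_coco

logger = logging.getLogger(__name__)

_REFERENCE_SIZE = 416  # scene geometry is specified at this canvas size


@dataclass
class ClassSpec:
    count_range: tuple    # inclusive (lo, hi) objects per scene
    radius_range: tuple   # (lo, hi) semi-major axis, px
    color: tuple          # mean RGB 0..255
    color_jitter: float = 12.0


@dataclass
class SceneConfig:
    """Scene layout parameters; defaults describe a 416x416 smear field."""

    image_size: int = _REFERENCE_SIZE
    rbc: ClassSpec = field(default_factory=lambda: ClassSpec((10, 40), (14, 26), (225, 135, 130)))
    wbc: ClassSpec = field(default_factory=lambda: ClassSpec((1, 3), (28, 44), (150, 110, 185)))
    platelet: ClassSpec = field(default_factory=lambda: ClassSpec((2, 8), (4, 9), (140, 90, 170)))
    max_overlap_iou: float = 0.3   # same-class bounding-box IoU cap
    background: tuple = (236, 228, 232)
    noise_sd: float = 5.0
    max_axis_ratio: float = 1.4
    wbc_nucleus_color: tuple = (95, 60, 140)

    def __post_init__(self):
        for spec in (self.rbc, self.wbc, self.platelet):
            lo, hi = spec.radius_range
            if hi >= self.image_size / 2:
                raise ValueError("object radii must be below half the image size")
            if spec.count_range[0] > spec.count_range[1]:
                raise ValueError("empty count range")

    @classmethod
    def scaled(cls, image_size: int) -> "SceneConfig":
        """Geometrically faithful scaled-down scene.

        Radii scale with the side ratio and object counts with the area
        ratio, so the object density per stride-32 grid cell — what makes
        the assignment problem easy or hard — matches the reference scene.
        """
        s = image_size / _REFERENCE_SIZE
        ref = cls()

        def shrink(spec: ClassSpec) -> ClassSpec:
            lo = max(1, int(round(spec.count_range[0] * s * s)))
            hi = max(lo, int(round(spec.count_range[1] * s * s)))
            return ClassSpec((lo, hi),
                             (max(1.5, spec.radius_range[0] * s),
                              max(2.0, spec.radius_range[1] * s)),
                             spec.color, spec.color_jitter)

        return cls(image_size=image_size, rbc=shrink(ref.rbc),
                   wbc=shrink(ref.wbc), platelet=shrink(ref.platelet))

    def class_specs(self):
        return {"RBC": self.rbc, "WBC": self.wbc, "Platelets": self.platelet}


def _bbox_iou(a, b):
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def _sample_ellipse(rng, cfg: SceneConfig, spec: ClassSpec):
    a = rng.uniform(*spec.radius_range)
    ratio = rng.uniform(1.0, cfg.max_axis_ratio)
    b = a / ratio
    theta = rng.uniform(0, np.pi)
    # tight axis-aligned half-extents of a rotated ellipse
    hx = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    hy = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    cx = rng.uniform(hx, cfg.image_size - hx)
    cy = rng.uniform(hy, cfg.image_size - hy)
    return (cx, cy, a, b, theta, hx, hy)


def _render_ellipse(canvas, cx, cy, a, b, theta, color, soft=1.0):
    h, w, _ = canvas.shape
    x0 = max(0, int(cx - a - 3)); x1 = min(w, int(cx + a + 4))
    y0 = max(0, int(cy - a - 3)); y1 = min(h, int(cy + a + 4))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    r = np.sqrt(u * u + v * v)
    # soft edge: full color inside, linear falloff over ~`soft` px
    alpha = np.clip((1.0 - r) * (min(a, b) / soft), 0.0, 1.0)[..., None]
    region = canvas[y0:y1, x0:x1].astype(np.float64)
    canvas[y0:y1, x0:x1] = (region * (1 - alpha)
                            + np.asarray(color, dtype=np.float64) * alpha)


def generate_scene(cfg: SceneConfig, seed: int):
    """Render one scene; returns (uint8 HxWx3 image, DatasetRecord).

    Fully deterministic in (cfg, seed).  If the overlap cap cannot be met
    after 100 placement tries an object is dropped with a logged warning.
    """
    rng = np.random.RandomState(seed)
    size = cfg.image_size
    canvas = np.tile(np.asarray(cfg.background, dtype=np.float64),
                     (size, size, 1))
    boxes, labels = [], []
    placed: dict[str, list] = {name: [] for name in cfg.class_specs()}

    # draw order: RBC underneath, then WBC, platelets on top
    for name in ("RBC", "WBC", "Platelets"):
        spec = cfg.class_specs()[name]
        count = int(rng.randint(spec.count_range[0], spec.count_range[1] + 1))
        for _ in range(count):
            for _attempt in range(100):
                cx, cy, a, b, theta, hx, hy = _sample_ellipse(rng, cfg, spec)
                bbox = (cx - hx, cy - hy, cx + hx, cy + hy)
                if all(_bbox_iou(bbox, other) <= cfg.max_overlap_iou
                       for other in placed[name]):
                    break
            else:
                logger.warning("dropped a %s after 100 placement attempts", name)
                continue
            placed[name].append(bbox)
            color = np.clip(np.asarray(spec.color, dtype=np.float64)
                            + rng.normal(0, spec.color_jitter, 3), 0, 255)
            _render_ellipse(canvas, cx, cy, a, b, theta, color)
            if name == "WBC":  # nucleus: a smaller, darker concentric ellipse
                _render_ellipse(canvas, cx, cy, 0.55 * a, 0.55 * b,
                                theta + 0.4, cfg.wbc_nucleus_color)
            x, y = bbox[0], bbox[1]
            boxes.append([x, y, bbox[2] - x, bbox[3] - y])
            labels.append(name)

    canvas += rng.normal(0, cfg.noise_sd, canvas.shape)
    image = np.clip(canvas, 0, 255).astype(np.uint8)
    record = DatasetRecord(
        image_id=seed, file_name=f"scene_{seed:06d}.png",
        width=size, height=size,
        boxes=np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
        categories=labels, image=image)
    return image, record


def generate_records(cfg: SceneConfig, n_images: int, seed: int):
    """`n_images` in-memory scenes with per-scene seeds ``seed + index``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    records = []
    for i in range(n_images):
        _, rec = generate_scene(cfg, seed + i)
        rec.image_id = i + 1
        records.append(rec)
    return records


def generate_dataset(cfg: SceneConfig, n_images: int, out_dir, seed: int = 0):
    """Write `n_images` PNG scenes plus one COCO JSON; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = generate_records(cfg, n_images, seed)
    for rec in records:
        Image.fromarray(rec.image).save(out_dir / rec.file_name)
    json_path = out_dir / "annotations.json"
    write_coco(records, json_path, categories=CATEGORIES)
    return json_path
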