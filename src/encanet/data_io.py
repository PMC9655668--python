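"""COCO-format dataset reading/writing, geometric augmentation and splitting.

Blood-smear datasets arrive as a directory of images plus one COCO JSON
(`images` / `annotations` / `categories` arrays, boxes in 0-based pixel
``xywh``).  Records are kept lightweight: the image array is attached lazily
so a 364-image dataset can be split and inspected without touching pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

CATEGORIES = ("Platelets", "RBC", "WBC")

# per-channel normalization applied before the network (RGB in [0,1])
PIXEL_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
PIXEL_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


class CocoFormatError(ValueError):
    """Raised when a COCO JSON is structurally invalid."""


@dataclass
class DatasetRecord:
    """One image with its box annotations (COCO xywh pixels)."""

    image_id: int
    file_name: str
    width: int
    height: int
    boxes: np.ndarray          # (n, 4) float, xywh
    categories: list           # n category names
    image: np.ndarray | None = None  # (H, W, 3) uint8 when loaded

    def copy(self) -> "DatasetRecord":
        return replace(self, boxes=self.boxes.copy(),
                       categories=list(self.categories),
                       image=None if self.image is None else self.image.copy())


def normalize_image(image: np.ndarray) -> np.ndarray:
    """uint8 HWC RGB -> float32 CHW, zero-mean unit-variance per channel."""
    x = image.astype(np.float32) / 255.0
    x = (x - PIXEL_MEAN) / PIXEL_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def load_image(record: DatasetRecord, root=None) -> np.ndarray:
    if record.image is not None:
        return record.image
    path = Path(root) / record.file_name if root else Path(record.file_name)
    return np.asarray(Image.open(path).convert("RGB"))


# ---------------------------------------------------------------------------
# COCO JSON
# ---------------------------------------------------------------------------

def read_coco(json_path) -> list[DatasetRecord]:
    """Parse a COCO JSON into one record per image.

    Every annotation must reference a declared image and category; a dangling
    id raises :class:`CocoFormatError` naming the offender.
    """
    with open(json_path) as fh:
        doc = json.load(fh)
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise CocoFormatError(f"missing required COCO key {key!r}")
    cat_names = {c["id"]: c["name"] for c in doc["categories"]}
    records: dict[int, DatasetRecord] = {}
    for img in doc["images"]:
        records[img["id"]] = DatasetRecord(
            image_id=img["id"], file_name=img["file_name"],
            width=img["width"], height=img["height"],
            boxes=np.zeros((0, 4)), categories=[])
    boxes: dict[int, list] = {i: [] for i in records}
    for ann in doc["annotations"]:
        iid = ann["image_id"]
        if iid not in records:
            raise CocoFormatError(
                f"annotation {ann.get('id')} references unknown image_id {iid}")
        if ann["category_id"] not in cat_names:
            raise CocoFormatError(
                f"annotation {ann.get('id')} references unknown category_id "
                f"{ann['category_id']}")
        boxes[iid].append(ann)
        rec = records[iid]
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            raise CocoFormatError(f"annotation {ann.get('id')} has non-positive size")
        rec.categories.append(cat_names[ann["category_id"]])
    for iid, anns in boxes.items():
        records[iid].boxes = np.array([a["bbox"] for a in anns], dtype=np.float64) \
            if anns else np.zeros((0, 4))
    return [records[i] for i in sorted(records)]


def write_coco(records, json_path, categories=CATEGORIES) -> None:
    """Write records back to COCO JSON (category ids assigned 1..K in order)."""
    cat_ids = {name: i + 1 for i, name in enumerate(categories)}
    doc = {
        "images": [{"id": r.image_id, "file_name": r.file_name,
                    "width": r.width, "height": r.height} for r in records],
        "annotations": [],
        "categories": [{"id": i, "name": n} for n, i in cat_ids.items()],
    }
    ann_id = 1
    for r in records:
        for box, cat in zip(np.asarray(r.boxes).reshape(-1, 4), r.categories):
            doc["annotations"].append({
                "id": ann_id, "image_id": r.image_id,
                "category_id": cat_ids[cat],
                "bbox": [float(v) for v in box],
                "area": float(box[2] * box[3]),
                "iscrowd": 0,
            })
            ann_id += 1
    with open(json_path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def resize_with_boxes(record: DatasetRecord, target: int = 416) -> DatasetRecord:
    """Anisotropic resize to ``target x target``; boxes scale with each axis."""
    if record.width <= 0 or record.height <= 0:
        raise ValueError("cannot resize a zero-sized image")
    sx, sy = target / record.width, target / record.height
    out = record.copy()
    if record.boxes.size:
        out.boxes[:, 0] *= sx
        out.boxes[:, 2] *= sx
        out.boxes[:, 1] *= sy
        out.boxes[:, 3] *= sy
    if record.image is not None:
        out.image = np.asarray(
            Image.fromarray(record.image).resize((target, target), Image.BILINEAR))
    out.width = out.height = target
    return out


def flip(record: DatasetRecord, axis: str) -> DatasetRecord:
    """Mirror the image and boxes horizontally (`h`) or vertically (`v`)."""
    if axis not in ("h", "v"):
        raise ValueError("axis must be 'h' or 'v'")
    out = record.copy()
    if record.boxes.size:
        if axis == "h":
            out.boxes[:, 0] = record.width - record.boxes[:, 0] - record.boxes[:, 2]
        else:
            out.boxes[:, 1] = record.height - record.boxes[:, 1] - record.boxes[:, 3]
    if record.image is not None:
        out.image = record.image[:, ::-1] if axis == "h" else record.image[::-1]
        out.image = np.ascontiguousarray(out.image)
    return out


def split_dataset(records, ratios=(7, 2, 1), seed: int = 0):
    """Deterministic shuffled split into train/val/test.

    Validation and test take the floor of their proportional share; the
    remainder goes to train, so the partition is exact and disjoint
    (364 images at 7:2:1 -> 256/72/36).
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    n = len(records)
    if n < len(ratios):
        raise ValueError(f"cannot split {n} records into {len(ratios)} parts")
    total = sum(ratios)
    n_val = int(n * ratios[1] / total)
    n_test = int(n * ratios[2] / total)
    n_train = n - n_val - n_test
    order = np.random.RandomState(seed).permutation(n)
    shuffled = [records[i] for i in order]
    return (shuffled[:n_train],
            shuffled[n_train:n_train + n_val],
            shuffled[n_train + n_val:])
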