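"""Anchor machinery, target assignment, losses and NMS.

The detector predicts at a single stride-32 level with A square anchors per
cell.  Training uses uniform matching (each ground-truth box claims its k
nearest anchors by center distance, with IoU-based demotion of bad positives
and ignoring of well-overlapping unmatched anchors), a focal classification
loss and a GIoU regression loss; inference uses per-class greedy NMS.

Boxes are handled in two conventions: COCO ``xywh`` at the dataset boundary
and corner ``xyxy`` internally.  All functions here are plain numpy except
the loss helpers, which also accept autograd tensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nnops import Tensor, maximum, minimum

ANCHOR_SIZES = (32, 64, 128, 256, 512)  # square anchor sides at image size 416


@dataclass
class DetectionRecord:
    """One detection or ground-truth box in COCO convention."""

    image_id: int
    category: str
    score: float
    box: tuple  # (x, y, w, h) pixels


@dataclass
class MatchResult:
    """Per-anchor assignment: 1 positive, 0 negative, -1 ignored."""

    labels: np.ndarray      # (M,) in {-1, 0, 1}
    gt_index: np.ndarray    # (M,) index of the matched GT for positives, else -1


# ---------------------------------------------------------------------------
# box utilities
# ---------------------------------------------------------------------------

def xywh_to_xyxy(boxes):
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    out = boxes.copy()
    out[:, 2:] = boxes[:, :2] + boxes[:, 2:]
    return out


def xyxy_to_xywh(boxes):
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    out = boxes.copy()
    out[:, 2:] = boxes[:, 2:] - boxes[:, :2]
    return out


def box_iou(a, b):
    """Pairwise IoU between xyxy box arrays of shapes (M,4) and (N,4)."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


# ---------------------------------------------------------------------------
# anchors and box coding
# ---------------------------------------------------------------------------

def generate_anchors(anchors_per_cell: int = 5, stride: int = 32,
                     image_size: int = 416, sizes=None) -> np.ndarray:
    """Square anchors centered on every cell of the stride grid, xyxy pixels.

    By default the anchor sides are the canonical {32,...,512} scaled by
    ``image_size / 416`` so a scaled-down study keeps the same geometry.
    """
    if image_size % stride != 0:
        raise ValueError(f"image size {image_size} not divisible by stride {stride}")
    if sizes is None:
        sizes = tuple(s * image_size / 416.0 for s in ANCHOR_SIZES[:anchors_per_cell])
    if len(sizes) != anchors_per_cell:
        raise ValueError("need one size per anchor")
    g = image_size // stride
    centers = (np.arange(g) + 0.5) * stride
    cx, cy = np.meshgrid(centers, centers)  # (g, g)
    cx, cy = cx.ravel(), cy.ravel()
    anchors = np.empty((g * g, anchors_per_cell, 4), dtype=np.float64)
    for i, s in enumerate(sizes):
        anchors[:, i, 0] = cx - s / 2
        anchors[:, i, 1] = cy - s / 2
        anchors[:, i, 2] = cx + s / 2
        anchors[:, i, 3] = cy + s / 2
    return anchors.reshape(-1, 4)


def _centers_sizes(boxes_xyxy):
    b = np.asarray(boxes_xyxy, dtype=np.float64).reshape(-1, 4)
    ctr = (b[:, :2] + b[:, 2:]) / 2
    size = b[:, 2:] - b[:, :2]
    return ctr, size


def encode_boxes(anchors, boxes):
    """Center/size deltas of xyxy `boxes` relative to xyxy `anchors`."""
    actr, asize = _centers_sizes(anchors)
    bctr, bsize = _centers_sizes(boxes)
    if np.any(asize <= 0) or np.any(bsize <= 0):
        raise ValueError("boxes and anchors must have positive width and height")
    deltas = np.empty_like(np.asarray(anchors, dtype=np.float64).reshape(-1, 4))
    deltas[:, :2] = (bctr - actr) / asize
    deltas[:, 2:] = np.log(bsize / asize)
    return deltas


def decode_boxes(anchors, deltas):
    """Inverse of :func:`encode_boxes`; exact round-trip."""
    actr, asize = _centers_sizes(anchors)
    deltas = np.asarray(deltas, dtype=np.float64).reshape(-1, 4)
    if np.any(asize <= 0):
        raise ValueError("anchors must have positive width and height")
    ctr = actr + deltas[:, :2] * asize
    size = asize * np.exp(np.clip(deltas[:, 2:], -10, 10))
    out = np.empty_like(deltas)
    out[:, :2] = ctr - size / 2
    out[:, 2:] = ctr + size / 2
    return out


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

def uniform_match(gt_boxes, anchors, k: int = 4, ignore_iou: float = 0.7,
                  min_pos_iou: float = 0.15) -> MatchResult:
    """Uniform matching: each GT claims its `k` nearest anchors by center L2.

    Positives whose IoU with their GT falls below ``min_pos_iou`` are demoted
    to ignored; unmatched anchors with IoU above ``ignore_iou`` to any GT are
    ignored rather than treated as negatives.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    anchors = np.asarray(anchors, dtype=np.float64).reshape(-1, 4)
    m = anchors.shape[0]
    labels = np.zeros(m, dtype=np.int8)
    gt_index = np.full(m, -1, dtype=np.int64)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    if gt_boxes.shape[0] == 0:
        return MatchResult(labels, gt_index)

    actr, _ = _centers_sizes(anchors)
    gctr, _ = _centers_sizes(gt_boxes)
    dist = np.linalg.norm(actr[None, :, :] - gctr[:, None, :], axis=-1)  # (G, M)
    iou = box_iou(gt_boxes, anchors)                                     # (G, M)

    for gi in range(gt_boxes.shape[0]):
        nearest = np.argsort(dist[gi], kind="stable")[:k]
        for ai in nearest:
            if labels[ai] == 1 and dist[gt_index[ai], ai] <= dist[gi, ai]:
                continue  # a closer GT already claimed this anchor
            labels[ai] = 1
            gt_index[ai] = gi

    # demote low-quality positives
    pos = labels == 1
    if pos.any():
        pos_idx = np.where(pos)[0]
        low = iou[gt_index[pos_idx], pos_idx] < min_pos_iou
        labels[pos_idx[low]] = -1
        gt_index[pos_idx[low]] = -1

    # ignore unmatched anchors that overlap some GT too well
    neg = labels == 0
    max_iou = iou.max(axis=0)
    labels[neg & (max_iou > ignore_iou)] = -1
    return MatchResult(labels, gt_index)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def focal_loss(p, y, alpha: float = 0.25, gamma: float = 2.0):
    """Focal loss on probabilities: ``-a (1-p)^g log p`` for positives and
    ``-(1-a) p^g log(1-p)`` for negatives.  Sum over elements."""
    eps = 1e-6
    pd = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64)
    if np.any(pd <= 0) or np.any(pd >= 1):
        warnings.warn("focal_loss received probabilities outside (0,1); clamping",
                      stacklevel=2)
    if isinstance(p, Tensor):
        p = p.clip(eps, 1 - eps)
        y = np.asarray(y, dtype=p.data.dtype)
        pos = -alpha * (1 - p) ** gamma * p.log()
        neg = -(1 - alpha) * p ** gamma * (1 - p).log()
        return (y * pos + (1 - y) * neg).sum()
    p = np.clip(pd, eps, 1 - eps)
    y = np.asarray(y, dtype=np.float64)
    pos = -alpha * (1 - p) ** gamma * np.log(p)
    neg = -(1 - alpha) * p ** gamma * np.log(1 - p)
    return float(np.sum(y * pos + (1 - y) * neg))


def giou_loss(b1, b2):
    """``1 - GIoU`` between xyxy boxes; elementwise over (M, 4) pairs, summed.

    Ranges over [0, 2]; 0 exactly when the boxes coincide.
    """
    is_tensor = isinstance(b1, Tensor) or isinstance(b2, Tensor)
    d1 = b1.data if isinstance(b1, Tensor) else np.asarray(b1, dtype=np.float64)
    d2 = b2.data if isinstance(b2, Tensor) else np.asarray(b2, dtype=np.float64)
    d1, d2 = d1.reshape(-1, 4), d2.reshape(-1, 4)
    if np.any(d1[:, 2:] <= d1[:, :2]) or np.any(d2[:, 2:] <= d2[:, :2]):
        raise ValueError("degenerate box: corners must satisfy x2 > x1, y2 > y1")
    if not is_tensor:
        return float(np.sum(_giou_np(d1, d2)))

    b1 = b1 if isinstance(b1, Tensor) else Tensor(d1)
    b2 = b2 if isinstance(b2, Tensor) else Tensor(d2)
    x1 = maximum(b1[:, 0], b2[:, 0]); y1 = maximum(b1[:, 1], b2[:, 1])
    x2 = minimum(b1[:, 2], b2[:, 2]); y2 = minimum(b1[:, 3], b2[:, 3])
    zero = Tensor(np.zeros(1, dtype=b1.data.dtype))
    iw = maximum(x2 - x1, zero); ih = maximum(y2 - y1, zero)
    inter = iw * ih
    a1 = (b1[:, 2] - b1[:, 0]) * (b1[:, 3] - b1[:, 1])
    a2 = (b2[:, 2] - b2[:, 0]) * (b2[:, 3] - b2[:, 1])
    union = a1 + a2 - inter
    ex1 = minimum(b1[:, 0], b2[:, 0]); ey1 = minimum(b1[:, 1], b2[:, 1])
    ex2 = maximum(b1[:, 2], b2[:, 2]); ey2 = maximum(b1[:, 3], b2[:, 3])
    enclose = (ex2 - ex1) * (ey2 - ey1) + 1e-9
    giou = inter / (union + 1e-9) - (enclose - union) / enclose
    return (1.0 - giou).sum()


def _giou_np(d1, d2):
    tl = np.maximum(d1[:, :2], d2[:, :2])
    br = np.minimum(d1[:, 2:], d2[:, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[:, 0] * wh[:, 1]
    a1 = (d1[:, 2] - d1[:, 0]) * (d1[:, 3] - d1[:, 1])
    a2 = (d2[:, 2] - d2[:, 0]) * (d2[:, 3] - d2[:, 1])
    union = a1 + a2 - inter
    etl = np.minimum(d1[:, :2], d2[:, :2])
    ebr = np.maximum(d1[:, 2:], d2[:, 2:])
    enclose = (ebr - etl)[:, 0] * (ebr - etl)[:, 1] + 1e-9
    giou = inter / (union + 1e-9) - (enclose - union) / enclose
    return 1.0 - giou


# ---------------------------------------------------------------------------
# non-maximum suppression
# ---------------------------------------------------------------------------

def nms(boxes, scores, iou_threshold: float = 0.6) -> np.ndarray:
    """Greedy NMS on xyxy boxes; returns kept indices by descending score."""
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must be in (0, 1]")
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        ious = box_iou(boxes[i], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_threshold]
    return np.asarray(keep, dtype=np.int64)


def nms_records(records, iou_threshold: float = 0.6):
    """Per-class NMS over :class:`DetectionRecord` lists (COCO xywh boxes)."""
    kept = []
    by_class: dict[str, list[DetectionRecord]] = {}
    for r in records:
        by_class.setdefault(r.category, []).append(r)
    for recs in by_class.values():
        boxes = xywh_to_xyxy([r.box for r in recs])
        scores = np.array([r.score for r in recs])
        for i in nms(boxes, scores, iou_threshold):
            kept.append(recs[i])
    kept.sort(key=lambda r: -r.score)
    return kept
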