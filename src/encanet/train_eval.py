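"""Training loop, inference, COCO evaluation and attention-map visualization.

The training recipe is SGD (momentum 0.9, weight decay 1e-4) at batch size 4
with a base learning rate of 0.12 held for 12 epochs; a linear warmup over
the first 1500 iterations ramps the rate from 1/1000 of its base value to
stabilize the early updates.  The loss is focal classification (alpha 0.25,
gamma 2) on the combined class/objectness probability plus GIoU and
delta-space L1 box losses on positive anchors, all normalized by the number
of positives; gradients are clipped by global norm.  Inference applies a
0.05 score floor and per-class NMS at IoU 0.6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .architecture import ENCANet
from .data_io import CATEGORIES, DatasetRecord, flip, load_image, normalize_image
from .detection import (DetectionRecord, decode_boxes, encode_boxes, focal_loss,
                        generate_anchors, giou_loss, nms, uniform_match,
                        xywh_to_xyxy, xyxy_to_xywh)
from .metrics import coco_metrics
from .nnops import SGD, Tensor, concatenate

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 4
    base_lr: float = 0.12
    epochs: int = 12
    warmup_iters: int = 1500
    warmup_factor: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0
    max_iters: int | None = None   # overrides epochs when set
    flip_prob: float = 0.5
    match_k: int = 4
    giou_weight: float = 1.0
    l1_weight: float = 1.0   # delta-space L1 keeps gradients well-conditioned
    clip_grad_norm: float | None = 10.0

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.warmup_iters < 0:
            raise ValueError("warmup_iters must be >= 0")


def lr_at(iteration: int, cfg: TrainConfig) -> float:
    """Linear warmup from ``base_lr * warmup_factor`` to ``base_lr``, then flat."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    if cfg.warmup_iters == 0 or iteration >= cfg.warmup_iters:
        return cfg.base_lr
    t = iteration / cfg.warmup_iters
    return cfg.base_lr * (cfg.warmup_factor + (1.0 - cfg.warmup_factor) * t)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _flatten_predictions(outputs, num_classes, anchors_per_cell):
    """Map head outputs to per-anchor (M, K) logits and (M, 4) deltas.

    Channel layout is anchor-major; anchor flat order is cell-major
    (row*grid + col) then anchor index, matching :func:`generate_anchors`.
    """
    cls, box, obj = outputs["cls_logits"], outputs["box_deltas"], outputs["obj_logits"]
    n, _, h, w = cls.shape
    a, k = anchors_per_cell, num_classes
    cls = cls.reshape((n, a, k, h, w)).transpose((0, 3, 4, 1, 2)).reshape((n, h * w * a, k))
    box = box.reshape((n, a, 4, h, w)).transpose((0, 3, 4, 1, 2)).reshape((n, h * w * a, 4))
    obj = obj.reshape((n, a, 1, h, w)).transpose((0, 3, 4, 1, 2)).reshape((n, h * w * a, 1))
    return cls, box, obj


def detection_loss(outputs, gt_list, anchors, cfg: TrainConfig, num_classes: int,
                   anchors_per_cell: int, categories=CATEGORIES):
    """Focal + GIoU training loss for one batch.

    `gt_list` holds per-image (xyxy boxes, class-index array) tuples.
    Returns (total, dict of floats).
    """
    cls, box, obj = _flatten_predictions(outputs, num_classes, anchors_per_cell)
    actr = (anchors[:, :2] + anchors[:, 2:]) / 2
    asize = anchors[:, 2:] - anchors[:, :2]
    total_focal, total_giou, total_l1, n_pos = None, None, None, 0
    for i, (gt_boxes, gt_classes) in enumerate(gt_list):
        match = uniform_match(gt_boxes, anchors, k=cfg.match_k)
        valid = match.labels >= 0
        # clamp logits so float32 sigmoids stay strictly inside (0, 1)
        p = (cls[i].clip(-15, 15).sigmoid() * obj[i].clip(-15, 15).sigmoid())[valid]
        target = np.zeros((int(valid.sum()), num_classes), dtype=np.float32)
        pos_rows = match.labels[valid] == 1
        if pos_rows.any():
            target[pos_rows, gt_classes[match.gt_index[valid][pos_rows]]] = 1.0
        fl = focal_loss(p, target)
        total_focal = fl if total_focal is None else total_focal + fl

        pos_idx = np.where(match.labels == 1)[0]
        n_pos += len(pos_idx)
        if len(pos_idx):
            d = box[i][pos_idx]  # (P, 4) deltas
            ctr = Tensor(actr[pos_idx].astype(np.float32)) + \
                d[:, :2] * Tensor(asize[pos_idx].astype(np.float32))
            # bound the log-size numerically but keep the restoring gradient
            dsz = d[:, 2:]
            dsz = dsz + (dsz.clip(-8, 8) - dsz).detach()
            size = Tensor(asize[pos_idx].astype(np.float32)) * dsz.exp()
            pred = concatenate([ctr - size * 0.5, ctr + size * 0.5], axis=1)
            matched_gt = gt_boxes[match.gt_index[pos_idx]]
            gl = giou_loss(pred, matched_gt.astype(np.float32))
            total_giou = gl if total_giou is None else total_giou + gl
            tdeltas = encode_boxes(anchors[pos_idx], matched_gt).astype(np.float32)
            diff = d - Tensor(tdeltas)
            l1 = ((diff * diff + 1e-8) ** 0.5).sum()
            total_l1 = l1 if total_l1 is None else total_l1 + l1

    denom = 1.0 / max(1, n_pos)
    total = total_focal * denom
    if total_giou is not None:
        total = total + total_giou * (cfg.giou_weight * denom) \
            + total_l1 * (cfg.l1_weight * denom)
    parts = {"focal": float(total_focal.data) * denom,
             "giou": 0.0 if total_giou is None else float(total_giou.data) * denom,
             "l1": 0.0 if total_l1 is None else float(total_l1.data) * denom}
    return total, parts


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def recalibrate_batch_norm(model: ENCANet, records, batch_size: int = 4,
                           categories=CATEGORIES) -> None:
    """Replace batch-norm running statistics by exact dataset averages.

    With batch size 4 and a coarse stride-32 grid, per-batch normalization
    statistics are noisy; averaging activation moments over the training set
    after optimization makes eval-mode behavior match train-mode behavior.
    """
    from .nnops import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved_momentum = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0  # running stats == current batch stats
    sums = [None] * len(bns)
    model.train()
    n_batches = 0
    try:
        for start in range(0, len(records), batch_size):
            chunk = records[start:start + batch_size]
            x = np.stack([_prepare(r, categories)[0] for r in chunk])
            model(x)
            for i, bn in enumerate(bns):
                stats = (bn.running_mean.copy(), bn.running_var.copy())
                sums[i] = stats if sums[i] is None else (sums[i][0] + stats[0],
                                                         sums[i][1] + stats[1])
            n_batches += 1
    finally:
        for bn, mom in zip(bns, saved_momentum):
            bn.momentum = mom
    for i, bn in enumerate(bns):
        bn.running_mean[...] = sums[i][0] / n_batches
        bn.running_var[...] = sums[i][1] / n_batches
    model.eval()


def _clip_grad_norm(params, max_norm: float) -> float:
    from .nnops import _kernels

    total = 0.0
    for p in params:
        if p.grad is None:
            continue
        g = p.grad if p.grad.flags["C_CONTIGUOUS"] else np.ascontiguousarray(p.grad)
        p.grad = g
        if _kernels.HAVE_NUMBA and g.dtype == np.float32:
            total += float(_kernels.sq_norm(g.ravel()))
        else:
            flat = g.ravel()
            total += float(np.dot(flat, flat))
    norm = float(np.sqrt(total))
    if norm > max_norm:
        scale = np.float32(max_norm / (norm + 1e-12))
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


@dataclass
class TrainResult:
    loss_log: list
    part_log: list
    model: ENCANet


def _prepare(record: DatasetRecord, categories) -> tuple:
    image = record.image if record.image is not None else load_image(record)
    gt_boxes = xywh_to_xyxy(record.boxes) if record.boxes.size else np.zeros((0, 4))
    gt_classes = np.array([categories.index(c) for c in record.categories], dtype=np.int64)
    return normalize_image(image), gt_boxes, gt_classes


def train(model: ENCANet, records: list[DatasetRecord], cfg: TrainConfig,
          categories=CATEGORIES) -> TrainResult:
    """Train in place; deterministic given ``cfg.seed``.

    Runs ``epochs * ceil(n / batch)`` iterations (or ``max_iters``), logging
    every per-iteration loss.  A non-finite loss aborts with a diagnostic
    naming the offending term.
    """
    if not records:
        raise ValueError("dataset is empty")
    rng = np.random.RandomState(cfg.seed)
    n = len(records)
    iters_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_iters = cfg.max_iters if cfg.max_iters is not None \
        else cfg.epochs * iters_per_epoch
    anchors = generate_anchors(model.cfg.anchors_per_cell, model.cfg.stride,
                               model.cfg.image_size)
    opt = SGD(model.parameters(), lr=cfg.base_lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    model.train()
    loss_log, part_log = [], []
    for it in range(total_iters):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        batch, gt_list = [], []
        for j in idx:
            rec = records[j]
            if rng.rand() < cfg.flip_prob:
                rec = flip(rec, "h")
            if rng.rand() < cfg.flip_prob:
                rec = flip(rec, "v")
            img, gtb, gtc = _prepare(rec, categories)
            batch.append(img)
            gt_list.append((gtb, gtc))
        x = np.stack(batch)
        outputs = model(x)
        loss, parts = detection_loss(outputs, gt_list, anchors, cfg,
                                     model.cfg.num_classes,
                                     model.cfg.anchors_per_cell, categories)
        for name, val in parts.items():
            if not np.isfinite(val):
                raise RuntimeError(f"non-finite loss in term {name!r} at iteration {it}")
        opt.zero_grad()
        loss.backward()
        if cfg.clip_grad_norm is not None:
            _clip_grad_norm(opt.params, cfg.clip_grad_norm)
        opt.lr = lr_at(it, cfg)
        opt.step()
        loss_log.append(float(loss.data))
        part_log.append(parts)
    return TrainResult(loss_log, part_log, model)


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def predict(model: ENCANet, record: DatasetRecord, score_floor: float = 0.05,
            nms_threshold: float = 0.6, max_dets: int = 100,
            categories=CATEGORIES) -> list[DetectionRecord]:
    """Detections for one image: decode, clip, threshold, per-class NMS."""
    model.eval()
    image = record.image if record.image is not None else load_image(record)
    x = normalize_image(image)[None]
    outputs = model(x)
    k, a = model.cfg.num_classes, model.cfg.anchors_per_cell
    cls, box, obj = _flatten_predictions(outputs, k, a)
    anchors = generate_anchors(a, model.cfg.stride, model.cfg.image_size)
    scores = expit(cls.data[0]) * expit(obj.data[0])      # (M, K)
    boxes = decode_boxes(anchors, box.data[0])            # (M, 4) xyxy
    size = model.cfg.image_size
    boxes = np.clip(boxes, 0, size)
    results = []
    for ci, cat in enumerate(categories[:k]):
        s = scores[:, ci]
        keep = s >= score_floor
        if not keep.any():
            continue
        b, s = boxes[keep], s[keep]
        ok = (b[:, 2] - b[:, 0] > 1e-3) & (b[:, 3] - b[:, 1] > 1e-3)
        b, s = b[ok], s[ok]
        if not len(b):
            continue
        for i in nms(b, s, nms_threshold)[:max_dets]:
            xywh = xyxy_to_xywh(b[i])[0]
            results.append(DetectionRecord(record.image_id, cat, float(s[i]),
                                           tuple(float(v) for v in xywh)))
    results.sort(key=lambda r: -r.score)
    return results[:max_dets]


def evaluate(model: ENCANet, records: list[DatasetRecord],
             score_floor: float = 0.05, nms_threshold: float = 0.6,
             categories=CATEGORIES) -> dict:
    """COCO metrics of the model on a record list (AP, AP50, ... on 0-100)."""
    detections = []
    for rec in records:
        detections.extend(predict(model, rec, score_floor, nms_threshold,
                                  categories=categories))
    return coco_metrics(records, detections, categories=categories)


def detections_to_coco(detections, categories=CATEGORIES) -> list[dict]:
    """Serialize detections as COCO results JSON entries."""
    cat_ids = {name: i + 1 for i, name in enumerate(categories)}
    return [{"image_id": d.image_id, "category_id": cat_ids[d.category],
             "bbox": [float(v) for v in d.box], "score": float(d.score)}
            for d in detections]


# ---------------------------------------------------------------------------
# visualization
# ---------------------------------------------------------------------------

TAP_POINTS = ("after_backbone", "after_encoder")


def attention_map(model: ENCANet, image: np.ndarray, tap_point: str = "after_encoder"):
    """Channel-mean activation heatmap at a tap point, upsampled to the image.

    Returns ``(heatmap, overlay)``: the heatmap is min-max normalized to
    [0, 1] (a constant map degenerates to all zeros); the overlay blends a
    colormapped heatmap onto the input image.
    """
    if tap_point not in TAP_POINTS:
        raise ValueError(f"unknown tap point {tap_point!r}; expected one of {TAP_POINTS}")
    model.eval()
    x = normalize_image(image)[None]
    feat = model.features(x, tap=tap_point)
    fmap = feat.data[0].mean(axis=0)  # (h, w)
    lo, hi = float(fmap.min()), float(fmap.max())
    if hi - lo < 1e-12:
        fmap = np.zeros_like(fmap)
    else:
        fmap = (fmap - lo) / (hi - lo)
    zoom = (image.shape[0] / fmap.shape[0], image.shape[1] / fmap.shape[1])
    heat = np.clip(ndimage.zoom(fmap, zoom, order=1), 0.0, 1.0)
    from matplotlib import cm
    colored = cm.jet(heat)[..., :3]
    overlay = (0.5 * image.astype(np.float64) / 255.0 + 0.5 * colored)
    overlay = (np.clip(overlay, 0, 1) * 255).astype(np.uint8)
    return heat, overlay
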