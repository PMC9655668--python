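"""MS-COCO-protocol detection metrics.

Average precision with 101-point interpolated precision, IoU thresholds
0.50:0.05:0.95, per-image greedy matching in score order, at most 100
detections per image, and the standard small/medium/large area stratification
(32^2 and 96^2 pixel-area cuts).  AP is averaged over categories that have at
least one ground-truth instance.  Values are reported on the 0-100 scale.
"""

from __future__ import annotations

import numpy as np

from .data_io import CATEGORIES, DatasetRecord
from .detection import DetectionRecord, box_iou, xywh_to_xyxy

IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)
RECALL_THRESHOLDS = np.linspace(0.0, 1.0, 101)
AREA_RANGES = {
    "all": (0.0, 1e10),
    "small": (0.0, 32.0 ** 2),
    "medium": (32.0 ** 2, 96.0 ** 2),
    "large": (96.0 ** 2, 1e10),
}
MAX_DETS = 100


def _match_image(gt_boxes, gt_ignore, det_boxes, iou_thr):
    """COCO per-image greedy matching; returns (det_matched, det_to_ignored)."""
    nd, ng = len(det_boxes), len(gt_boxes)
    matched = np.zeros(nd, dtype=bool)
    to_ignored = np.zeros(nd, dtype=bool)
    if ng == 0:
        return matched, to_ignored
    ious = box_iou(det_boxes, gt_boxes)
    gt_taken = np.zeros(ng, dtype=bool)
    for d in range(nd):
        # prefer an untaken non-ignored GT; fall back to an ignored one
        real = ~gt_ignore & ~gt_taken
        if real.any():
            g = np.where(real)[0][np.argmax(ious[d, real])]
            if ious[d, g] >= iou_thr:
                gt_taken[g] = True
                matched[d] = True
                continue
        if gt_ignore.any():
            g = np.where(gt_ignore)[0][np.argmax(ious[d, gt_ignore])]
            if ious[d, g] >= iou_thr:
                to_ignored[d] = True
    return matched, to_ignored


def _ap_single(gts_by_img, dets_by_img, iou_thr, area_range):
    """(AP in [0,1] or nan if no GT) for one category/IoU/area combination."""
    lo, hi = area_range
    scores, tps, fps = [], [], []
    n_pos = 0
    for img_id, (gt_boxes, gt_areas) in gts_by_img.items():
        ignore = (gt_areas < lo) | (gt_areas > hi)
        n_pos += int((~ignore).sum())
        det_boxes, det_scores = dets_by_img.get(img_id, (np.zeros((0, 4)), np.zeros(0)))
        order = np.argsort(-det_scores, kind="stable")[:MAX_DETS]
        det_boxes, det_scores = det_boxes[order], det_scores[order]
        matched, to_ignored = _match_image(gt_boxes, ignore, det_boxes, iou_thr)
        det_areas = (det_boxes[:, 2] - det_boxes[:, 0]) * (det_boxes[:, 3] - det_boxes[:, 1])
        out_of_range = (det_areas < lo) | (det_areas > hi)
        keep = ~(to_ignored | (~matched & out_of_range))
        scores.append(det_scores[keep])
        tps.append(matched[keep])
        fps.append(~matched[keep])
    # images with detections but no GT entry at all still contribute FPs
    for img_id, (det_boxes, det_scores) in dets_by_img.items():
        if img_id in gts_by_img:
            continue
        order = np.argsort(-det_scores, kind="stable")[:MAX_DETS]
        det_boxes, det_scores = det_boxes[order], det_scores[order]
        det_areas = (det_boxes[:, 2] - det_boxes[:, 0]) * (det_boxes[:, 3] - det_boxes[:, 1])
        keep = ~((det_areas < lo) | (det_areas > hi))
        scores.append(det_scores[keep])
        tps.append(np.zeros(keep.sum(), dtype=bool))
        fps.append(np.ones(keep.sum(), dtype=bool))
    if n_pos == 0:
        return np.nan
    scores = np.concatenate(scores) if scores else np.zeros(0)
    tps = np.concatenate(tps) if tps else np.zeros(0, bool)
    fps = np.concatenate(fps) if fps else np.zeros(0, bool)
    order = np.argsort(-scores, kind="stable")
    tp_cum = np.cumsum(tps[order])
    fp_cum = np.cumsum(fps[order])
    recall = tp_cum / n_pos
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # monotone non-increasing envelope, then 101-point interpolation
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    idx = np.searchsorted(recall, RECALL_THRESHOLDS, side="left")
    interp = np.where(idx < len(precision), precision[np.minimum(idx, max(len(precision) - 1, 0))], 0.0) \
        if len(precision) else np.zeros_like(RECALL_THRESHOLDS)
    return float(np.mean(interp))


def coco_metrics(gt_records: list[DatasetRecord],
                 detections: list[DetectionRecord],
                 categories=CATEGORIES) -> dict:
    """COCO AP summary: AP, AP50, AP75, APS, APM, APL on the 0-100 scale."""
    gts = {}   # (category) -> {image_id: (xyxy boxes, areas)}
    for cat in categories:
        per_img = {}
        for rec in gt_records:
            mask = np.array([c == cat for c in rec.categories], dtype=bool)
            boxes = np.asarray(rec.boxes, dtype=np.float64).reshape(-1, 4)[mask]
            areas = boxes[:, 2] * boxes[:, 3]
            per_img[rec.image_id] = (xywh_to_xyxy(boxes), areas)
        gts[cat] = per_img
    dets = {}
    for cat in categories:
        per_img = {}
        for d in detections:
            if d.category != cat:
                continue
            boxes, scores = per_img.setdefault(d.image_id, ([], []))
            boxes.append(d.box)
            scores.append(d.score)
        dets[cat] = {i: (xywh_to_xyxy(np.asarray(b).reshape(-1, 4)), np.asarray(s))
                     for i, (b, s) in per_img.items()}

    def mean_ap(iou_thrs, area_name):
        vals = []
        for cat in categories:
            for t in np.atleast_1d(iou_thrs):
                vals.append(_ap_single(gts[cat], dets[cat], t, AREA_RANGES[area_name]))
        vals = [v for v in vals if not np.isnan(v)]
        return 100.0 * float(np.mean(vals)) if vals else 0.0

    return {
        "AP": mean_ap(IOU_THRESHOLDS, "all"),
        "AP50": mean_ap(0.5, "all"),
        "AP75": mean_ap(0.75, "all"),
        "APS": mean_ap(IOU_THRESHOLDS, "small"),
        "APM": mean_ap(IOU_THRESHOLDS, "medium"),
        "APL": mean_ap(IOU_THRESHOLDS, "large"),
    }
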