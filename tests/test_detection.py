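"""Anchors, box coding, matching, losses and NMS against brute-force oracles."""

import numpy as np
import pytest

from encanet.detection import (box_iou, decode_boxes, encode_boxes, focal_loss,
                               generate_anchors, giou_loss, nms, nms_records,
                               uniform_match, DetectionRecord, xywh_to_xyxy)


def test_anchor_count_and_geometry():
    anchors = generate_anchors(5, 32, 416)
    assert anchors.shape == (845, 4)  # 13*13*5
    first = anchors[0]
    cx, cy = (first[0] + first[2]) / 2, (first[1] + first[3]) / 2
    assert (cx, cy) == (16.0, 16.0)  # stride/2 offset
    # adjacent cells differ by exactly the stride in one coordinate
    a0, a1 = anchors[0], anchors[5]           # next cell in x
    np.testing.assert_allclose(a1 - a0, [32, 0, 32, 0])
    a_row = anchors[13 * 5]                   # next cell in y
    np.testing.assert_allclose(a_row - a0, [0, 32, 0, 32])


def test_anchor_indivisible_image_size():
    with pytest.raises(ValueError, match="divisible"):
        generate_anchors(5, 32, 100)


def test_encode_decode_roundtrip(rng):
    anchors = generate_anchors(5, 32, 416)
    idx = rng.integers(0, len(anchors), size=1000)
    boxes = anchors[idx].copy()
    boxes[:, :2] += rng.uniform(-10, 10, size=(1000, 2))
    boxes[:, 2:] += rng.uniform(11, 30, size=(1000, 2))
    deltas = encode_boxes(anchors[idx], boxes)
    np.testing.assert_allclose(decode_boxes(anchors[idx], deltas), boxes, atol=1e-5)


def test_zero_deltas_return_anchor():
    anchors = generate_anchors(5, 32, 416)[:10]
    np.testing.assert_allclose(decode_boxes(anchors, np.zeros((10, 4))), anchors)


def test_log_width_coding():
    anchor = np.array([[0.0, 0.0, 32.0, 32.0]])
    deltas = np.array([[0.0, 0.0, np.log(2.0), 0.0]])
    out = decode_boxes(anchor, deltas)[0]
    assert out[2] - out[0] == pytest.approx(64.0)


def test_encode_rejects_degenerate_boxes():
    anchor = np.array([[0.0, 0.0, 32.0, 32.0]])
    with pytest.raises(ValueError, match="positive"):
        encode_boxes(anchor, np.array([[5.0, 5.0, 5.0, 9.0]]))


# ---------------------------------------------------------------------------
# uniform matching
# ---------------------------------------------------------------------------


def brute_force_match(gt_boxes, anchors, k):
    """Exhaustive distance-sort assignment with the same demotion rules."""
    m = len(anchors)
    labels = np.zeros(m, dtype=np.int8)
    gt_index = np.full(m, -1, dtype=np.int64)
    if len(gt_boxes) == 0:
        return labels, gt_index
    actr = (anchors[:, :2] + anchors[:, 2:]) / 2
    gctr = (gt_boxes[:, :2] + gt_boxes[:, 2:]) / 2
    iou = box_iou(gt_boxes, anchors)
    dist = np.linalg.norm(actr[None] - gctr[:, None], axis=-1)
    for gi in range(len(gt_boxes)):
        for ai in np.argsort(dist[gi], kind="stable")[:k]:
            if labels[ai] == 1 and dist[gt_index[ai], ai] <= dist[gi, ai]:
                continue
            labels[ai], gt_index[ai] = 1, gi
    pos = np.where(labels == 1)[0]
    for ai in pos:
        if iou[gt_index[ai], ai] < 0.15:
            labels[ai], gt_index[ai] = -1, -1
    for ai in range(m):
        if labels[ai] == 0 and iou[:, ai].max() > 0.7:
            labels[ai] = -1
    return labels, gt_index


def test_single_gt_k4_claims_four_anchors():
    """One GT claims its 4 nearest anchors; low-IoU claims are demoted to
    ignored (never negative), so positives + demoted == k."""
    anchors = generate_anchors(5, 32, 416)
    gt = np.array([[100.0, 100.0, 180.0, 180.0]])  # 80x80 at a cell center
    match = uniform_match(gt, anchors, k=4)
    n_pos = int((match.labels == 1).sum())
    n_ign = int((match.labels == -1).sum())
    assert n_pos == 3  # the 256-px anchor claim has IoU < 0.15 and is demoted
    assert n_pos + n_ign >= 4
    assert (match.labels[match.gt_index >= 0] == 1).all()


def test_no_gt_all_negative():
    anchors = generate_anchors(5, 32, 416)
    match = uniform_match(np.zeros((0, 4)), anchors, k=4)
    assert (match.labels == 0).all()


def test_uniform_match_agrees_with_brute_force(rng):
    anchors = generate_anchors(5, 32, 416)
    for _ in range(10):
        ng = rng.integers(1, 8)
        xy = rng.uniform(0, 300, size=(ng, 2))
        wh = rng.uniform(20, 120, size=(ng, 2))
        gt = np.concatenate([xy, xy + wh], axis=1)
        match = uniform_match(gt, anchors, k=4)
        labels, gtidx = brute_force_match(gt, anchors, 4)
        np.testing.assert_array_equal(match.labels, labels)
        np.testing.assert_array_equal(match.gt_index, gtidx)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def test_focal_loss_scalar_value():
    # -0.25 * (1-0.5)^2 * log(0.5)
    val = focal_loss(np.array([0.5]), np.array([1.0]))
    assert val == pytest.approx(0.043322, abs=1e-6)


def test_focal_loss_vanishes_for_confident_positive():
    assert focal_loss(np.array([0.999999]), np.array([1.0])) < 1e-10


def test_focal_loss_reduces_to_cross_entropy():
    # gamma=0, alpha=1 on positive labels is plain cross-entropy
    p = np.array([0.3, 0.8])
    y = np.array([1.0, 1.0])
    ce = -(np.log(0.3) + np.log(0.8))
    assert focal_loss(p, y, alpha=1.0, gamma=0.0) == pytest.approx(ce, rel=1e-6)


def test_focal_loss_clamps_out_of_range_with_warning():
    with pytest.warns(UserWarning, match="clamping"):
        val = focal_loss(np.array([1.0]), np.array([1.0]))
    assert np.isfinite(val)


def test_giou_identical_boxes():
    b = np.array([[10.0, 10.0, 50.0, 60.0]])
    assert giou_loss(b, b) == pytest.approx(0.0, abs=1e-6)


def test_giou_disjoint_unit_boxes_hand_value():
    b1 = np.array([[0.0, 0.0, 1.0, 1.0]])
    b2 = np.array([[2.0, 2.0, 3.0, 3.0]])
    # enclosing area 9, union 2: 1 - (0 - 7/9) = 16/9
    assert giou_loss(b1, b2) == pytest.approx(16.0 / 9.0, rel=1e-6)


def test_giou_range(rng):
    xy = rng.uniform(0, 100, size=(200, 2))
    wh = rng.uniform(1, 50, size=(200, 2))
    b1 = np.concatenate([xy, xy + wh], axis=1)
    xy2 = rng.uniform(0, 100, size=(200, 2))
    wh2 = rng.uniform(1, 50, size=(200, 2))
    b2 = np.concatenate([xy2, xy2 + wh2], axis=1)
    for a, b in zip(b1, b2):
        val = giou_loss(a[None], b[None])
        assert 0.0 <= val <= 2.0


def test_giou_degenerate_box_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        giou_loss(np.array([[0.0, 0.0, 0.0, 1.0]]), np.array([[0.0, 0.0, 1.0, 1.0]]))


# ---------------------------------------------------------------------------
# NMS
# ---------------------------------------------------------------------------


def brute_force_nms(boxes, scores, thr):
    order = np.argsort(-scores, kind="stable")
    keep, suppressed = [], np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        for j in order:
            if j != i and not suppressed[j] and box_iou(boxes[i], boxes[j])[0, 0] > thr:
                suppressed[j] = True
    return np.asarray(keep)


def test_nms_identical_boxes_keep_highest_score():
    boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], dtype=float)
    keep = nms(boxes, np.array([0.6, 0.9]), 0.6)
    assert list(keep) == [1]


def test_nms_below_threshold_keeps_both():
    # IoU exactly 0.5 < 0.6 threshold
    boxes = np.array([[0, 0, 10, 20], [0, 10, 10, 30]], dtype=float)
    iou = box_iou(boxes[:1], boxes[1:])[0, 0]
    assert iou < 0.6
    assert len(nms(boxes, np.array([0.9, 0.8]), 0.6)) == 2


def test_nms_matches_brute_force_oracle(rng):
    xy = rng.uniform(0, 300, size=(200, 2))
    wh = rng.uniform(10, 120, size=(200, 2))
    boxes = np.concatenate([xy, xy + wh], axis=1)
    scores = rng.uniform(0, 1, size=200)
    keep = nms(boxes, scores, 0.6)
    expected = brute_force_nms(boxes, scores, 0.6)
    np.testing.assert_array_equal(np.sort(keep), np.sort(expected))
    # survivor pairwise IoU never exceeds the threshold
    surv = boxes[keep]
    iou = box_iou(surv, surv)
    np.fill_diagonal(iou, 0)
    assert iou.max() <= 0.6 + 1e-12


def test_nms_records_is_per_class():
    recs = [
        DetectionRecord(1, "RBC", 0.9, (0, 0, 10, 10)),
        DetectionRecord(1, "WBC", 0.8, (0, 0, 10, 10)),
        DetectionRecord(1, "RBC", 0.7, (1, 1, 10, 10)),
    ]
    kept = nms_records(recs, 0.6)
    cats = sorted(r.category for r in kept)
    assert cats == ["RBC", "WBC"]  # overlapping RBC suppressed, WBC untouched


def test_nms_invalid_threshold():
    with pytest.raises(ValueError):
        nms(np.zeros((1, 4)), np.zeros(1), 0.0)
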