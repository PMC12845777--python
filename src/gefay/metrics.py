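"""Detection metrics: IoU, greedy NMS, and mAP over an IoU sweep.

Average precision uses 101-point interpolation of the precision-recall
curve (the COCO convention), computed per class from a greedy
highest-score-first one-to-one matching of predictions to ground truths.
``mAP@0.5`` evaluates at IoU 0.5; ``mAP@0.5:0.95`` averages the ten
thresholds 0.5, 0.55, ..., 0.95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Detections", "box_iou", "nms", "evaluate_map", "MapResult",
           "IOU_GRID"]

IOU_GRID = np.round(np.arange(0.5, 1.0, 0.05), 2)  # 0.5 .. 0.95


@dataclass
class Detections:
    """Per-image detection set: pixel xyxy boxes, scores, class ids."""

    boxes: np.ndarray    # (n, 4) x1,y1,x2,y2
    scores: np.ndarray   # (n,)
    classes: np.ndarray  # (n,) int

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
        self.classes = np.asarray(self.classes, dtype=np.int64).reshape(-1)
        if not (len(self.boxes) == len(self.scores) == len(self.classes)):
            raise ValueError("boxes, scores and classes must have equal length")

    def __len__(self):
        return len(self.scores)

    @staticmethod
    def empty() -> "Detections":
        return Detections(np.zeros((0, 4)), np.zeros(0), np.zeros(0, dtype=int))


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two xyxy box sets, shape (len(a), len(b))."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.prod(np.clip(br - tl, 0, None), axis=2)
    area_a = np.prod(a[:, 2:] - a[:, :2], axis=1)
    area_b = np.prod(b[:, 2:] - b[:, :2], axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(dets: Detections, iou_thresh: float = 0.45,
        conf_thresh: float = 0.25) -> Detections:
    """Greedy per-class suppression by descending score.

    Survivors all score >= ``conf_thresh`` and no two surviving boxes of
    the same class overlap above ``iou_thresh``.  The result is sorted by
    descending score; idempotent.
    """
    if not 0 <= iou_thresh <= 1 or not 0 <= conf_thresh <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    keep_mask = dets.scores >= conf_thresh
    boxes, scores, classes = (dets.boxes[keep_mask], dets.scores[keep_mask],
                              dets.classes[keep_mask])
    order = np.argsort(-scores, kind="stable")
    boxes, scores, classes = boxes[order], scores[order], classes[order]
    keep: list[int] = []
    alive = np.ones(len(scores), dtype=bool)
    for i in range(len(scores)):
        if not alive[i]:
            continue
        keep.append(i)
        same = alive & (classes == classes[i])
        same[: i + 1] = False
        if same.any():
            ious = box_iou(boxes[i : i + 1], boxes[same])[0]
            dead = np.where(same)[0][ious > iou_thresh]
            alive[dead] = False
    return Detections(boxes[keep], scores[keep], classes[keep])


@dataclass
class MapResult:
    map50: float
    map50_95: float
    ap_per_class: dict[int, np.ndarray] = field(default_factory=dict)
    # class id -> AP at each threshold of the grid

    def as_dict(self) -> dict:
        return {"mAP@0.5": self.map50, "mAP@0.5:0.95": self.map50_95}


def _ap_101(recall: np.ndarray, precision: np.ndarray) -> float:
    """101-point interpolated area under the PR curve.

    At each recall point r the interpolated precision is
    ``max{precision_i : recall_i >= r}`` (0 when the recall never reaches
    r), averaged over r in {0, 0.01, ..., 1}.
    """
    if len(recall) == 0:
        return 0.0
    env = np.maximum.accumulate(precision[::-1])[::-1]
    points = np.linspace(0, 1, 101)
    idx = np.searchsorted(recall, points, side="left")
    vals = np.where(idx < len(recall), env[np.minimum(idx, len(recall) - 1)], 0.0)
    return float(np.mean(vals))


def _match_class(preds: list[Detections], truths: list[Detections],
                 cls: int, thresholds: np.ndarray):
    """Greedy one-to-one matching for one class; returns per-prediction
    scores and TP flags at each threshold, plus the gt count."""
    n_gt = 0
    scores_all: list[np.ndarray] = []
    tps_all: list[np.ndarray] = []
    for p, t in zip(preds, truths):
        gt_boxes = t.boxes[t.classes == cls]
        n_gt += len(gt_boxes)
        sel = p.classes == cls
        boxes, scores = p.boxes[sel], p.scores[sel]
        order = np.argsort(-scores, kind="stable")
        boxes, scores = boxes[order], scores[order]
        tp = np.zeros((len(scores), len(thresholds)), dtype=bool)
        if len(boxes) and len(gt_boxes):
            ious = box_iou(boxes, gt_boxes)
            for ti, thr in enumerate(thresholds):
                taken = np.zeros(len(gt_boxes), dtype=bool)
                for pi in range(len(boxes)):
                    cand = np.where(~taken & (ious[pi] >= thr))[0]
                    if len(cand):
                        best = cand[np.argmax(ious[pi, cand])]
                        taken[best] = True
                        tp[pi, ti] = True
        scores_all.append(scores)
        tps_all.append(tp)
    scores = np.concatenate(scores_all) if scores_all else np.zeros(0)
    tps = np.vstack(tps_all) if tps_all else np.zeros((0, len(thresholds)), bool)
    return scores, tps, n_gt


def evaluate_map(preds: list[Detections], truths: list[Detections],
                 iou_grid: np.ndarray = IOU_GRID) -> MapResult:
    """Dataset mAP@0.5 and mAP over the IoU grid (default 0.5:0.95)."""
    if len(preds) != len(truths):
        raise ValueError("preds and truths must cover the same images")
    iou_grid = np.asarray(iou_grid, dtype=np.float64)
    gt_classes = np.unique(np.concatenate([t.classes for t in truths])) \
        if truths else np.zeros(0, dtype=int)
    pred_classes = np.unique(np.concatenate([p.classes for p in preds])) \
        if preds else np.zeros(0, dtype=int)
    ap: dict[int, np.ndarray] = {}
    for cls in sorted(set(gt_classes) | set(pred_classes)):
        scores, tps, n_gt = _match_class(preds, truths, int(cls), iou_grid)
        if n_gt == 0:
            warnings.warn(f"class {cls} appears in predictions but has no "
                          f"ground truths; its AP counts as 0", stacklevel=2)
            ap[int(cls)] = np.zeros(len(iou_grid))
            continue
        order = np.argsort(-scores, kind="stable")
        tps = tps[order]
        aps = np.zeros(len(iou_grid))
        for ti in range(len(iou_grid)):
            tp_cum = np.cumsum(tps[:, ti])
            fp_cum = np.cumsum(~tps[:, ti])
            recall = tp_cum / n_gt
            precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
            aps[ti] = _ap_101(recall, precision)
        ap[int(cls)] = aps
    if not ap:
        return MapResult(0.0, 0.0, {})
    all_aps = np.stack(list(ap.values()))
    i50 = int(np.argmin(np.abs(iou_grid - 0.5)))
    return MapResult(float(all_aps[:, i50].mean()), float(all_aps.mean()), ap)
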