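"""Composite detection loss with anchor-based target assignment.

The assignment follows the single-stage family convention the detector
belongs to: a ground-truth box matches every anchor of a scale whose
width/height ratio satisfies ``max(r, 1/r) < 4``, and besides its own
grid cell it is also assigned to the two nearest neighbouring cells
(offset rule 0.5).  The loss is

``L = w_box * mean(1 - CIoU) + w_obj * BCE(objectness) + w_cls * BCE(class)``

with the objectness target at positive cells set to the (detached) CIoU
of the decoded prediction, and per-scale objectness balance weights.
A zero-object batch yields a finite loss with only the objectness term
active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .nn import bce_with_logits

__all__ = ["LossWeights", "ciou_xywh", "build_targets", "compute_loss"]


@dataclass(frozen=True)
class LossWeights:
    box: float = 0.05
    obj: float = 1.0
    cls: float = 0.5
    anchor_t: float = 4.0                     # wh-ratio matching threshold
    balance: tuple = (4.0, 1.0, 0.4)          # per-scale objectness weights


def ciou_xywh(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Complete IoU between predicted boxes (M,4 xywh, autograd) and fixed
    target boxes (M,4 xywh).  Returns a length-M tensor in (-1, 1]."""
    t = np.asarray(target, dtype=np.float32)
    px, py, pw, ph = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    tx, ty, tw, th = t[:, 0], t[:, 1], t[:, 2], t[:, 3]

    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    tx1, tx2 = tx - tw * 0.5, tx + tw * 0.5
    ty1, ty2 = ty - th * 0.5, ty + th * 0.5

    iw = px2.minimum(Tensor(tx2)) - px1.maximum(Tensor(tx1))
    ih = py2.minimum(Tensor(ty2)) - py1.maximum(Tensor(ty1))
    inter = iw.clamp(lo=0) * ih.clamp(lo=0)
    union = pw * ph + tw * th - inter + eps
    iou = inter / union

    # smallest enclosing box diagonal
    cw = px2.maximum(Tensor(tx2)) - px1.minimum(Tensor(tx1))
    ch = py2.maximum(Tensor(ty2)) - py1.minimum(Tensor(ty1))
    c2 = cw * cw + ch * ch + eps
    rho2 = (px - tx) ** 2 + (py - ty) ** 2

    # aspect-ratio consistency term
    v = (4.0 / math.pi ** 2) * ((Tensor(np.arctan(tw / np.maximum(th, eps)))
                                 - (pw / (ph + eps)).atan()) ** 2)
    alpha = (v / (1.0 - iou + v + eps)).detach()
    return iou - rho2 / c2 - alpha * v


def build_targets(targets: np.ndarray, anchors: np.ndarray, strides,
                  grids: list[tuple[int, int]], batch_size: int,
                  anchor_t: float = 4.0):
    """Assign normalized labels to (scale, image, anchor, cell) positions.

    ``targets`` is (M, 6): image index, class, cx, cy, w, h (all in [0,1]).
    Returns, per scale: index arrays (b, a, gj, gi), the target boxes in
    grid units (dx, dy relative to the cell corner in [-0.5, 1.5], w, h),
    the matched anchor wh in grid units, and the class ids.
    """
    targets = np.asarray(targets, dtype=np.float32).reshape(-1, 6)
    out = []
    offs = np.array([[0, 0], [-1, 0], [1, 0], [0, -1], [0, 1]], dtype=np.float32)
    for si, (stride, (gh, gw)) in enumerate(zip(strides, grids)):
        anc = anchors[si] / stride  # (na, 2) in grid units
        na = len(anc)
        if len(targets) == 0:
            out.append((np.zeros(0, int), np.zeros(0, int), np.zeros(0, int),
                        np.zeros(0, int), np.zeros((0, 4), np.float32),
                        np.zeros((0, 2), np.float32), np.zeros(0, int)))
            continue
        t = targets.copy()
        t[:, 2] *= gw
        t[:, 4] *= gw
        t[:, 3] *= gh
        t[:, 5] *= gh
        # anchor matching by wh ratio
        rep = np.repeat(t[None], na, axis=0)                 # (na, M, 6)
        ai = np.repeat(np.arange(na)[:, None], len(t), axis=1)
        r = rep[..., 4:6] / anc[:, None, :]
        keep = np.maximum(r, 1.0 / r).max(axis=2) < anchor_t  # (na, M)
        t_m = rep[keep]
        a_m = ai[keep]
        if len(t_m) == 0:
            out.append((np.zeros(0, int), np.zeros(0, int), np.zeros(0, int),
                        np.zeros(0, int), np.zeros((0, 4), np.float32),
                        np.zeros((0, 2), np.float32), np.zeros(0, int)))
            continue
        # neighbouring-cell expansion
        gxy = t_m[:, 2:4]
        fx, fy = gxy[:, 0] % 1.0, gxy[:, 1] % 1.0
        sel = [np.ones(len(t_m), bool),
               (fx < 0.5) & (gxy[:, 0] > 1.0),
               (fx >= 0.5) & (gxy[:, 0] < gw - 1.0),
               (fy < 0.5) & (gxy[:, 1] > 1.0),
               (fy >= 0.5) & (gxy[:, 1] < gh - 1.0)]
        t_all, a_all, off_all = [], [], []
        for off, m in zip(offs, sel):
            t_all.append(t_m[m])
            a_all.append(a_m[m])
            off_all.append(np.broadcast_to(off, (int(m.sum()), 2)))
        t_m = np.concatenate(t_all)
        a_m = np.concatenate(a_all)
        off = np.concatenate(off_all)
        cell = np.floor(t_m[:, 2:4] + off * 0.5).astype(int)
        gi = np.clip(cell[:, 0], 0, gw - 1)
        gj = np.clip(cell[:, 1], 0, gh - 1)
        b = t_m[:, 0].astype(int)
        cls = t_m[:, 1].astype(int)
        dxy = t_m[:, 2:4] - cell  # in [-0.5, 1.5]
        tbox = np.concatenate([dxy, t_m[:, 4:6]], axis=1).astype(np.float32)
        out.append((b, a_m, gj, gi, tbox, anc[a_m].astype(np.float32), cls))
    return out


def compute_loss(preds: list[Tensor], targets: np.ndarray, anchors: np.ndarray,
                 strides, nc: int, weights: LossWeights = LossWeights()):
    """Total loss plus (box, obj, cls) components as floats."""
    batch = preds[0].shape[0]
    grids = [(p.shape[2], p.shape[3]) for p in preds]
    assigned = build_targets(targets, anchors, strides, grids, batch,
                             weights.anchor_t)
    lbox = Tensor(0.0)
    lobj = Tensor(0.0)
    lcls = Tensor(0.0)
    n_pos = 0
    for si, (p, (b, a, gj, gi, tbox, anc, cls)) in enumerate(zip(preds, assigned)):
        tobj = np.zeros(p.shape[:4], dtype=np.float32)
        if len(b):
            n_pos += len(b)
            ps = p[b, a, gj, gi]  # (M, 5+nc)
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(anc)
            pbox = concat([pxy, pwh], axis=1)
            iou = ciou_xywh(pbox, tbox)
            lbox = lbox + (1.0 - iou).mean()
            tobj[b, a, gj, gi] = np.clip(iou.data, 0, None)
            if nc > 1:
                tcls = np.zeros((len(b), nc), dtype=np.float32)
                tcls[np.arange(len(b)), cls] = 1.0
                lcls = lcls + bce_with_logits(ps[:, 5:], tcls).mean()
        lobj = lobj + bce_with_logits(p[:, :, :, :, 4], tobj).mean() \
            * weights.balance[si]
    # batch-size scaling: per-image gradient magnitude independent of batch
    loss = (weights.box * lbox + weights.obj * lobj + weights.cls * lcls) * batch
    parts = {"box": float(lbox.data), "obj": float(lobj.data),
             "cls": float(lcls.data), "n_pos": n_pos}
    return loss, parts
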