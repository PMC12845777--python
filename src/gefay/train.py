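"""Desk-scale training and evaluation harness.

Defaults mirror the study conditions: 300 epochs, batch size 40, SGD with
learning rate 0.01 and momentum 0.937, early stopping with a patience of
100 epochs, 640x640 inputs.  The best checkpoint is selected by
validation mAP@0.5.  With a fixed seed and a single thread, two runs
produce identical histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor, no_grad
from .data import DetectionDataset
from .loss import LossWeights, compute_loss
from .metrics import Detections, MapResult, evaluate_map, nms
from .model import Detector
from .nn import SGD

__all__ = ["TrainConfig", "train", "evaluate", "predict_image", "TrainResult"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    batch_size: int = 40
    lr: float = 0.01
    momentum: float = 0.937
    optimizer: str = "sgd"
    early_stop_patience: int = 100
    image_size: int = 640
    seed: int = 0
    weight_decay: float = 0.0005
    warmup_steps: int = 50
    augment: bool = True
    conf_thresh: float = 0.001    # evaluation-time confidence floor
    iou_thresh: float = 0.45      # evaluation-time NMS threshold
    eval_every: int = 1           # validate every k-th epoch
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.lr <= 0 or self.momentum < 0:
            raise ValueError("epochs, batch_size, lr and momentum must be positive")
        if self.early_stop_patience > self.epochs:
            raise ValueError("patience must not exceed epochs")
        if self.optimizer != "sgd":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainResult:
    best_state: dict
    best_map50: float
    best_epoch: int
    history: list[dict]
    stopped_early: bool


def predict_image(model: Detector, img: np.ndarray, conf_thresh: float = 0.25,
                  iou_thresh: float = 0.45, max_det: int = 300) -> Detections:
    """Run one image (3,S,S) through the model, decode and apply NMS."""
    scales = model.predict(img[None])
    nc = model.detect.nc
    rows = np.concatenate([s[0] for s in scales], axis=0)  # (M, 5+nc)
    obj = rows[:, 4]
    cls_scores = rows[:, 5:] * obj[:, None] if nc > 1 else obj[:, None]
    cls = cls_scores.argmax(axis=1)
    score = cls_scores.max(axis=1)
    keep = score >= conf_thresh
    xywh = rows[keep, :4]
    boxes = np.stack([xywh[:, 0] - xywh[:, 2] / 2, xywh[:, 1] - xywh[:, 3] / 2,
                      xywh[:, 0] + xywh[:, 2] / 2, xywh[:, 1] + xywh[:, 3] / 2],
                     axis=1)
    dets = nms(Detections(boxes, score[keep], cls[keep]),
               iou_thresh=iou_thresh, conf_thresh=conf_thresh)
    if len(dets) > max_det:
        dets = Detections(dets.boxes[:max_det], dets.scores[:max_det],
                          dets.classes[:max_det])
    return dets


def evaluate(model: Detector, dataset: DetectionDataset,
             conf_thresh: float = 0.001, iou_thresh: float = 0.45) -> MapResult:
    """mAP@0.5 and mAP@0.5:0.95 of the model on one dataset split."""
    preds, truths = [], []
    for i in range(len(dataset)):
        img, _ = dataset.load(i)
        preds.append(predict_image(model, img, conf_thresh, iou_thresh))
        boxes, classes = dataset.ground_truth(i)
        truths.append(Detections(boxes, np.ones(len(classes)), classes))
    return evaluate_map(preds, truths)


def train(model: Detector, data_root: str | Path, cfg: TrainConfig,
          val_split: str = "val", train_split: str = "train",
          log=None) -> TrainResult:
    """SGD training with best-epoch checkpointing and early stopping."""
    train_ds = DetectionDataset(data_root, train_split, cfg.image_size)
    try:
        val_ds = DetectionDataset(data_root, val_split, cfg.image_size)
    except ValueError:
        val_ds = train_ds
    if model.detect.nc != train_ds.nc:
        raise ValueError(f"model has nc={model.detect.nc} but dataset "
                         f"declares nc={train_ds.nc}")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    anchors = model.detect.anchors
    strides = model.strides
    nc = model.detect.nc

    history: list[dict] = []
    best = TrainResult(model.state_dict(), -1.0, -1, history, False)
    since_best = 0
    step = 0
    for epoch in range(cfg.epochs):
        model.train()
        losses = []
        for imgs, targets in train_ds.batches(cfg.batch_size, rng,
                                              augment=cfg.augment):
            step += 1
            if step <= cfg.warmup_steps:
                opt.lr = cfg.lr * step / cfg.warmup_steps
            preds = model.forward(Tensor(imgs))
            loss, parts = compute_loss(preds, targets, anchors, strides, nc,
                                       cfg.loss_weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if (epoch + 1) % cfg.eval_every and epoch != cfg.epochs - 1:
            history.append(entry)
            if log:
                log(entry)
            continue
        res = evaluate(model, val_ds, cfg.conf_thresh, cfg.iou_thresh)
        entry.update({"val_map50": res.map50, "val_map50_95": res.map50_95})
        history.append(entry)
        if log:
            log(entry)
        if res.map50 > best.best_map50:
            best.best_state = model.state_dict()
            best.best_map50 = res.map50
            best.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                best.stopped_early = True
                break
    best.history = history
    return best
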