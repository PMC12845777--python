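"""Dataset reading: YOLO-format labels, image loading, light augmentation.

Layout convention: ``images/{split}/*.png|jpg`` with matching
``labels/{split}/*.txt`` (one ``class cx cy w h`` line per object,
normalized to [0,1], 0-based class ids) and a ``data.yaml`` naming the
classes.  Malformed labels raise :class:`LabelError` naming the file and
line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = ["LabelError", "DetectionDataset", "read_labels", "load_image"]

IMG_SUFFIXES = (".png", ".jpg", ".jpeg")


class LabelError(ValueError):
    pass


def read_labels(path: str | Path, nc: int | None = None) -> np.ndarray:
    """Parse one YOLO label file to an (n, 5) array [cls, cx, cy, w, h]."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise LabelError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            try:
                cls = int(parts[0])
                vals = [float(v) for v in parts[1:]]
            except ValueError as e:
                raise LabelError(f"{path}:{ln}: {e}") from None
            if cls < 0 or (nc is not None and cls >= nc):
                raise LabelError(f"{path}:{ln}: class id {cls} out of range")
            if not all(0.0 <= v <= 1.0 for v in vals):
                raise LabelError(f"{path}:{ln}: coordinate outside [0, 1]")
            if vals[2] <= 0 or vals[3] <= 0:
                raise LabelError(f"{path}:{ln}: non-positive box size")
            rows.append([cls, *vals])
    return np.array(rows, dtype=np.float32).reshape(-1, 5)


def load_image(path: str | Path, size: int) -> np.ndarray:
    """Load an RGB image resized to (3, size, size), values in [0, 1]."""
    with Image.open(path) as im:
        im = im.convert("RGB").resize((size, size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32) / 255.0
    return arr.transpose(2, 0, 1)


@dataclass
class DatasetInfo:
    root: Path
    nc: int
    names: list[str]


class DetectionDataset:
    """One split of a detection dataset."""

    def __init__(self, root: str | Path, split: str = "train",
                 image_size: int = 640):
        self.root = Path(root)
        self.split = split
        self.image_size = image_size
        meta_path = self.root / "data.yaml"
        if not meta_path.exists():
            raise FileNotFoundError(f"no data.yaml under {self.root}")
        meta = yaml.safe_load(meta_path.read_text())
        self.nc = int(meta["nc"])
        self.names = list(meta.get("names", range(self.nc)))
        img_dir = self.root / "images" / split
        self.items: list[tuple[Path, Path]] = []
        for img in sorted(img_dir.glob("*")):
            if img.suffix.lower() in IMG_SUFFIXES:
                lbl = self.root / "labels" / split / (img.stem + ".txt")
                self.items.append((img, lbl))
        if not self.items:
            raise ValueError(f"empty dataset split {split!r} under {self.root}")

    def __len__(self):
        return len(self.items)

    def load(self, i: int, augment: bool = False,
             rng: np.random.Generator | None = None):
        """Returns (image (3,S,S) float32, labels (n,5))."""
        img_path, lbl_path = self.items[i]
        img = load_image(img_path, self.image_size)
        labels = read_labels(lbl_path, self.nc) if lbl_path.exists() \
            else np.zeros((0, 5), np.float32)
        if augment and rng is not None:
            img, labels = _augment(img, labels, rng)
        return img, labels

    def batches(self, batch_size: int, rng: np.random.Generator | None = None,
                augment: bool = False):
        """Yield (images (B,3,S,S), targets (M,6)) with image-index column."""
        order = np.arange(len(self))
        if rng is not None:
            rng.shuffle(order)
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            imgs, tgts = [], []
            for bi, i in enumerate(idx):
                img, labels = self.load(int(i), augment=augment, rng=rng)
                imgs.append(img)
                if len(labels):
                    tgts.append(np.concatenate(
                        [np.full((len(labels), 1), bi, np.float32), labels], axis=1))
            targets = np.concatenate(tgts) if tgts else np.zeros((0, 6), np.float32)
            yield np.stack(imgs), targets

    def ground_truth(self, i: int):
        """Labels of image ``i`` as pixel-space xyxy boxes + classes."""
        _, lbl_path = self.items[i]
        labels = read_labels(lbl_path, self.nc) if lbl_path.exists() \
            else np.zeros((0, 5), np.float32)
        s = self.image_size
        boxes = np.stack([
            (labels[:, 1] - labels[:, 3] / 2) * s,
            (labels[:, 2] - labels[:, 4] / 2) * s,
            (labels[:, 1] + labels[:, 3] / 2) * s,
            (labels[:, 2] + labels[:, 4] / 2) * s,
        ], axis=1) if len(labels) else np.zeros((0, 4), np.float32)
        return boxes, labels[:, 0].astype(int)


def _augment(img: np.ndarray, labels: np.ndarray, rng: np.random.Generator):
    """Horizontal flip + mild scale jitter (paste on mean-colour canvas)."""
    if rng.random() < 0.5:
        img = img[:, :, ::-1].copy()
        if len(labels):
            labels = labels.copy()
            labels[:, 1] = 1.0 - labels[:, 1]
    s = img.shape[1]
    factor = rng.uniform(0.8, 1.2)
    new = max(32, int(round(s * factor)))
    if new != s:
        pil = Image.fromarray((img.transpose(1, 2, 0) * 255).astype(np.uint8))
        pil = pil.resize((new, new), Image.BILINEAR)
        resized = np.asarray(pil, dtype=np.float32).transpose(2, 0, 1) / 255.0
        canvas = np.full_like(img, img.mean(axis=(1, 2), keepdims=True))
        if new < s:
            off = int(rng.integers(0, s - new + 1))
            canvas[:, off : off + new, off : off + new] = resized
            scale, shift = new / s, off / s
        else:
            off = int(rng.integers(0, new - s + 1))
            canvas = resized[:, off : off + s, off : off + s]
            scale, shift = new / s, -off / s
        img = canvas
        if len(labels):
            labels = labels.copy()
            labels[:, 1] = labels[:, 1] * scale + shift
            labels[:, 2] = labels[:, 2] * scale + shift
            labels[:, 3] *= scale
            labels[:, 4] *= scale
            # clip boxes to the visible canvas, drop the vanished
            x1 = np.clip(labels[:, 1] - labels[:, 3] / 2, 0, 1)
            x2 = np.clip(labels[:, 1] + labels[:, 3] / 2, 0, 1)
            y1 = np.clip(labels[:, 2] - labels[:, 4] / 2, 0, 1)
            y2 = np.clip(labels[:, 2] + labels[:, 4] / 2, 0, 1)
            labels[:, 1], labels[:, 2] = (x1 + x2) / 2, (y1 + y2) / 2
            labels[:, 3], labels[:, 4] = x2 - x1, y2 - y1
            labels = labels[(labels[:, 3] > 0.01) & (labels[:, 4] > 0.01)]
    return img, labels
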