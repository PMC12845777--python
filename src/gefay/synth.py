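"""Deterministic synthetic "field" scenes with labelled pseudo-weed instances.

The generator emulates the shape of a cotton-field weed detection task:
12 object classes, cluttered vegetation-like backgrounds, variable object
scale, YOLO-format plain-text labels, and a 7:2:1 train/val/test split.
Each class is a procedurally drawn leaf rosette with a class-specific
lobe count and hue, so classes are visually separable but share the
background statistics.  Labels are derived from the rendered ownership
mask, so every label box equals the visible extent of its object exactly.

Identical :class:`SceneSpec` values produce byte-identical datasets.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

__all__ = ["SceneSpec", "generate", "SPLITS"]

SPLITS = ("train", "val", "test")
_SPLIT_RATIO = (0.7, 0.2, 0.1)


@dataclass(frozen=True)
class SceneSpec:
    """Conditions of the synthetic scenes."""

    image_size: int = 640
    n_images: int = 30
    n_classes: int = 12
    min_objects: int = 1
    max_objects: int = 4
    min_scale: float = 0.12           # object diameter as a fraction of image
    max_scale: float = 0.35
    clutter: float = 0.5              # background texture strength in [0, 1]
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.n_images < 1:
            raise ValueError("n_classes and n_images must be >= 1")
        if not (0 < self.min_scale <= self.max_scale < 1):
            raise ValueError("scale range must satisfy 0 < min <= max < 1")
        if self.min_objects < 0 or self.max_objects < self.min_objects:
            raise ValueError("invalid objects_per_image range")


def _class_style(cls: int, n_classes: int):
    """Lobe count and base RGB hue for a class."""
    lobes = 3 + (cls % 10)
    hue = cls / max(n_classes, 1)
    # leaf-ish palette: greens through yellow-browns and purples
    r = 0.35 + 0.55 * abs(math.sin(math.pi * (hue + 0.15)))
    g = 0.45 + 0.5 * abs(math.sin(math.pi * (hue + 0.55)))
    b = 0.2 + 0.6 * abs(math.sin(math.pi * (hue + 0.85)))
    return lobes, tuple(int(255 * v) for v in (r, g, b))


def _background(rng: np.random.Generator, size: int, clutter: float) -> np.ndarray:
    """Soil + vegetation texture: coarse noise upsampled over a brown base."""
    base = np.array([92, 76, 52], dtype=np.float64)
    coarse = rng.normal(0, 1, (size // 16 + 1, size // 16 + 1, 3))
    idx = np.linspace(0, coarse.shape[0] - 1, size)
    xi = idx.astype(int)
    smooth = coarse[xi][:, xi]
    fine = rng.normal(0, 1, (size, size, 3))
    img = base + clutter * (34 * smooth + 10 * fine)
    # sparse grass streaks
    n_str = int(clutter * size * size / 3000)
    ys = rng.integers(0, size, n_str)
    xs = rng.integers(0, size, n_str)
    ls = rng.integers(4, 18, n_str)
    for y, x, l in zip(ys, xs, ls):
        img[y, x : min(x + l, size), 1] += 28
    return np.clip(img, 0, 255).astype(np.uint8)


def _rosette_polygon(rng: np.random.Generator, cx: float, cy: float,
                     radius: float, lobes: int) -> list[tuple[float, float]]:
    """Star-like leaf rosette: alternating outer/inner vertices with jitter."""
    phase = rng.uniform(0, 2 * math.pi)
    pts = []
    for i in range(2 * lobes):
        ang = phase + math.pi * i / lobes
        r = radius if i % 2 == 0 else radius * rng.uniform(0.35, 0.55)
        r *= rng.uniform(0.9, 1.1)
        pts.append((cx + r * math.cos(ang), cy + r * math.sin(ang)))
    return pts


def _render_scene(rng: np.random.Generator, spec: SceneSpec):
    """Returns the RGB image array, the YOLO label rows, and the pixel
    ownership map (object index per pixel, -1 for background)."""
    s = spec.image_size
    img = _background(rng, s, spec.clutter)
    owner = np.full((s, s), -1, dtype=np.int32)
    shades = []
    n_obj = int(rng.integers(spec.min_objects, spec.max_objects + 1))
    for oi in range(n_obj):
        cls = int(rng.integers(spec.n_classes))
        lobes, color = _class_style(cls, spec.n_classes)
        radius = 0.5 * s * rng.uniform(spec.min_scale, spec.max_scale)
        cx = rng.uniform(radius, s - radius)
        cy = rng.uniform(radius, s - radius)
        mask_img = Image.new("1", (s, s), 0)
        ImageDraw.Draw(mask_img).polygon(
            _rosette_polygon(rng, cx, cy, radius, lobes), fill=1)
        mask = np.array(mask_img, dtype=bool)
        owner[mask] = oi
        jitter = rng.integers(-25, 26, 3)
        shades.append((cls, np.clip(np.array(color) + jitter, 0, 255)))
    labels = []
    for oi, (cls, color) in enumerate(shades):
        vis = owner == oi
        if vis.sum() < 24:     # fully/mostly occluded: drop the object
            owner[vis] = -1
            continue
        img[vis] = (0.85 * color + 0.15 * img[vis]).astype(np.uint8)
        ys, xs = np.nonzero(vis)
        x0, x1 = xs.min(), xs.max() + 1
        y0, y1 = ys.min(), ys.max() + 1
        labels.append((cls, (x0 + x1) / 2 / s, (y0 + y1) / 2 / s,
                       (x1 - x0) / s, (y1 - y0) / s))
    return img, labels, owner


def _split_of(index: int, n_images: int) -> str:
    train_end = int(round(_SPLIT_RATIO[0] * n_images))
    val_end = train_end + int(round(_SPLIT_RATIO[1] * n_images))
    if index < train_end:
        return "train"
    return "val" if index < val_end else "test"


def generate(spec: SceneSpec, out_dir: str | Path, split: bool = True) -> Path:
    """Write the dataset (images/{split}/*.png, labels/{split}/*.txt,
    data.yaml) under ``out_dir`` and return its path.

    With ``split=False`` every image lands in the train split (used for
    overfit-style diagnostics); otherwise the 7:2:1 ratio applies.
    """
    out = Path(out_dir)
    for s in SPLITS:
        (out / "images" / s).mkdir(parents=True, exist_ok=True)
        (out / "labels" / s).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    for i in range(spec.n_images):
        img, labels, _ = _render_scene(rng, spec)
        split_name = _split_of(i, spec.n_images) if split else "train"
        name = f"scene_{i:05d}"
        Image.fromarray(img).save(out / "images" / split_name / f"{name}.png")
        with open(out / "labels" / split_name / f"{name}.txt", "w") as fh:
            for cls, cx, cy, w, h in labels:
                fh.write(f"{cls} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n")
    names = [f"weed_{i:02d}" for i in range(spec.n_classes)]
    with open(out / "data.yaml", "w") as fh:
        fh.write(f"path: {out.resolve()}\n")
        fh.write("train: images/train\nval: images/val\ntest: images/test\n")
        fh.write(f"nc: {spec.n_classes}\n")
        fh.write("names: [" + ", ".join(names) + "]\n")
    return out


def dataset_checksum(root: str | Path) -> str:
    """SHA-256 over every image and label file (order-stable)."""
    h = hashlib.sha256()
    for path in sorted(Path(root).rglob("*")):
        if path.suffix in (".png", ".txt", ".yaml"):
            h.update(path.name.encode())
            if path.name != "data.yaml":  # data.yaml embeds the absolute path
                h.update(path.read_bytes())
    return h.hexdigest()
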