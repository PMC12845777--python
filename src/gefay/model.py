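"""Declarative construction of the detector graph.

The layout is the v6-generation single-stage design: a 6x6 stride-2 stem
convolution, four conv/C3 backbone stages, SPPF, a PANet neck (two
top-down and two bottom-up paths) and a three-scale head.  Base channel
widths {64,128,256,512,1024} are scaled by ``width_multiple`` and rounded
to the nearest multiple of 8; bottleneck repeat counts are scaled by
``depth_multiple`` as ``max(1, round(n * depth))``.

Attention is inserted at named C3 slots: backbone ``P2..P5`` and neck
``N1..N4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .attention import AttentionSpec
from .autograd import Tensor, no_grad
from .blocks import SPPF, AttentionC3, ConvBlock, Detect

__all__ = ["ModelSpec", "LayerRecord", "Detector", "build_model",
           "make_divisible", "DEFAULT_ANCHORS", "BACKBONE_SLOTS", "NECK_SLOTS",
           "ALL_SLOTS"]

DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),      # stride 8
    ((30, 61), (62, 45), (59, 119)),     # stride 16
    ((116, 90), (156, 198), (373, 326)), # stride 32
)

BACKBONE_SLOTS = ("P2", "P3", "P4", "P5")
NECK_SLOTS = ("N1", "N2", "N3", "N4")
ALL_SLOTS = BACKBONE_SLOTS + NECK_SLOTS


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(round(x / divisor) * divisor))


@dataclass(frozen=True)
class ModelSpec:
    """Full description of a detector variant."""

    nc: int = 12
    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    input_size: int = 640
    anchors: tuple = DEFAULT_ANCHORS
    attention: AttentionSpec = field(default_factory=AttentionSpec)
    attention_placement: tuple[str, ...] = ALL_SLOTS

    def __post_init__(self):
        if self.nc < 1:
            raise ValueError("nc must be >= 1")
        if self.depth_multiple <= 0 or self.width_multiple <= 0:
            raise ValueError("depth/width multipliers must be positive")
        bad = [s for s in self.attention_placement if s not in ALL_SLOTS]
        if bad:
            raise ValueError(f"unknown attention slots {bad}; valid: {ALL_SLOTS}")

    def with_(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


@dataclass
class LayerRecord:
    index: int
    name: str
    kind: str
    from_: tuple[int, ...]
    in_channels: int
    out_channels: int
    kernel: int
    stride: int
    repeats: int
    out_size: int  # spatial side length at spec.input_size
    params: int = 0


# graph rows: (from, kind, base_args); channels in base (width-1.0) units
_GRAPH = [
    (-1, "conv", dict(c=64, k=6, s=2, p=2)),                 # 0  P1/2
    (-1, "conv", dict(c=128, k=3, s=2)),                     # 1  P2/4
    (-1, "c3", dict(c=128, n=3, slot="P2")),                 # 2
    (-1, "conv", dict(c=256, k=3, s=2)),                     # 3  P3/8
    (-1, "c3", dict(c=256, n=6, slot="P3")),                 # 4
    (-1, "conv", dict(c=512, k=3, s=2)),                     # 5  P4/16
    (-1, "c3", dict(c=512, n=9, slot="P4")),                 # 6
    (-1, "conv", dict(c=1024, k=3, s=2)),                    # 7  P5/32
    (-1, "c3", dict(c=1024, n=3, slot="P5")),                # 8
    (-1, "sppf", dict(c=1024, k=5)),                         # 9
    (-1, "conv", dict(c=512, k=1, s=1)),                     # 10
    (-1, "upsample", {}),                                    # 11
    ((-1, 6), "concat", {}),                                 # 12
    (-1, "c3", dict(c=512, n=3, shortcut=False, slot="N1")), # 13
    (-1, "conv", dict(c=256, k=1, s=1)),                     # 14
    (-1, "upsample", {}),                                    # 15
    ((-1, 4), "concat", {}),                                 # 16
    (-1, "c3", dict(c=256, n=3, shortcut=False, slot="N2")), # 17 P3 out
    (-1, "conv", dict(c=256, k=3, s=2)),                     # 18
    ((-1, 14), "concat", {}),                                # 19
    (-1, "c3", dict(c=512, n=3, shortcut=False, slot="N3")), # 20 P4 out
    (-1, "conv", dict(c=512, k=3, s=2)),                     # 21
    ((-1, 10), "concat", {}),                                # 22
    (-1, "c3", dict(c=1024, n=3, shortcut=False, slot="N4")),# 23 P5 out
    ((17, 20, 23), "head", {}),                              # 24
]


class Detector(nn.Module):
    """The assembled model graph; forward yields raw per-scale predictions."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        self.strides = (8, 16, 32)
        rng = np.random.default_rng(seed)
        gw, gd = spec.width_multiple, spec.depth_multiple
        none_spec = spec.attention.with_(variant="none")

        layers: list[nn.Module] = []
        records: list[LayerRecord] = []
        froms: list[tuple[int, ...]] = []
        ch: list[int] = []   # output channels per layer
        sz: list[int] = []   # output side length per layer
        for i, (frm, kind, args) in enumerate(_GRAPH):
            frm = (frm,) if isinstance(frm, int) else tuple(frm)
            frm = tuple(f if f >= 0 else i + f for f in frm)
            c_in = 3 if i == 0 else ch[frm[0]]
            size_in = spec.input_size if i == 0 else sz[frm[0]]
            kernel = stride = repeats = 1
            if kind == "conv":
                c_out = make_divisible(args["c"] * gw)
                kernel, stride = args["k"], args["s"]
                mod = ConvBlock(c_in, c_out, kernel, stride, p=args.get("p"), rng=rng)
                size_out = size_in // stride
            elif kind == "c3":
                c_out = make_divisible(args["c"] * gw)
                repeats = max(1, round(args["n"] * gd))
                slot = args["slot"]
                attn = spec.attention if slot in spec.attention_placement else none_spec
                mod = AttentionC3(c_in, c_out, repeats, args.get("shortcut", True),
                                  spec=attn, rng=rng)
                kind = "attnc3" if attn.variant != "none" else "c3"
                size_out = size_in
            elif kind == "sppf":
                c_out = make_divisible(args["c"] * gw)
                kernel = args["k"]
                mod = SPPF(c_in, c_out, kernel, rng=rng)
                size_out = size_in
            elif kind == "upsample":
                c_out = c_in
                mod = nn.UpsampleNearest2x()
                size_out = size_in * 2
            elif kind == "concat":
                sizes = {sz[f] for f in frm}
                if len(sizes) != 1:
                    raise ValueError(
                        f"layer {i}: concat inputs have mismatched sizes {sizes}")
                c_out = sum(ch[f] for f in frm)
                mod = nn.Identity()  # concat handled in forward
                size_out = sizes.pop()
            elif kind == "head":
                head_ch = tuple(ch[f] for f in frm)
                anchors = np.asarray(spec.anchors, dtype=np.float32)
                mod = Detect(spec.nc, head_ch, anchors, self.strides, rng=rng)
                c_out = 3 * (spec.nc + 5)
                size_out = sz[frm[0]]
            else:  # pragma: no cover
                raise ValueError(f"unknown layer kind {kind!r}")
            layers.append(mod)
            froms.append(frm)
            ch.append(c_out)
            sz.append(size_out)
            records.append(LayerRecord(
                index=i, name=f"{kind}_{i}", kind=kind, from_=frm,
                in_channels=c_in, out_channels=c_out, kernel=kernel,
                stride=stride, repeats=repeats, out_size=size_out,
                params=mod.num_parameters()))

        self.layers = nn.ModuleList(layers)
        self.froms = froms
        self.layer_records = records
        # indices whose outputs are reused later
        needed = {f for i, frm in enumerate(froms) for f in frm if f != i - 1}
        self.save = sorted(needed)

    @property
    def detect(self) -> Detect:
        return self.layers[-1]

    # -- execution ---------------------------------------------------------

    def forward(self, x) -> list[Tensor]:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}x{w} must be divisible by 32")
        saved: dict[int, Tensor] = {}
        y = x
        from .autograd import concat as _cat
        for i, (mod, frm) in enumerate(zip(self.layers, self.froms)):
            kind = self.layer_records[i].kind
            if kind == "concat":
                y = _cat([y if f == i - 1 else saved[f] for f in frm], axis=1)
            elif kind == "head":
                y = mod([saved.get(f) if f != i - 1 else y for f in frm])
            else:
                y = mod(y if frm[0] == i - 1 else saved[frm[0]])
            if i in self.save:
                saved[i] = y
        return y

    def predict(self, x) -> list[np.ndarray]:
        """Inference forward returning decoded (n, -1, 5+nc) arrays per scale."""
        self.eval()
        with no_grad():
            raw = self.forward(x)
        return [decode_scale(r.data, self.detect.anchors[s], self.strides[s])
                for s, r in enumerate(raw)]

    def table(self) -> str:
        """TSV export of the layer records."""
        cols = ["index", "name", "kind", "from", "c_in", "c_out", "k", "s",
                "n", "out_size", "params"]
        lines = ["\t".join(cols)]
        for r in self.layer_records:
            lines.append("\t".join(map(str, (
                r.index, r.name, r.kind, ",".join(map(str, r.from_)),
                r.in_channels, r.out_channels, r.kernel, r.stride,
                r.repeats, r.out_size, r.params))))
        return "\n".join(lines)


def decode_scale(raw: np.ndarray, anchors: np.ndarray, stride: float) -> np.ndarray:
    """Decode one scale's raw logits (n,na,h,w,5+nc) to pixel-space
    ``(n, na*h*w, 5+nc)`` with xywh boxes, objectness and class scores."""
    n, na, h, w, no = raw.shape
    from .autograd import _sigmoid
    s = _sigmoid(raw)
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    grid = np.stack([gx, gy], axis=-1).astype(np.float32)  # (h, w, 2)
    xy = (s[..., 0:2] * 2.0 - 0.5 + grid) * stride
    wh = (s[..., 2:4] * 2.0) ** 2 * anchors[:, None, None, :]
    out = np.concatenate([xy, wh, s[..., 4:]], axis=-1)
    return out.reshape(n, na * h * w, no)


def build_model(spec: ModelSpec, seed: int = 0) -> Detector:
    """Build the detector; identical specs and seeds give identical weights."""
    return Detector(spec, seed=seed)
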