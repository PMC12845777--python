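"""Building blocks of the single-stage detector.

``ConvBlock`` (conv + batch norm + SiLU), ``Bottleneck``, the
cross-stage-partial ``C3`` block, ``AttentionC3`` (a C3 whose output
passes through a pluggable attention operator), fast spatial pyramid
pooling (``SPPF``) and the three-scale ``Detect`` head.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .attention import AttentionSpec, build_attention
from .autograd import Tensor, concat

__all__ = ["ConvBlock", "Bottleneck", "C3", "AttentionC3", "SPPF", "Detect"]


class ConvBlock(nn.Module):
    """Bias-free convolution, batch normalization, SiLU."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, p, rng=rng)
        self.bn = nn.BatchNorm2d(c2)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


class Bottleneck(nn.Module):
    """1x1 then 3x3 convolution, with a residual when shapes allow."""

    def __init__(self, c1: int, c2: int, shortcut: bool = True, e: float = 1.0, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBlock(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBlock(c_, c2, 3, 1, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(nn.Module):
    """Cross-stage-partial block: two half-width entry branches, a stack of
    bottlenecks on one of them, concatenation, 1x1 fusion."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True, rng=None):
        super().__init__()
        if c2 % 2:
            raise ValueError(f"C3 output channels must be even, got {c2}")
        c_ = c2 // 2
        self.cv1 = ConvBlock(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBlock(c1, c_, 1, 1, rng=rng)
        self.cv3 = ConvBlock(2 * c_, c2, 1, 1, rng=rng)
        self.m = nn.ModuleList(Bottleneck(c_, c_, shortcut, 1.0, rng=rng) for _ in range(n))

    def forward(self, x):
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(concat([y, self.cv2(x)], axis=1))


class AttentionC3(nn.Module):
    """C3 followed by an attention plug-in on its output.

    With ``spec.variant == 'none'`` this is parameter-for-parameter a
    plain C3.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 spec: AttentionSpec | None = None, rng=None):
        super().__init__()
        self.c3 = C3(c1, c2, n, shortcut, rng=rng)
        spec = spec or AttentionSpec()
        self.attn = build_attention(spec.variant, c2, spec, rng=rng)

    def forward(self, x):
        return self.attn(self.c3(x))


class SPPF(nn.Module):
    """Fast spatial pyramid pooling: serial max pools, concatenated, fused."""

    def __init__(self, c1: int, c2: int, k: int = 5, rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBlock(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBlock(c_ * 4, c2, 1, 1, rng=rng)
        self.pool = nn.MaxPool2d(k, 1, k // 2)

    def forward(self, x):
        y0 = self.cv1(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(concat([y0, y1, y2, y3], axis=1))


class Detect(nn.Module):
    """Three-scale head: one biased 1x1 convolution per scale emitting
    3 anchors x (4 box + 1 objectness + nc class) channels."""

    def __init__(self, nc: int, channels: tuple[int, int, int],
                 anchors: np.ndarray, strides=(8, 16, 32), rng=None):
        super().__init__()
        self.nc = nc
        self.no = nc + 5
        self.na = anchors.shape[1]
        self.anchors = np.asarray(anchors, dtype=np.float32)  # (3, na, 2) pixels
        self.strides = np.asarray(strides, dtype=np.float32)
        self.convs = nn.ModuleList(
            nn.Conv2d(c, self.na * self.no, 1, bias=True, rng=rng) for c in channels
        )

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        out = []
        for conv, f in zip(self.convs, feats):
            n, _, h, w = f.shape
            y = conv(f).reshape(n, self.na, self.no, h, w).transpose(0, 1, 3, 4, 2)
            out.append(y)  # (n, na, h, w, 5+nc), raw logits
        return out
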