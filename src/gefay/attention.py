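"""Attention operators behind one plug-in interface.

Implements group-enhanced fusion attention (GEFA) together with the
classical comparison modules — squeeze-and-excitation (SE), efficient
channel attention (ECA), coordinate attention (CA), the convolutional
block attention module (CBAM) and mixed local channel attention (MLCA) —
so any of them can occupy the attention slot of an ``AttentionC3`` block.

All operators are shape preserving (C,H,W -> C,H,W) and gate the input
with weights strictly inside (0, 1).

GEFA pipeline
-------------
1. *Group enhancement*: the C input channels are partitioned into G equal
   groups; a grouped ``group_kernel`` convolution expands each group by
   ``group_width_factor``, and a grouped 1x1 convolution projects back to
   C channels (each followed by batch normalization, with SiLU in
   between).  The per-group outputs are concatenated along the channel
   axis, giving the enhanced features U.
2. *Local branch*: U is average-pooled onto a p x p grid of regions
   (local average pooling), a shared 1-D convolution of adaptive kernel
   size k(C) mixes each region descriptor across neighbouring channels,
   and the region weights are expanded back to H x W by nearest-neighbour
   de-pooling.
3. *Global branch*: the same 1-D mixer is applied to the globally pooled
   descriptor.
4. The two branches are averaged, squashed by a sigmoid into a gate
   A in (0,1), and fused residually: ``y = x + A * U``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from . import nn
from .autograd import Tensor, concat

__all__ = [
    "EcaKernelPolicy", "AttentionSpec", "eca_kernel_size",
    "local_avg_pool", "local_unpool",
    "GEFA", "SE", "ECA", "CA", "CBAM", "MLCA",
    "build_attention", "VARIANTS", "default_reduction",
]

VARIANTS = ("none", "se", "eca", "ca", "cbam", "mlca", "gefa")


@dataclass(frozen=True)
class EcaKernelPolicy:
    """Hyperparameters of the adaptive 1-D kernel-size rule k(C)."""

    gamma: float = 2.0
    b: float = 2.0
    min_k: int = 3

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.min_k < 1 or self.min_k % 2 == 0:
            raise ValueError("min_k must be an odd positive integer")


@dataclass(frozen=True)
class AttentionSpec:
    """Which attention variant to build, and its hyperparameters."""

    variant: str = "none"
    groups: int = 8                      # gefa: number of channel groups G
    local_grid: int = 5                  # mlca/gefa: p of the p x p pooling grid
    reduction: int | None = None         # se/ca/cbam: r (None -> per-variant default)
    kernel_policy: EcaKernelPolicy = field(default_factory=EcaKernelPolicy)
    group_kernel: int = 1                # gefa: spatial kernel of the grouped conv
    group_width_factor: float = 1.625    # gefa: per-group expansion ratio
    share_mixer: bool = True             # share the 1-D mixer across branches

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown attention variant {self.variant!r}; "
                             f"expected one of {VARIANTS}")
        if self.groups < 1 or self.local_grid < 1 or self.group_kernel < 1:
            raise ValueError("groups, local_grid and group_kernel must be >= 1")
        if self.group_width_factor <= 0:
            raise ValueError("group_width_factor must be positive")

    def resolved_reduction(self) -> int:
        return self.reduction if self.reduction is not None else default_reduction(self.variant)

    def with_(self, **kw) -> "AttentionSpec":
        return replace(self, **kw)


def _hidden_width(c: int, g: int, width_factor: float) -> int:
    """Expanded per-group width: ``width_factor * c`` rounded (half up) to
    the nearest positive multiple of the group count."""
    exact = Fraction(width_factor).limit_denominator(64) * c
    return max(g, int(math.floor(exact / g + Fraction(1, 2))) * g)


def default_reduction(variant: str) -> int:
    return {"se": 4, "ca": 16, "cbam": 16}.get(variant, 1)


def eca_kernel_size(c: int, policy: EcaKernelPolicy = EcaKernelPolicy()) -> int:
    """Adaptive 1-D kernel size k(C) = odd(log2(C)/gamma + b/gamma).

    Round half up to the nearest integer, add one if even, clamp to
    ``policy.min_k``.  The result is always odd.
    """
    if c < 1:
        raise ValueError(f"channel count must be >= 1, got {c}")
    v = math.log2(c) / policy.gamma + policy.b / policy.gamma
    k = math.floor(v + 0.5)
    if k % 2 == 0:
        k += 1
    return max(k, policy.min_k)


def local_avg_pool(x: Tensor, p: int) -> Tensor:
    """Partition each channel into a p x p grid of regions and average."""
    return nn.adaptive_avg_pool2d(x, p)


def local_unpool(w: Tensor, h: int, width: int) -> Tensor:
    """Nearest-neighbour de-pooling of p x p region weights to h x width."""
    return nn.nearest_unpool2d(w, h, width)


def _global_max_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    flat = x.data.reshape(n, c, h * w)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2).reshape(n, c, 1, 1)

    def backward(grad):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[:, :, None], grad.reshape(n, c, 1), axis=2)
        x._accum(dflat.reshape(x.shape))

    return Tensor._result(out, (x,), backward)


class _AttentionBase(nn.Module):
    """Common plug-in surface: shape-preserving ``apply``/``forward``."""

    def apply(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def weight_inventory(self) -> dict[str, int]:
        return {name: p.size for name, p in self.named_parameters()}


class SE(_AttentionBase):
    """Squeeze-and-excitation: global pooling + bottleneck MLP channel gate."""

    def __init__(self, c: int, r: int = 4, rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, math.ceil(c / r))
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Conv2d(c, hidden, 1, rng=rng)
        self.fc2 = nn.Conv2d(hidden, c, 1, rng=rng)

    def forward(self, x):
        s = nn.adaptive_avg_pool2d(x, 1)
        return x * self.fc2(self.fc1(s).relu()).sigmoid()


class ECA(_AttentionBase):
    """Efficient channel attention: 1-D conv of adaptive size on the pooled descriptor."""

    def __init__(self, c: int, policy: EcaKernelPolicy = EcaKernelPolicy(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.mixer = nn.ChannelConv1d(eca_kernel_size(c, policy), rng=rng)

    def forward(self, x):
        n, c = x.shape[:2]
        s = nn.adaptive_avg_pool2d(x, 1).reshape(n, c, 1)
        a = self.mixer(s).sigmoid().reshape(n, c, 1, 1)
        return x * a


class CA(_AttentionBase):
    """Coordinate attention: directional pooling with position-aware gates."""

    def __init__(self, c: int, r: int = 16, rng: np.random.Generator | None = None):
        super().__init__()
        mip = max(8, c // r)
        rng = rng or np.random.default_rng(0)
        self.conv1 = nn.Conv2d(c, mip, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(mip)
        self.conv_h = nn.Conv2d(mip, c, 1, rng=rng)
        self.conv_w = nn.Conv2d(mip, c, 1, rng=rng)

    def forward(self, x):
        n, c, h, w = x.shape
        ph = x.mean(axis=3, keepdims=True)                      # (n,c,h,1)
        pw = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (n,c,w,1)
        y = self.bn1(self.conv1(concat([ph, pw], axis=2))).silu()
        yh = y[:, :, :h]
        yw = y[:, :, h:].transpose(0, 1, 3, 2)
        ah = self.conv_h(yh).sigmoid()
        aw = self.conv_w(yw).sigmoid()
        return x * ah * aw


class CBAM(_AttentionBase):
    """Convolutional block attention: channel gate then 7x7 spatial gate."""

    def __init__(self, c: int, r: int = 16, rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, c // r)
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Conv2d(c, hidden, 1, rng=rng)
        self.fc2 = nn.Conv2d(hidden, c, 1, rng=rng)
        self.spatial = nn.Conv2d(2, 1, 7, rng=rng)

    def forward(self, x):
        avg = nn.adaptive_avg_pool2d(x, 1)
        mx = _global_max_pool(x)
        cg = (self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())).sigmoid()
        x = x * cg
        sa = concat([x.mean(axis=1, keepdims=True), _channel_max(x)], axis=1)
        return x * self.spatial(sa).sigmoid()


def _channel_max(x: Tensor) -> Tensor:
    arg = x.data.argmax(axis=1)[:, None]
    out = np.take_along_axis(x.data, arg, axis=1)

    def backward(grad):
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, arg, grad, axis=1)
        x._accum(dx)

    return Tensor._result(out, (x,), backward)


class MLCA(_AttentionBase):
    """Mixed local channel attention: local p x p + global descriptors, shared 1-D mixer."""

    def __init__(self, c: int, p: int = 5, policy: EcaKernelPolicy = EcaKernelPolicy(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.mixer = nn.ChannelConv1d(eca_kernel_size(c, policy), rng=rng)

    def forward(self, x):
        n, c, h, w = x.shape
        loc = local_avg_pool(x, self.p).reshape(n, c, self.p * self.p)
        glo = nn.adaptive_avg_pool2d(x, 1).reshape(n, c, 1)
        yl = self.mixer(loc).reshape(n, c, self.p, self.p)
        yg = self.mixer(glo).reshape(n, c, 1, 1)
        a = ((local_unpool(yl, h, w) + yg) * 0.5).sigmoid()
        return x * a


class GEFA(_AttentionBase):
    """Group-enhanced fusion attention (see module docstring)."""

    def __init__(self, c: int, spec: AttentionSpec, rng: np.random.Generator | None = None):
        super().__init__()
        g = spec.groups
        if c % g:
            raise ValueError(f"channel count {c} not divisible by groups={g}")
        hidden = _hidden_width(c, g, spec.group_width_factor)
        rng = rng or np.random.default_rng(0)
        self.p = spec.local_grid
        self.enhance1 = nn.Conv2d(c, hidden, spec.group_kernel, groups=g, rng=rng)
        self.bn1 = nn.BatchNorm2d(hidden)
        self.enhance2 = nn.Conv2d(hidden, c, 1, groups=g, rng=rng)
        self.bn2 = nn.BatchNorm2d(c)
        k = eca_kernel_size(c, spec.kernel_policy)
        self.mixer = nn.ChannelConv1d(k, rng=rng)
        self.mixer_global = self.mixer if spec.share_mixer else nn.ChannelConv1d(k, rng=rng)
        if not spec.share_mixer:
            self._own_global = self.mixer_global  # ensure discovery of the duplicate

    def forward(self, x):
        n, c, h, w = x.shape
        if h < self.p or w < self.p:
            raise ValueError(f"spatial size {h}x{w} smaller than local grid p={self.p}")
        u = self.bn2(self.enhance2(self.bn1(self.enhance1(x)).silu()))
        loc = self.mixer(local_avg_pool(u, self.p).reshape(n, c, self.p * self.p))
        loc = local_unpool(loc.reshape(n, c, self.p, self.p), h, w)
        glo = self.mixer_global(nn.adaptive_avg_pool2d(u, 1).reshape(n, c, 1))
        a = ((loc + glo.reshape(n, c, 1, 1)) * 0.5).sigmoid()
        return x + a * u

    def named_parameters(self, prefix: str = ""):
        seen = set()
        for name, p in super().named_parameters(prefix):
            if id(p) not in seen:
                seen.add(id(p))
                yield name, p


def build_attention(variant: str, c: int, spec: AttentionSpec | None = None,
                    rng: np.random.Generator | None = None) -> nn.Module:
    """Construct the attention plug-in for a channel count ``c``.

    This is the slot contract AttentionC3 consumes: the returned module is
    shape preserving and exposes ``apply`` plus a ``weight_inventory``.
    """
    spec = spec or AttentionSpec(variant=variant)
    if variant != spec.variant:
        spec = spec.with_(variant=variant)
    if variant == "none":
        return nn.Identity()
    if variant == "se":
        return SE(c, spec.resolved_reduction(), rng=rng)
    if variant == "eca":
        return ECA(c, spec.kernel_policy, rng=rng)
    if variant == "ca":
        return CA(c, spec.resolved_reduction(), rng=rng)
    if variant == "cbam":
        return CBAM(c, spec.resolved_reduction(), rng=rng)
    if variant == "mlca":
        return MLCA(c, spec.local_grid, spec.kernel_policy, rng=rng)
    if variant == "gefa":
        return GEFA(c, spec, rng=rng)
    raise ValueError(f"unknown attention variant {variant!r}")
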