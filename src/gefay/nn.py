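"""Neural-network layers over the autograd core.

Contains exactly the layer set the detector needs: 2-D convolution with
groups/stride/padding (im2col + BLAS matmul), batch normalization, SiLU,
max pooling, nearest-neighbour up/down sampling, adaptive average pooling,
a 1-D cross-channel convolution, and an SGD-with-momentum optimizer.
Weight initialization is He-uniform for convolutions and identity
(scale 1, shift 0) for normalization layers, driven by an explicit
``numpy.random.Generator`` so that construction is reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, _sigmoid

__all__ = [
    "Module", "ModuleList", "Parameter",
    "Conv2d", "BatchNorm2d", "SiLU", "Identity",
    "MaxPool2d", "UpsampleNearest2x",
    "adaptive_avg_pool2d", "nearest_unpool2d", "ChannelConv1d",
    "bce_with_logits", "SGD",
]


def Parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


class Module:
    """Base class: attribute-walking parameter discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, ModuleList):
                yield from v

    def modules(self):
        yield self
        for c in self.children():
            yield from c.modules()

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield (f"{prefix}{k}", v)
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{k}.")
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield from m.named_parameters(f"{prefix}{k}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        sd = {k: p.data.copy() for k, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                sd[f"{name}running_mean"] = m.running_mean.copy()
                sd[f"{name}running_var"] = m.running_var.copy()
        return sd

    def load_state_dict(self, sd: dict) -> None:
        params = dict(self.named_parameters())
        for k, v in sd.items():
            if k in params:
                params[k].data = np.asarray(v, dtype=np.float32)
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                if f"{name}running_mean" in sd:
                    m.running_mean = np.asarray(sd[f"{name}running_mean"], dtype=np.float32)
                    m.running_var = np.asarray(sd[f"{name}running_var"], dtype=np.float32)

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{k}.")
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield from m._named_modules(f"{prefix}{k}.{i}.")


class ModuleList(list):
    pass


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return x.silu()


# ---------------------------------------------------------------------------
# convolution


def _im2col(xp: np.ndarray, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k * k, oh * ow), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i : i + s * oh : s, j : j + s * ow : s]
            cols[:, :, i * k + j] = patch.reshape(n, c, oh * ow)
    return cols


def _col2im(dcols: np.ndarray, xp_shape, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    n, c = xp_shape[:2]
    dxp = np.zeros(xp_shape, dtype=np.float32)
    dcols = dcols.reshape(n, c, k * k, oh, ow)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i * k + j]
    return dxp


class Conv2d(Module):
    """2-D convolution (optionally grouped); bias off by default."""

    def __init__(self, c_in: int, c_out: int, k: int = 1, s: int = 1,
                 p: int | None = None, groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c_in < 1 or c_out < 1 or k < 1 or s < 1:
            raise ValueError("conv dimensions must be positive")
        if c_in % groups or c_out % groups:
            raise ValueError(f"channels ({c_in}->{c_out}) not divisible by groups={groups}")
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, k, s
        self.p = k // 2 if p is None else p
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = (c_in // groups) * k * k
        bound = math.sqrt(6.0 / fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound, (c_out, c_in // groups, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        k, s, p, g = self.k, self.s, self.p, self.groups
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
        cols = _im2col(xp, k, s, oh, ow)  # (n, c, k*k, L)
        L = oh * ow
        cols_g = cols.reshape(n, g, (c // g) * k * k, L)
        w_g = self.weight.data.reshape(g, self.c_out // g, (c // g) * k * k)
        out = np.matmul(w_g[None], cols_g).reshape(n, self.c_out, oh, ow)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]

        conv, weight, bias = self, self.weight, self.bias
        xp_shape = xp.shape

        def backward(grad):
            gg = grad.reshape(n, g, conv.c_out // g, L)
            dw = np.matmul(gg, cols_g.transpose(0, 1, 3, 2)).sum(axis=0)
            weight._accum(dw.reshape(weight.data.shape))
            if bias is not None:
                bias._accum(grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = np.matmul(np.swapaxes(w_g, -1, -2)[None], gg)
                dxp = _col2im(dcols.reshape(n, c, k * k, L), xp_shape, k, s, oh, ow)
                x._accum(dxp[:, :, p : p + h, p : p + w] if p else dxp)

        parents = (x, weight) if bias is None else (x, weight, bias)
        return Tensor._result(out, parents, backward)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones((1, c, 1, 1)))
        self.bias = Parameter(np.zeros((1, c, 1, 1)))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            rm = self.running_mean[None, :, None, None]
            rv = self.running_var[None, :, None, None]
            xhat = (x - rm) * Tensor(1.0 / np.sqrt(rv + self.eps))
        return xhat * self.weight + self.bias


class MaxPool2d(Module):
    def __init__(self, k: int, s: int = 1, p: int | None = None):
        super().__init__()
        self.k, self.s = k, s
        self.p = k // 2 if p is None else p

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x.data
        cols = _im2col(xp, k, s, oh, ow)
        arg = cols.argmax(axis=2)
        out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0].reshape(n, c, oh, ow)
        xp_shape = xp.shape

        def backward(grad):
            dcols = np.zeros((n, c, k * k, oh * ow), dtype=np.float32)
            np.put_along_axis(dcols, arg[:, :, None], grad.reshape(n, c, 1, oh * ow), axis=2)
            dxp = _col2im(dcols, xp_shape, k, s, oh, ow)
            x._accum(dxp[:, :, p : p + h, p : p + w] if p else dxp)

        return Tensor._result(out, (x,), backward)


class UpsampleNearest2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        out = x.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(grad):
            x._accum(grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return Tensor._result(out, (x,), backward)


# ---------------------------------------------------------------------------
# pooling primitives used by the attention operators


def _grid_bounds(size: int, p: int):
    """Region boundaries of an adaptive p-way partition of ``size`` cells."""
    starts = [(i * size) // p for i in range(p)]
    ends = [-((-(i + 1) * size) // p) for i in range(p)]
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, p: int) -> Tensor:
    """Average pooling onto a p x p grid of (near-)equal regions."""
    n, c, h, w = x.shape
    if p < 1:
        raise ValueError("grid size p must be >= 1")
    if h < p or w < p:
        raise ValueError(f"spatial size {h}x{w} smaller than grid p={p}")
    rs, re = _grid_bounds(h, p)
    cs, ce = _grid_bounds(w, p)
    out = np.empty((n, c, p, p), dtype=np.float32)
    for i in range(p):
        for j in range(p):
            out[:, :, i, j] = x.data[:, :, rs[i]:re[i], cs[j]:ce[j]].mean(axis=(2, 3))

    def backward(grad):
        dx = np.zeros_like(x.data)
        for i in range(p):
            for j in range(p):
                area = (re[i] - rs[i]) * (ce[j] - cs[j])
                dx[:, :, rs[i]:re[i], cs[j]:ce[j]] += grad[:, :, i, j, None, None] / area
        x._accum(dx)

    return Tensor._result(out, (x,), backward)


def nearest_unpool2d(w: Tensor, h: int, width: int) -> Tensor:
    """Nearest-neighbour expansion of a p x p grid back to h x width."""
    n, c, p, q = w.shape
    if p > h or q > width:
        raise ValueError(f"grid {p}x{q} larger than target {h}x{width}")
    ri = (np.arange(h) * p) // h
    ci = (np.arange(width) * q) // width
    out = w.data[:, :, ri][:, :, :, ci]

    def backward(grad):
        dw = np.zeros_like(w.data)
        np.add.at(dw, (slice(None), slice(None), ri[:, None], ci[None, :]), grad)
        w._accum(dw)

    return Tensor._result(out, (w,), backward)


class ChannelConv1d(Module):
    """One shared 1-D filter applied along the channel axis of (N, C, m).

    Zero padding of k//2 keeps the channel count; the filter has exactly
    ``k`` learned weights (no bias) regardless of C and m.
    """

    def __init__(self, k: int, rng: np.random.Generator | None = None):
        super().__init__()
        if k < 1 or k % 2 == 0:
            raise ValueError(f"kernel size must be odd and positive, got {k}")
        self.k = k
        rng = rng or np.random.default_rng(0)
        bound = math.sqrt(6.0 / k)
        self.weight = Parameter(rng.uniform(-bound, bound, k))

    def forward(self, x: Tensor) -> Tensor:
        n, c, m = x.shape
        k = self.k
        pad = k // 2
        xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
        wt = self.weight
        out = np.zeros((n, c, m), dtype=np.float32)
        for t in range(k):
            out += wt.data[t] * xp[:, t : t + c]

        def backward(grad):
            dw = np.array([(grad * xp[:, t : t + c]).sum() for t in range(k)], dtype=np.float32)
            wt._accum(dw)
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for t in range(k):
                    dxp[:, t : t + c] += wt.data[t] * grad
                x._accum(dxp[:, pad : pad + c])

        return Tensor._result(out, (x, wt), backward)


# ---------------------------------------------------------------------------
# loss primitive and optimizer


def bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    y = np.asarray(y, dtype=np.float32)
    zd = z.data
    loss = np.maximum(zd, 0) - zd * y + np.log1p(np.exp(-np.abs(zd)))

    def backward(grad):
        z._accum(grad * (_sigmoid(zd) - y))

    return Tensor._result(loss, (z,), backward)


class SGD:
    """SGD with momentum; optional decoupled weight decay on conv weights."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.937,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim >= 2:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
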