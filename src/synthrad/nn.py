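"""Minimal numpy neural-network layers with hand-written backward passes.

Just enough machinery for small convolutional translation networks:
2D convolution (im2col), instance normalization, ReLU / LeakyReLU /
Sigmoid, nearest-neighbour upsampling, residual blocks, a Sequential
container and an Adam optimizer.  Data layout is (N, C, H, W);
parameters default to float32 (override per layer with ``dtype``).

Each layer caches what its backward pass needs during ``forward``; a
``backward(dy)`` call consumes that cache and accumulates parameter
gradients into ``Param.grad``.  A layer instance must therefore be run
forward immediately before the corresponding backward.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Module", "Conv2d", "InstanceNorm2d", "ReLU", "LeakyReLU",
    "Sigmoid", "Upsample2x", "Sequential", "ResBlock", "Adam",
]


#: training dtype; float32 keeps the conv stack fast on one CPU
DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray, dtype=None):
        self.value = np.asarray(value, dtype=dtype or DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    def parameters(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Module):
    """2D convolution (cross-correlation) with zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 dtype=None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        self.dtype = dtype or DTYPE
        self.weight = Param(rng.normal(0.0, 0.02, (out_ch, in_ch, kernel, kernel)),
                            self.dtype)
        self.bias = Param(np.zeros(out_ch), self.dtype)
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :ho, :wo]  # (n, c, ho, wo, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.bias.value
        self._cache = (cols, x.shape, (ho, wo))
        return y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape, (ho, wo) = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dy = np.asarray(dy, dtype=self.dtype)
        dy2 = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        cols2 = cols.reshape(n * ho * wo, -1)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        self.weight.grad += (dy2.T @ cols2).reshape(self.weight.value.shape)
        self.bias.grad += dy2.sum(axis=0)
        if s == 1:
            # dx = full correlation of dy with the 180-degree-flipped kernel;
            # an im2col over dy is much smaller than one over x when
            # out_ch < in_ch * k^2
            q = k - 1 - p
            dyp = np.pad(dy, ((0, 0), (0, 0), (q, q), (q, q))) if q else dy
            dwin = np.lib.stride_tricks.sliding_window_view(dyp, (k, k),
                                                            axis=(2, 3))
            dy_cols = dwin.transpose(0, 2, 3, 1, 4, 5).reshape(
                n * h * w, self.out_ch * k * k
            )
            wflip = np.ascontiguousarray(
                self.weight.value[:, :, ::-1, ::-1].transpose(0, 2, 3, 1)
            ).reshape(self.out_ch * k * k, c)
            dx = (dy_cols @ wflip).reshape(n, h, w, c).transpose(0, 3, 1, 2)
            return np.ascontiguousarray(dx)
        dcols = (dy2 @ wmat).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=self.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += (
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, ch: int, eps: float = 1e-5, dtype=None):
        self.eps = eps
        self.dtype = dtype or DTYPE
        self.gamma = Param(np.ones(ch), self.dtype)
        self.beta = Param(np.zeros(ch), self.dtype)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        x = np.asarray(x, dtype=self.dtype)
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value[None, :, None, None] + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dy):
        xhat, inv = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Module):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def forward_collect(self, x, collect_types=(LeakyReLU, ReLU)):
        """Forward pass returning (output, intermediate activations)."""
        feats = []
        for l in self.layers:
            x = l.forward(x)
            if isinstance(l, collect_types):
                feats.append(x)
        return x, feats


class ResBlock(Module):
    """conv3x3 - IN - ReLU - conv3x3 - IN plus identity skip."""

    def __init__(self, ch: int, rng: np.random.Generator | None = None,
                 dtype=None):
        self.body = Sequential(
            Conv2d(ch, ch, 3, 1, 1, rng=rng, dtype=dtype),
            InstanceNorm2d(ch, dtype=dtype),
            ReLU(),
            Conv2d(ch, ch, 3, 1, 1, rng=rng, dtype=dtype),
            InstanceNorm2d(ch, dtype=dtype),
        )

    def parameters(self):
        return self.body.parameters()

    def forward(self, x):
        return x + self.body.forward(x)

    def backward(self, dy):
        return dy + self.body.backward(dy)


class Adam:
    """Adam with external per-step learning rate (for linear decay)."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
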