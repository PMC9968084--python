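"""Minimal numpy convolutional-network building blocks.

Implements exactly what the compact encoder–decoder segmenter needs:
3×3 same-padding and 1×1 convolutions (im2col + matmul), ReLU,
non-overlapping 2×2 max pooling, nearest-neighbour 2× upsampling, channel
concatenation, and SGD/Adam optimizers — all with explicit analytic
backward passes.  Arrays are ``(N, C, H, W)`` float32.  Everything is
deterministic given the initialization seed (single-threaded BLAS).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Conv2d:
    """k×k convolution with 'same' zero padding (k in {1, 3})."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
        self.W = Param(w)
        self.b = Param(np.zeros(cout))
        self.cin, self.cout, self.k = cin, cout, k
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if self.k == 1:
            return x.transpose(0, 2, 3, 1).reshape(N * H * W, C)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N, H, W, C, k, k) -> (N*H*W, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * H * W, C * self.k * self.k
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        cols = self._im2col(x)
        out = cols @ self.W.value + self.b.value
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(N, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._xshape
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.W.grad += self._cols.T @ dyr
        self.b.grad += dyr.sum(axis=0)
        if self.k == 1:
            dx = (dyr @ self.W.value.T).reshape(N, H, W, C).transpose(0, 3, 1, 2)
            self._cols = None
            return np.ascontiguousarray(dx)
        # gradient w.r.t. input = correlation of dy with the flipped kernel
        Wk = self.W.value.reshape(C, self.k, self.k, self.cout)
        Wback = Wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
            self.cout * self.k * self.k, C
        )
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(dyp, (self.k, self.k), axis=(2, 3))
        dycols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * H * W, self.cout * self.k * self.k
        )
        dx = (dycols @ Wback).reshape(N, H, W, C).transpose(0, 3, 1, 2)
        self._cols = None
        return np.ascontiguousarray(dx)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """Non-overlapping 2×2 max pooling."""

    def __init__(self):
        self._mask = None
        self._xshape = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            up = np.repeat(np.repeat(out, 2, axis=2), 2, axis=3)
            mask = (x == up)
            # break ties so gradient mass is not duplicated
            xr_mask = mask.reshape(N, C, H // 2, 2, W // 2, 2)
            flat = xr_mask.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
            first = flat.argmax(axis=-1)
            sel = np.zeros_like(flat)
            np.put_along_axis(sel, first[..., None], 1, axis=-1)
            self._mask = sel.reshape(N, C, H // 2, W // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5
            ).reshape(N, C, H, W).astype(bool)
            self._xshape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        up = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3)
        return up * self._mask


class Upsample2:
    """Nearest-neighbour 2× upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = dy.shape
        return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))

    def params(self) -> list[Param]:
        return []


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax2(logits: np.ndarray) -> np.ndarray:
    """Softmax over a 2-channel axis-1."""
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


class SGD:
    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            if self.momentum:
                v *= self.momentum
                v += p.grad
                p.value -= self.lr * v
            else:
                p.value -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.b1 ** self._t
        b2t = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class ConvBlock:
    """Two 3×3 conv + ReLU pairs."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(cout, cout, 3, rng)
        self.r2 = ReLU()

    def params(self) -> list[Param]:
        return self.c1.params() + self.c2.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.r2.forward(
            self.c2.forward(self.r1.forward(self.c1.forward(x, train), train), train),
            train,
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))
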