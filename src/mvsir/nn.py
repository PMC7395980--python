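"""Minimal NumPy neural-network layers with explicit backpropagation.

Just enough machinery for small patch classifiers: stride-1 2D convolution
(via im2col and BLAS matmul), max pooling with ceil / shape-preserving
padding, dense layers, ReLU, and an Adam optimizer with optional L2 weight
decay.  Data layout is NHWC; the default dtype is float32 (float64 is
supported for finite-difference gradient checking).

Each layer caches what its backward pass needs during ``forward``; calling
``backward`` propagates an upstream gradient and accumulates parameter
gradients in ``Param.grad``.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "Dense",
    "ReLU",
    "Flatten",
    "Adam",
]


class Param:
    """A trainable array with an accumulated gradient of the same shape."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    """Base class: forward caches (when ``train``), backward consumes the
    cache once.  ``train=False`` skips every cache and takes faster paths —
    inference-only forward passes touch far less memory."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, fan_in: int, shape, dtype) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2D(Layer):
    """Stride-1 2D convolution, NHWC, padding 'same' or 'valid'.

    Weights are stored flat as (k*k*c_in, c_out) so both the forward and
    the weight-gradient reduce to one matmul over the im2col matrix.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: str = "same",
                 *, rng: np.random.Generator, dtype=np.float32):
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "valid" and kernel != 1:
            raise ValueError("valid padding is only used for 1x1 kernels here")
        self.c_in, self.c_out, self.kernel, self.padding = c_in, c_out, kernel, padding
        fan_in = kernel * kernel * c_in
        self.w = Param(_he_normal(rng, fan_in, (fan_in, c_out), dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        k = self.kernel
        p = (k - 1) // 2
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, Ho, Wo, C, k, k) -> (N*Ho*Wo, k*k*C)
        win = sliding_window_view(x, (k, k), axis=(1, 2))
        n, ho, wo, c = win.shape[:4]
        col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        return col.reshape(n * ho * wo, k * k * c), (n, ho, wo, p)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        if self.kernel == 1:
            flat = x.reshape(-1, c)
            y = flat @ self.w.value + self.b.value
            if train:
                self._cache = (flat, (n, h, w))
            return y.reshape(n, h, w, self.c_out)
        col, (n, ho, wo, p) = self._im2col(x)
        y = col @ self.w.value + self.b.value
        if train:
            self._cache = (col, (n, ho, wo, p, h, w))
        return y.reshape(n, ho, wo, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.kernel
        if k == 1:
            flat, (n, h, w) = self._cache
            dflat = dy.reshape(-1, self.c_out)
            self.w.grad += flat.T @ dflat
            self.b.grad += dflat.sum(axis=0)
            return (dflat @ self.w.value.T).reshape(n, h, w, self.c_in)
        col, (n, ho, wo, p, h, w) = self._cache
        dflat = dy.reshape(-1, self.c_out)
        self.w.grad += col.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcol = (dflat @ self.w.value.T).reshape(n, ho, wo, k, k, self.c_in)
        dx = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, i:i + ho, j:j + wo, :] += dcol[:, :, :, i, j, :]
        return dx[:, p:p + h, p:p + w, :] if p else dx


class MaxPool2D(Layer):
    """Max pooling over pool x pool windows.

    mode='ceil'  : stride = pool, partial windows kept (right/bottom padded
                   with -inf), so 15 -> 8 for pool 2.
    mode='same'  : stride = 1, output shape equals input shape.
    Gradient at ties is split uniformly among the tied window entries.
    """

    def __init__(self, pool: int = 2, mode: str = "ceil"):
        if mode not in ("ceil", "same"):
            raise ValueError(f"unknown pooling mode {mode!r}")
        self.pool, self.mode = pool, mode
        self.stride = pool if mode == "ceil" else 1
        self._cache = None

    def _out_len(self, n: int) -> int:
        if self.mode == "same":
            return n
        return -(-n // self.stride)  # ceil division

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = self._out_len(h), self._out_len(w)
        k, s = self.pool, self.stride
        ph = (ho - 1) * s + k - h
        pw = (wo - 1) * s + k - w
        neg = np.array(-np.inf, dtype=x.dtype)
        if not train:
            # cache-free fast paths (no argmax bookkeeping needed)
            if s == k:  # 'ceil': pad to a window multiple, reshape, reduce
                xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)),
                            constant_values=neg)
                return xp.reshape(n, ho, k, wo, k, c).max(axis=4).max(axis=2)
            # 'same': running maximum of the k*k shifted views
            xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)),
                        constant_values=neg)
            y = xp[:, :h, :w, :].copy()
            for i in range(k):
                for j in range(k):
                    if i or j:
                        np.maximum(y, xp[:, i:i + h, j:j + w, :], out=y)
            return y
        xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=neg)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        y = win.max(axis=(-2, -1))
        mask = (win == y[..., None, None]).astype(x.dtype)
        mask /= mask.sum(axis=(-2, -1), keepdims=True)
        self._cache = (mask, (h, w, ph, pw, ho, wo))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, (h, w, ph, pw, ho, wo) = self._cache
        k, s = self.pool, self.stride
        n, c = dy.shape[0], dy.shape[3]
        dwin = mask * dy[..., None, None]
        dx = np.zeros((n, h + ph, w + pw, c), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, i:i + (ho - 1) * s + 1:s, j:j + (wo - 1) * s + 1:s, :] += \
                    dwin[..., i, j]
        return dx[:, :h, :w, :]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.n_in, self.n_out = n_in, n_out
        self.w = Param(_he_normal(rng, n_in, (n_in, n_out), dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.w.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train:
            # inputs are always fresh intermediates, so clip in place
            return np.maximum(x, x.dtype.type(0), out=x)
        self._mask = x > 0
        return np.where(self._mask, x, x.dtype.type(0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, dy.dtype.type(0))


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Adam:
    """Adam with optional decoupled-from-framework weight handling.

    ``decay_mode='l2'`` adds weight_decay * w to the gradient (classic L2
    regularisation); ``decay_mode='lr'`` instead shrinks the step size as
    lr / (1 + weight_decay * epoch) and applies no L2 term.
    """

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 weight_decay: float = 0.0, decay_mode: str = "l2",
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if decay_mode not in ("l2", "lr"):
            raise ValueError(f"unknown decay_mode {decay_mode!r}")
        self.params = params
        self.lr, self.weight_decay, self.decay_mode = lr, weight_decay, decay_mode
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.epoch = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        lr = self.lr
        if self.decay_mode == "lr":
            lr = lr / (1.0 + self.weight_decay * self.epoch)
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.decay_mode == "l2" and self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p.value -= (lr * (m / bias1) /
                        (np.sqrt(v / bias2) + self.eps)).astype(p.value.dtype)
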