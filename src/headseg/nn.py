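"""Minimal NumPy neural-network layers for 1D segmentation.

Each layer implements ``forward(x, training)`` and ``backward(dy)``; forward
caches what backward needs, so a layer instance is used at exactly one
position in a network.  Convolutions are evaluated as GEMM over an im2col
view, which keeps the whole training step inside BLAS.  All computation is
dtype-generic: float32 for training speed, float64 for finite-difference
gradient checks.

Array layout is (batch, channels, length) throughout.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(B, C, Lp) padded input -> contiguous (B*L, C*k) patch matrix."""
    b, c, lp = xp.shape
    l_out = lp - k + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B, C, L, k)
    return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(b * l_out, c * k)


class Conv1d:
    """Stride-1 'same' 1D convolution (cross-correlation), bias included."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        padding: int,
        rng: np.random.Generator,
        init: str = "kaiming",
        dtype=np.float32,
    ) -> None:
        self.cin, self.cout, self.k, self.pad = in_channels, out_channels, kernel, padding
        fan_in = in_channels * kernel
        fan_out = out_channels * kernel
        if init == "kaiming":  # feeds a rectifier
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel))
        elif init == "xavier":  # feeds the sigmoid head
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, (out_channels, in_channels, kernel))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.w = Param(w.astype(dtype), "conv.w")
        self.b = Param(np.zeros(out_channels, dtype=dtype), "conv.b")
        self._xp: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        b, c, l = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad))) if self.pad else x
        self._xp = xp if training else None
        cols = _im2col(xp, self.k)  # (B*L', Cin*k)
        w2 = self.w.data.reshape(self.cout, -1)
        y = cols @ w2.T + self.b.data
        l_out = l + 2 * self.pad - self.k + 1
        return np.ascontiguousarray(y.reshape(b, l_out, self.cout).transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xp is not None, "backward before forward"
        b, cout, l_out = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(b * l_out, cout)
        cols = _im2col(self._xp, self.k)
        self.w.grad += (dyt.T @ cols).reshape(self.w.data.shape)
        self.b.grad += dy.sum(axis=(0, 2))
        # dX: full correlation of dY with the flipped kernel
        pad_back = self.k - 1 - self.pad
        dyp = np.pad(dy, ((0, 0), (0, 0), (pad_back, pad_back)))
        cols_dy = _im2col(dyp, self.k)  # (B*Lx, Cout*k)
        wf = np.ascontiguousarray(
            np.flip(self.w.data, axis=2).transpose(0, 2, 1)
        ).reshape(cout * self.k, self.cin)
        l_x = l_out  # stride 1, same-length contract
        dx = (cols_dy @ wf).reshape(b, l_x, self.cin).transpose(0, 2, 1)
        self._xp = None
        return np.ascontiguousarray(dx)


class BatchNorm1d:
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        c = x.shape[1]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        n = dy.shape[0] * dy.shape[2]
        dgamma = (dy * xhat).sum(axis=(0, 2))
        dbeta = dy.sum(axis=(0, 2))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.data[None, :, None] * inv_std[None, :, None]
        dx = g * (dy - (dbeta[None, :, None] + xhat * dgamma[None, :, None]) / n)
        return dx


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    params: list[Param] = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        mask = x > 0
        if training:
            self._mask = mask
        return np.where(mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0)
        self._mask = None
        return dx


class MaxPool1d:
    """Pool of size 2, stride 2; input length must be even."""

    def __init__(self) -> None:
        self._argmax = None

    params: list[Param] = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        b, c, l = x.shape
        if l % 2:
            raise ShapeError(f"max-pool input length {l} must be even")
        x4 = x.reshape(b, c, l // 2, 2)
        if training:
            self._argmax = x4.argmax(axis=3)
        return x4.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, lh = dy.shape
        onehot = self._argmax[..., None] == np.arange(2)
        self._argmax = None
        return (onehot * dy[..., None]).reshape(b, c, lh * 2)


class UpsampleNearest2:
    """Nearest-neighbour upsampling with scale factor 2."""

    params: list[Param] = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return np.repeat(x, 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, l = dy.shape
        return dy.reshape(b, c, l // 2, 2).sum(axis=3)


class ConvTranspose1d2x:
    """Transposed convolution with kernel 2, stride 2 (learned upsampling)."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32) -> None:
        self.c = channels
        w = rng.normal(0.0, np.sqrt(2.0 / channels), (channels, channels, 2))
        self.w = Param(w.astype(dtype), "upconv.w")
        self.b = Param(np.zeros(channels, dtype=dtype), "upconv.b")
        self._x = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        b, c, l = x.shape
        if training:
            self._x = x
        xr = np.ascontiguousarray(x.transpose(0, 2, 1)).reshape(b * l, c)
        y = xr @ self.w.data.reshape(c, c * 2)  # (B*L, Cout*2)
        y = y.reshape(b, l, c, 2).transpose(0, 2, 1, 3).reshape(b, c, 2 * l)
        return y + self.b.data[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, l2 = dy.shape
        l = l2 // 2
        dy4 = dy.reshape(b, c, l, 2)
        dyr = np.ascontiguousarray(dy4.transpose(0, 2, 1, 3)).reshape(b * l, c * 2)
        xr = np.ascontiguousarray(self._x.transpose(0, 2, 1)).reshape(b * l, c)
        self._x = None
        self.w.grad += (xr.T @ dyr).reshape(self.w.data.shape)
        self.b.grad += dy.sum(axis=(0, 2))
        dx = (dyr @ self.w.data.reshape(c, c * 2).T).reshape(b, l, c).transpose(0, 2, 1)
        return np.ascontiguousarray(dx)


class Sigmoid:
    def __init__(self) -> None:
        self._y = None

    params: list[Param] = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        self._y = None
        return dy * y * (1.0 - y)


class Adadelta:
    """Adadelta optimiser (running RMS of gradients and of updates).

    ``lr`` scales the adaptive step.  Defaults: rho 0.95 as in the original
    method description; eps 1e-5 (framework defaults span 1e-8..1e-5) —
    a larger eps shortens Adadelta's well-known accumulator cold start, which
    matters at the small update counts of desk-scale runs.
    """

    def __init__(self, params: list[Param], lr: float = 0.1, rho: float = 0.95, eps: float = 1e-5):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self._eg = [np.zeros_like(p.data) for p in params]
        self._ed = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, eg, ed in zip(self.params, self._eg, self._ed):
            g = p.grad
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            delta = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
            ed *= self.rho
            ed += (1 - self.rho) * delta * delta
            p.data += self.lr * delta

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0
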