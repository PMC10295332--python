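"""Minimal 1-D neural-network engine with explicit backward passes.

All layers operate on arrays shaped ``(batch, length, channels)``
(channels-last keeps the im2col buffers contiguous, so convolutions reduce
to single GEMMs with no transposes).  Each layer caches what its backward
pass needs during ``forward(..., training=True)``; calling ``backward``
consumes that cache.  Parameters are :class:`Parameter` objects (value +
gradient accumulator) collected by the Adam optimizer.

Kept deliberately small: convolution (same-length zero padding), batch
normalization, leaky ReLU, factor-2 max pooling, factor-2 upsampling
(nearest or linear), and channel concatenation — exactly the vocabulary a
1-D U-block needs.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "DTYPE",
    "Parameter",
    "Conv1d",
    "BatchNorm1d",
    "LeakyReLU",
    "MaxPool1d",
    "Upsample1d",
    "concat_channels",
    "split_channels",
    "Adam",
]

#: Compute dtype of the network engine.
DTYPE = np.float64


class Parameter:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; layers with no parameters return an empty list."""

    def parameters(self) -> List[Parameter]:
        return []


class Conv1d(Layer):
    """1-D convolution with symmetric zero padding (output length == input).

    Weight shape is ``(in_channels, kernel, out_channels)``; the kernel
    must be odd so the padding is symmetric.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric padding")
        fan_in = in_channels * kernel
        # He/Kaiming init with leaky-ReLU gain (slope 0.1)
        std = np.sqrt(2.0 / (fan_in * (1.0 + 0.1 ** 2)))
        self.w = Parameter(rng.normal(0.0, std, size=(in_channels, kernel, out_channels)),
                           name=f"{name}.w")
        self.b = Parameter(np.zeros(out_channels), name=f"{name}.b")
        self.kernel = kernel
        self._cache: Optional[np.ndarray] = None

    def parameters(self) -> List[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # y[:, t] = sum_k xp[:, t+k] @ W[:, k]; computed as one GEMM against
        # all K taps at once followed by K shifted adds (no im2col buffer)
        B, L, C = x.shape
        K = self.kernel
        pad = K // 2
        Lp = L + 2 * pad
        xp = np.zeros((B, Lp, C), dtype=DTYPE)
        xp[:, pad:pad + L, :] = x
        cout = self.w.value.shape[2]
        z = (xp.reshape(B * Lp, C) @ self.w.value.reshape(C, K * cout))
        z = z.reshape(B, Lp, K, cout)
        y = np.tile(self.b.value, (B, L, 1))
        for k in range(K):
            y += z[:, k:k + L, k, :]
        if training:
            self._cache = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._cache
        if xp is None:
            raise RuntimeError("backward called before forward(training=True)")
        B, L, Cout = dy.shape
        K = self.kernel
        pad = K // 2
        Lp = L + 2 * pad
        Cin = self.w.value.shape[0]
        dz = np.zeros((B, Lp, K, Cout), dtype=DTYPE)
        for k in range(K):
            dz[:, k:k + L, k, :] = dy
        dz2 = dz.reshape(B * Lp, K * Cout)
        xp2 = xp.reshape(B * Lp, Cin)
        self.w.grad += (xp2.T @ dz2).reshape(Cin, K, Cout)
        self.b.grad += dy.sum(axis=(0, 1))
        dxp = dz2 @ self.w.value.reshape(Cin, K * Cout).T
        self._cache = None
        return dxp.reshape(B, Lp, Cin)[:, pad:pad + L, :]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length).

    Training uses batch statistics and updates exponential running
    estimates (momentum 0.9); inference uses the running estimates, so
    evaluation is deterministic and batch-size invariant.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9,
                 name: str = "bn"):
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def parameters(self) -> List[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        B, L, C = dy.shape
        n = B * L
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.value
        # standard batchnorm backward through batch mean/var
        dx = (inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 1), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 1), keepdims=True)
        )
        self._cache = None
        return dx


class LeakyReLU(Layer):
    """max(x, slope*x); default slope 0.1."""

    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mask = x >= 0
        if training:
            self._mask = mask
        return np.where(mask, x, DTYPE(self.slope) * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, DTYPE(self.slope) * dy)
        self._mask = None
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling by a factor (default 2)."""

    def __init__(self, factor: int = 2):
        self.factor = factor
        self._argmax: Optional[np.ndarray] = None
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, C = x.shape
        f = self.factor
        if L % f:
            raise ValueError(f"length {L} not divisible by pool factor {f}")
        xr = x.reshape(B, L // f, f, C)
        if training:
            self._argmax = xr.argmax(axis=2)
            self._shape = (B, L, C)
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, C = self._shape
        f = self.factor
        dxr = np.zeros((B, L // f, f, C), dtype=DTYPE)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        self._argmax = None
        return dxr.reshape(B, L, C)


class Upsample1d(Layer):
    """Upsampling by an integer factor along time; nearest or linear."""

    def __init__(self, factor: int = 2, mode: str = "nearest"):
        if mode not in ("nearest", "linear"):
            raise ValueError(f"unknown upsample mode: {mode!r}")
        self.factor = factor
        self.mode = mode

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        f = self.factor
        if self.mode == "nearest":
            return np.repeat(x, f, axis=1)
        B, L, C = x.shape
        # linear: sample the piecewise-linear interpolant at f points per gap
        idx = np.arange(L * f) / f
        lo = np.clip(np.floor(idx).astype(int), 0, L - 1)
        hi = np.clip(lo + 1, 0, L - 1)
        frac = (idx - np.floor(idx)).astype(DTYPE)[None, :, None]
        self._lin = (lo, hi, frac, L)
        return x[:, lo, :] * (1 - frac) + x[:, hi, :] * frac

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.factor
        if self.mode == "nearest":
            B, Lf, C = dy.shape
            return dy.reshape(B, Lf // f, f, C).sum(axis=2)
        lo, hi, frac, L = self._lin
        B, _, C = dy.shape
        dx = np.zeros((B, L, C), dtype=DTYPE)
        np.add.at(dx, (slice(None), lo, slice(None)), dy * (1 - frac))
        np.add.at(dx, (slice(None), hi, slice(None)), dy * frac)
        return dx


def concat_channels(parts: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenate along the channel (last) axis."""
    return np.concatenate(parts, axis=2)


def split_channels(grad: np.ndarray, sizes: Sequence[int]) -> List[np.ndarray]:
    """Inverse of :func:`concat_channels` for gradients."""
    return list(np.split(grad, np.cumsum(sizes)[:-1], axis=2))


class Adam:
    """Adam optimizer with an externally supplied per-step learning rate."""

    def __init__(self, params: Sequence[Parameter], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
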