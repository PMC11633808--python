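"""Minimal CPU layer library with explicit backpropagation.

Small, fully-convolutional 2D networks built from these layers train in
minutes on a single CPU at phantom scale, which is all this package needs.
All arrays are float32 in channel-last (N, H, W, C) layout — on a CPU this
keeps every GEMM operand contiguous and avoids per-layer transposes. Each
layer caches what its backward pass needs; ``backward`` consumes the
upstream gradient and accumulates parameter gradients in ``Param.grad``.

Randomness (weight init, dropout) is drawn from a ``numpy.random.Generator``
supplied by the owning model, so everything is reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
    "MaxPool2x",
    "Upsample2x",
    "Adam",
    "softmax",
    "softmax_backward",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Conv2d(Layer):
    """2D convolution with 'same' padding.

    Implemented as k*k shifted GEMMs over the padded input, which keeps all
    large operands contiguous. Weights are stored as (k, k, C_in, C_out),
    He-normal initialized. kernel_size 1 gives a plain per-voxel linear map
    (used as the output classifier layer).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        k = kernel_size
        if k % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        fan_in = in_channels * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, std, size=(k, k, in_channels, out_channels)))
        self.b = Param(np.zeros(out_channels))
        self.k = k
        self.pad = k // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        k, p, f = self.k, self.pad, self.out_channels
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        else:
            xp = np.ascontiguousarray(x)
        self._xp = xp
        hp, wp = h + 2 * p, w + 2 * p
        xf = xp.reshape(-1, c)
        out = np.empty((n, h, w, f), dtype=DTYPE)
        out[...] = self.b.value
        for di in range(k):
            for dj in range(k):
                full = (xf @ self.w.value[di, dj]).reshape(n, hp, wp, f)
                out += full[:, di:di + h, dj:dj + w, :]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, h, w, f = dout.shape
        k, p, c = self.k, self.pad, self.in_channels
        dout = np.ascontiguousarray(dout)
        dmat = dout.reshape(-1, f)
        self.b.grad += dmat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xs = np.ascontiguousarray(xp[:, di:di + h, dj:dj + w, :])
                self.w.grad[di, dj] += xs.reshape(-1, c).T @ dmat
                dxp[:, di:di + h, dj:dj + w, :] += (
                    dmat @ self.w.value[di, dj].T).reshape(n, h, w, c)
        if p:
            return np.ascontiguousarray(dxp[:, p:p + h, p:p + w, :])
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Training normalizes with batch moments and updates running estimates;
    evaluation uses the running estimates, making inference deterministic.
    """

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_channels))
        self.beta = Param(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, train, x.shape)
        return (self.gamma.value * xhat + self.beta.value).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma.value
        if not train:
            return (dxhat * inv).astype(DTYPE)
        # full batch-statistics backward
        sum_dxhat = dxhat.sum(axis=(0, 1, 2))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = dxhat - (sum_dxhat + xhat * sum_dxhat_xhat) / m
        return (dx * inv).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, DTYPE(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, DTYPE(0.0))


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate)
                      / (1.0 - self.rate)).astype(DTYPE)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class MaxPool2x(Layer):
    """2x2 max pooling (stride 2); requires even spatial size."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be divisible by 2 for pooling")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = (n, h, w, c)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=DTYPE)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(dx).reshape(n, h, w, c)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(DTYPE)


class Adam:
    """Adam optimizer; ``step`` applies the update and clears gradients."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= (self.lr * (m / b1t)
                        / (np.sqrt(v / b2t) + self.eps)).astype(DTYPE)
            p.grad[...] = 0.0


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    zs = z - z.max(axis=axis, keepdims=True)
    e = np.exp(zs)
    return (e / e.sum(axis=axis, keepdims=True)).astype(DTYPE)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray,
                     axis: int = -1) -> np.ndarray:
    """Gradient through softmax: dz = p * (dp - sum(dp * p))."""
    inner = (dprobs * probs).sum(axis=axis, keepdims=True)
    return (probs * (dprobs - inner)).astype(DTYPE)
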