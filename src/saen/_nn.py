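"""Minimal deterministic NumPy engine for small convolutional networks.

Implements exactly the layers a 2D encoder–decoder segmentation network
needs — 3×3 same-padding convolution, ReLU, 2×2 max pooling, 2×2 stride-2
transposed convolution, inverted dropout, 1×1 convolution — with explicit
forward/backward passes and an Adam optimizer.  Everything is float32,
single-threaded NumPy, and seeded through `numpy.random.Generator`, so a
fixed seed reproduces training bit-for-bit on a given BLAS build.

Internally activations are channel-major, (channels, batch, height,
width): the im2col patch matrix is then built with near-contiguous copies
and convolution forward/backward reduce to single GEMMs without layout
shuffles.  The network wrapper transposes to/from the conventional
(batch, channels, H, W) at its boundary.
"""
from __future__ import annotations

import numpy as np


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Zero-mean Gaussian init with scale sqrt(2/fan_in) (He et al. style)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C,N,H,W) -> (C*k*k, N*H*W) patch matrix for a same-size k×k conv."""
    c, n, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (c, k, k, n, h, w), (s0, s2, s3, s1, s2, s3), writeable=False
    )
    return np.ascontiguousarray(view).reshape(c * k * k, n * h * w)


class Conv2d:
    """k×k convolution, stride 1, same padding (k odd)."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int = 3):
        self.k = k
        self.pad = k // 2
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * k * k
        self.w = Param(he_normal(rng, (c_out, c_in, k, k), fan_in))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        _, n, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        self._cols = cols
        y = self.w.value.reshape(self.c_out, -1) @ cols
        y += self.b.value[:, None]
        return y.reshape(self.c_out, n, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        _, n, h, w = dy.shape
        dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(self.c_out, -1)
        self.w.grad += (dyf @ self._cols.T).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=1)
        # input gradient = same-size correlation of dy with the spatially
        # flipped, channel-transposed kernel
        wt = self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
        dycols = _im2col(dyf.reshape(self.c_out, n, h, w), self.k, self.pad)
        dx = wt.reshape(self.c_in, -1) @ dycols
        return dx.reshape(self.c_in, n, h, w)

    def params(self) -> list[Param]:
        return [self.w, self.b]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, np.float32(0.0))

    def params(self) -> list[Param]:
        return []


class MaxPool2:
    """2×2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(c, n, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(c, n, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, h, w = self._x_shape
        dxr = np.zeros((c, n, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(c, n, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dxr).reshape(c, n, h, w)

    def params(self) -> list[Param]:
        return []


class UpConv2:
    """2×2 stride-2 transposed convolution (the 'up-convolution')."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(he_normal(rng, (c_in, c_out, 2, 2), c_in))
        self.b = Param(np.zeros(c_out, dtype=np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, h, w = x.shape
        self._x = x
        y = np.einsum("cnhw,cokl->onhkwl", x, self.w.value, optimize=True)
        y = np.ascontiguousarray(y).reshape(self.c_out, n, 2 * h, 2 * w)
        y += self.b.value[:, None, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        _, n, h2, w2 = dy.shape
        dyr = dy.reshape(self.c_out, n, h2 // 2, 2, w2 // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self.w.grad += np.einsum("cnhw,onhwkl->cokl", self._x, dyr, optimize=True)
        self.b.grad += dy.sum(axis=(1, 2, 3))
        return np.einsum("onhwkl,cokl->cnhw", dyr, self.w.value, optimize=True)

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Dropout:
    """Inverted dropout; `rate` is the drop probability θ."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, active: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not active or self.rate == 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        self._mask = (rng.random(x.shape, dtype=np.float32) >= self.rate).astype(np.float32)
        self._mask /= keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask

    def params(self) -> list[Param]:
        return []


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
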