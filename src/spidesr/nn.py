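"""Minimal numpy neural-network layers with manual backpropagation.

The restoration networks used here (a small U-net denoiser, a kernel
predictor/corrector pair and a kernel-conditioned SR network) are compact
enough to train on a CPU with plain numpy.  This module provides the few
layer types they need -- stride-1 "same" convolution, 2x2 average pooling,
nearest-neighbour upsampling, pixel shuffle, dense layers, feature-wise
affine conditioning -- each exposing ``forward``/``backward`` and holding
its parameters as :class:`Param` objects, plus an Adam optimizer.

Conventions: activations are float64 arrays in NCHW layout; ``backward``
must be called after the matching ``forward`` (caches are single-use);
gradients accumulate into ``Param.grad`` until :func:`zero_grad`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "ReLU",
    "LeakyReLU",
    "Linear",
    "AvgPool2",
    "UpsampleNearest2",
    "PixelShuffle",
    "GlobalAvgPool",
    "SFT",
    "Adam",
]


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: recursive parameter collection over attributes."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # serialization -------------------------------------------------------
    def state_list(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_list(self, arrays) -> None:
        own = self.params()
        if len(own) != len(arrays):
            raise ValueError(
                f"state mismatch: {len(own)} params, {len(arrays)} arrays"
            )
        for p, a in zip(own, arrays):
            a = np.asarray(a, dtype=np.float64)
            if a.shape != p.value.shape:
                raise ValueError(f"shape mismatch {a.shape} vs {p.value.shape}")
            p.value[...] = a


def _he_init(rng: np.random.Generator, shape, fan_in: int, scale: float = 1.0):
    std = scale * np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


class Conv2d(Module):
    """Stride-1 convolution with zero 'same' padding (odd kernel)."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 init_scale: float = 1.0):
        if ksize % 2 == 0:
            raise ValueError("ksize must be odd")
        self.cin, self.cout, self.k = cin, cout, ksize
        self.w = Param(_he_init(rng, (cout, cin, ksize, ksize), cin * ksize * ksize,
                                init_scale))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def _cols(self, x: np.ndarray, c: int) -> np.ndarray:
        n, _, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * self.k * self.k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        cols = self._cols(x, c)
        out = cols @ self.w.value.reshape(self.cout, -1).T + self.b.value
        self._cache = cols
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = dout.shape
        dm = dout.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        cols = self._cache
        self._cache = None
        self.w.grad += (dm.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dm.sum(axis=0)
        # input gradient = correlation of dout with the flipped kernel
        wflip = self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        p = self.k // 2
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(dp, (self.k, self.k), axis=(2, 3))
        cols2 = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, self.cout * self.k * self.k)
        dx = cols2 @ wflip.reshape(self.cin, -1).T
        return dx.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator,
                 init_scale: float = 1.0):
        self.din, self.dout = din, dout
        self.w = Param(_he_init(rng, (dout, din), din, init_scale))
        self.b = Param(np.zeros(dout))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class AvgPool2(Module):
    """2x2 average pooling, stride 2; requires even spatial dims."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("AvgPool2 requires even dims")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        n, c, h, w = self._shape
        d = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3)
        return d / 4.0


class UpsampleNearest2(Module):
    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class PixelShuffle(Module):
    """(N, C*r^2, H, W) -> (N, C, H*r, W*r)."""

    def __init__(self, r: int):
        self.r = r

    def forward(self, x):
        n, crr, h, w = x.shape
        r = self.r
        c = crr // (r * r)
        return (x.reshape(n, c, r, r, h, w)
                 .transpose(0, 1, 4, 2, 5, 3)
                 .reshape(n, c, h * r, w * r))

    def backward(self, dout):
        n, c, hr, wr = dout.shape
        r = self.r
        h, w = hr // r, wr // r
        return (dout.reshape(n, c, h, r, w, r)
                    .transpose(0, 1, 3, 5, 2, 4)
                    .reshape(n, c * r * r, h, w))


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class GlobalMomentPool(Module):
    """(N, C, H, W) -> (N, 2C): per-channel mean and root-mean-square.

    The RMS component carries contrast / gradient-energy information that
    plain average pooling discards; blur level is read off such second
    moments, so the kernel predictor and corrector pool with this layer.
    """

    _EPS = 1e-12

    def forward(self, x):
        self._x = x
        mean = x.mean(axis=(2, 3))
        self._rms = np.sqrt((x ** 2).mean(axis=(2, 3)) + self._EPS)
        return np.concatenate([mean, self._rms], axis=1)

    def backward(self, dout):
        n, c, h, w = self._x.shape
        dmean, drms = dout[:, :c], dout[:, c:]
        dx = np.broadcast_to(dmean[:, :, None, None], self._x.shape) / (h * w)
        dx = dx + self._x * (drms / (self._rms * h * w))[:, :, None, None]
        return dx


class SFT(Module):
    """Spatial feature transform: per-channel affine modulation from a code.

    out = f * (1 + gamma(z)) + beta(z), gamma/beta linear in the code z.
    The kernel estimate enters the SR network only through this layer; it is
    never concatenated to the image as an extra plane.
    """

    def __init__(self, channels: int, code_dim: int, rng: np.random.Generator):
        self.gamma = Linear(code_dim, channels, rng, init_scale=0.1)
        self.beta = Linear(code_dim, channels, rng, init_scale=0.1)

    def forward(self, f: np.ndarray, z: np.ndarray) -> np.ndarray:
        g = self.gamma.forward(z)
        b = self.beta.forward(z)
        self._f, self._g = f, g
        return f * (1.0 + g[:, :, None, None]) + b[:, :, None, None]

    def backward(self, dout: np.ndarray):
        df = dout * (1.0 + self._g[:, :, None, None])
        dg = (dout * self._f).sum(axis=(2, 3))
        db = dout.sum(axis=(2, 3))
        dz = self.gamma.backward(dg) + self.beta.backward(db)
        return df, dz


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
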