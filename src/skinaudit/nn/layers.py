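"""Minimal CPU neural-network layers with explicit backpropagation.

Everything is float32, NCHW.  Each layer caches what its backward pass
needs during ``forward(x, train=True)`` and exposes ``params`` /``grads``
dictionaries consumed by the SGD loop in :mod:`skinaudit.nn.resnet`.
Convolutions are evaluated as im2col matrix products.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "GlobalAvgPool", "Linear"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow),
        (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride))
    return np.ascontiguousarray(view).reshape(n, c * kh * kw, oh * ow)


def _col2im(dcols: np.ndarray, xshape: tuple, kh: int, kw: int,
            stride: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d6[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Module:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def modules(self):
        yield self

    def n_params(self) -> int:
        return sum(p.size for m in self.modules() for p in m.params.values())


class Conv2d(Module):
    """2-D convolution, no bias (a BatchNorm always follows it here)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        self.params["w"] = (rng.standard_normal((cout, cin, k, k))
                            * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n = x.shape[0]
        cols = _im2col(x, self.k, self.k, self.stride, self.pad)
        wm = self.params["w"].reshape(self.cout, -1)
        out = np.matmul(wm, cols)
        oh = (x.shape[2] + 2 * self.pad - self.k) // self.stride + 1
        ow = (x.shape[3] + 2 * self.pad - self.k) // self.stride + 1
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(n, self.cout, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        dflat = dout.reshape(n, self.cout, -1)
        self.grads["w"] = np.einsum("nfl,nkl->fk", dflat, self._cols).reshape(
            self.params["w"].shape).astype(np.float32)
        wm = self.params["w"].reshape(self.cout, -1)
        dcols = np.matmul(wm.T, dflat)
        dx = _col2im(dcols, self._xshape, self.k, self.k, self.stride, self.pad)
        self._cols = None
        return dx


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = eps, momentum
        self._batches_seen = 0  # cumulative-average mode when momentum is None

    def reset_running_stats(self) -> None:
        self.running_mean[:] = 0
        self.running_var[:] = 1
        self._batches_seen = 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self.momentum is None:  # exact cumulative average over batches
                self._batches_seen += 1
                f = 1.0 / self._batches_seen
            else:
                f = self.momentum
            self.running_mean = ((1 - f) * self.running_mean
                                 + f * mean).astype(np.float32)
            self.running_var = ((1 - f) * self.running_var
                                + f * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._xhat, self._ivar = xhat, ivar
        return (g * xhat + b).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        axes = (0, 2, 3)
        self.grads["gamma"] = (dout * xhat).sum(axis=axes).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=axes).astype(np.float32)
        g = self.params["gamma"][None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dmean = dout.mean(axis=axes)[None, :, None, None]
        dproj = (dout * xhat).mean(axis=axes)[None, :, None, None]
        dx = g * ivar[None, :, None, None] * (dout - dmean - xhat * dproj)
        self._xhat = None
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Module):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                    constant_values=-np.inf)
        cols = _im2col(xp, self.k, self.k, self.stride, 0)  # (n, c*k*k, L)
        L = cols.shape[2]
        cols = cols.reshape(n, c, self.k * self.k, L)
        idx = cols.argmax(axis=2)
        out = np.take_along_axis(cols, idx[:, :, None, :], axis=2)[:, :, 0, :]
        oh = (h + 2 * self.pad - self.k) // self.stride + 1
        if train:
            self._idx, self._xshape = idx, x.shape
        return out.reshape(n, c, oh, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dflat = dout.reshape(n, c, 1, -1)
        dcols = np.zeros((n, c, self.k * self.k, dflat.shape[3]), dtype=dout.dtype)
        np.put_along_axis(dcols, self._idx[:, :, None, :], dflat, axis=2)
        dcols = dcols.reshape(n, c * self.k * self.k, -1)
        dxp = _col2im(dcols, (n, c, h + 2 * self.pad, w + 2 * self.pad),
                      self.k, self.k, self.stride, 0)
        self._idx = None
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._shape).astype(dout.dtype)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(nin)
        self.params["w"] = rng.uniform(-bound, bound, (nout, nin)).astype(np.float32)
        self.params["b"] = np.zeros(nout, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] = (dout.T @ self._x).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        dx = dout @ self.params["w"]
        self._x = None
        return dx
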