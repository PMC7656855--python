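"""Minimal NumPy neural-network backend.

Implements exactly the layers the segmentation network needs — 2D same-padded
convolution, unpadded 1x1x3 z-convolution, batch normalization, ReLU,
dropout, 2x2 max pooling, 2x2-stride-2 transposed convolution — each with a
hand-written backward pass, plus the Adam optimizer.  All state is NumPy; all
randomness flows through explicitly passed ``numpy.random.Generator``s, so
training and Monte-Carlo dropout are exactly reproducible.

Layers are single-use per step: ``forward`` caches what ``backward`` needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
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

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Same-padded (for odd k) 2D convolution on (B, C, H, W), via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, pad: int | None = None):
        self.k = k
        self.cin = cin
        self.pad = (k - 1) // 2 if pad is None else pad
        self.w = Param(he_init(rng, (cout, cin, k, k), cin * k * k))
        self.b = Param(np.zeros(cout))

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.pad
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
        xcol = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b * h * w, c * k * k)
        self._xcol, self._shape = xcol, (b, c, h, w)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        y = xcol @ wmat.T + self.b.value
        return np.ascontiguousarray(y.reshape(b, h, w, -1).transpose(0, 3, 1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.pad
        b, c, h, w = self._shape
        o = gy.shape[1]
        gym = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(b * h * w, o)
        self.w.grad += (gym.T @ self._xcol).reshape(self.w.value.shape)
        self.b.grad += gym.sum(axis=0)
        wmat = self.w.value.reshape(o, -1)
        gcol = (gym @ wmat).reshape(b, h, w, c, k, k)
        gxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=gy.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + h, j : j + w] += gcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        del self._xcol
        return gxp[:, :, p : p + h, p : p + w] if p else gxp


class ConvZ3(Module):
    """Unpadded 1x1x3 convolution along z on (N, C, Z, H, W): Z -> Z-2."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(he_init(rng, (3, cout, cin), cin * 3))
        self.b = Param(np.zeros(cout))

    def forward(self, x: np.ndarray) -> np.ndarray:
        zo = x.shape[2] - 2
        if zo < 1:
            raise ValueError(f"z-convolution needs >= 3 slices, got {x.shape[2]}")
        # channels-last stacked matmul: (..., C) @ (C, O)
        xt = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))  # (N,Z,H,W,C)
        self._xt = xt
        y = None
        for d in range(3):
            t = xt[:, d : d + zo] @ self.w.value[d].T
            y = t if y is None else y + t
        y += self.b.value
        return np.ascontiguousarray(y.transpose(0, 4, 1, 2, 3))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xt = self._xt
        zo = gy.shape[2]
        gyt = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1))  # (N,Zo,H,W,O)
        o, c = self.w.value.shape[1:]
        gym = gyt.reshape(-1, o)
        gxt = np.zeros_like(xt)
        for d in range(3):
            xs = xt[:, d : d + zo].reshape(-1, c)
            self.w.grad[d] += gym.T @ xs
            gxt[:, d : d + zo] += (gym @ self.w.value[d]).reshape(gyt.shape[:-1] + (c,))
        self.b.grad += gym.sum(axis=0)
        del self._xt
        return np.ascontiguousarray(gxt.transpose(0, 4, 1, 2, 3))


class BatchNorm(Module):
    """Per-channel batch normalization on (B, C, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._train = train
        self._xhat, self._std = xhat, std
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = gy * self.gamma.value[None, :, None, None]
        if not self._train:
            gx = g / std[None, :, None, None]
        else:
            m = gy.shape[0] * gy.shape[2] * gy.shape[3]
            mean_g = g.mean(axis=(0, 2, 3), keepdims=True)
            mean_gx = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
            gx = (g - mean_g - xhat * mean_gx) / std[None, :, None, None]
        del self._xhat
        return gx


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._mask
        del self._mask
        return gx


class Dropout(Module):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p = p

    def forward(self, x: np.ndarray, active: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not active or self.p == 0.0:
            self._mask = None
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        self._mask = mask.astype(x.dtype)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        gx = gy * self._mask
        del self._mask
        return gx


class MaxPool2(Module):
    """2x2 max pooling with stride 2 on (B, C, H, W); H and W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even in-plane size, got {h}x{w}")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        gxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gxr, self._arg[..., None], gy[..., None], axis=-1)
        gx = gxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)
        del self._arg
        return gx


class ConvTranspose2(Module):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(he_init(rng, (cin, cout, 2, 2), cin))
        self.b = Param(np.zeros(cout))

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        o = self.w.value.shape[1]
        xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(b * h * w, c)
        self._xt, self._shape = xt, (b, c, h, w)
        y = (xt @ self.w.value.reshape(c, o * 4)).reshape(b, h, w, o, 2, 2)
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 4, 2, 5)).reshape(b, o, h * 2, w * 2)
        return y + self.b.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        o = self.w.value.shape[1]
        gy6 = np.ascontiguousarray(
            gy.reshape(b, o, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        ).reshape(b * h * w, o * 4)
        self.w.grad += (self._xt.T @ gy6).reshape(self.w.value.shape)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        gx = (gy6 @ self.w.value.reshape(c, o * 4).T).reshape(b, h, w, c)
        del self._xt
        return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.value.dtype)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over axis 1, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(probs: np.ndarray, gprobs: np.ndarray) -> np.ndarray:
    inner = (gprobs * probs).sum(axis=1, keepdims=True)
    return probs * (gprobs - inner)
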