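"""Minimal NumPy layers with explicit backpropagation for the toy segmentation model.

Everything runs in float64 on single samples shaped ``(C, H, W)``. Each layer
caches what its backward pass needs; parameter gradients accumulate into
per-layer ``grads`` dicts until :meth:`zero_grad` is called. The engine exists
to make per-region gradient queries exact and auditable — a finite-difference
oracle in the test-suite checks every path through it.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import ndtr

_NORM_EPS = 1e-5


def _normal_pdf(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


class Layer:
    """Base class: parameterized layers fill ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.grads: "OrderedDict[str, np.ndarray]" = OrderedDict()

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3x3(Layer):
    """Same-padded 3x3 convolution, zero boundary."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = c_in * 9
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
        self.params["b"] = np.zeros(c_out)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        # windows: (C_in, H, W, 3, 3)
        self._xw = sliding_window_view(xp, (3, 3), axis=(1, 2))
        w, b = self.params["w"], self.params["b"]
        return np.einsum("chwkl,ockl->ohw", self._xw, w, optimize=True) + b[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w = self.params["w"]
        self.grads["w"] += np.einsum("chwkl,ohw->ockl", self._xw, dy, optimize=True)
        self.grads["b"] += dy.sum(axis=(1, 2))
        dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1)))
        dyw = sliding_window_view(dyp, (3, 3), axis=(1, 2))
        w_flip = w[:, :, ::-1, ::-1]
        return np.einsum("ohwkl,ockl->chw", dyw, w_flip, optimize=True)


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in))
        self.params["b"] = np.zeros(c_out)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,chw->ohw", self.params["w"], x) + self.params["b"][:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["w"] += np.einsum("ohw,chw->oc", dy, self._x)
        self.grads["b"] += dy.sum(axis=(1, 2))
        return np.einsum("oc,ohw->chw", self.params["w"], dy)


class InstanceNorm(Layer):
    """Per-channel normalization over spatial axes with learnable affine."""

    def __init__(self, channels: int) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._std = np.sqrt(var + _NORM_EPS)
        self._xhat = (x - mu) / self._std
        return self.params["gamma"][:, None, None] * self._xhat + self.params["beta"][:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.grads["gamma"] += (dy * xhat).sum(axis=(1, 2))
        self.grads["beta"] += dy.sum(axis=(1, 2))
        dxhat = dy * self.params["gamma"][:, None, None]
        m1 = dxhat.mean(axis=(1, 2), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
        return (dxhat - m1 - xhat * m2) / self._std


class GELU(Layer):
    """Exact Gaussian-error-linear unit; smooth, so gradients are defined everywhere."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._cdf = ndtr(x)
        return x * self._cdf

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (self._cdf + self._x * _normal_pdf(self._x))


class ConvBlock(Layer):
    """conv3x3 -> instance norm -> GELU; the unit of gradient targeting."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv = Conv3x3(c_in, c_out, rng)
        self.norm = InstanceNorm(c_out)
        self.act = GELU()

    @property
    def params(self):  # type: ignore[override]
        d: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for k, v in self.conv.params.items():
            d["conv." + k] = v
        for k, v in self.norm.params.items():
            d["norm." + k] = v
        return d

    @params.setter
    def params(self, value) -> None:  # Layer.__init__ assigns; ignore
        pass

    @property
    def grads(self):  # type: ignore[override]
        d: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for k, v in self.conv.grads.items():
            d["conv." + k] = v
        for k, v in self.norm.grads.items():
            d["norm." + k] = v
        return d

    @grads.setter
    def grads(self, value) -> None:
        pass

    def zero_grad(self) -> None:
        self.conv.zero_grad()
        self.norm.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.norm.backward(self.act.backward(dy)))


def avg_pool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def avg_pool2_backward(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0


def upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, h, w = dy.shape
    return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    inner = (dprobs * probs).sum(axis=0, keepdims=True)
    return probs * (dprobs - inner)


class Adam:
    """In-place Adam over a flat list of (param, grad-getter) pairs."""

    def __init__(self, params: "list[np.ndarray]", lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: "list[np.ndarray]") -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
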