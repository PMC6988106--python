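"""Minimal 3D CNN building blocks with manual backpropagation.

Implements exactly what the potential-learning networks need: 3x3x3
convolutions (stride 1, zero padding 1), max pooling with stride equal to
the pool size (2 per axis where the axis allows), dense layers, ReLU and
sigmoid, plus SGD with momentum, weight decay and a stepped learning-rate
decay.  Arrays are ``(batch, channels, D, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "MaxPool3d", "ReLU", "Sigmoid", "Flatten", "Dense",
           "Sequential", "SGD"]


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


class Conv3d(Layer):
    """3D convolution, kernel 3, stride 1, zero padding 1 (same-size output)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._x_shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        # (B, C, D, H, W, k, k, k) -> (B, D*H*W, C*k^3)
        b, c, d, h, w_ = x.shape
        return np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
                                    ).reshape(b, d * h * w_, c * k**3)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, d, h, w_ = x.shape
        cols = self._im2col(x)
        self._cols = cols
        self._x_shape = x.shape
        out = cols @ self.w + self.b
        return out.reshape(b, d, h, w_, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c_out, d, h, w_ = grad.shape
        g = grad.transpose(0, 2, 3, 4, 1).reshape(b, d * h * w_, c_out)
        self.gw = np.einsum("bpf,bpc->fc", self._cols, g)
        self.gb = g.sum(axis=(0, 1))
        gcols = g @ self.w.T  # (B, P, C*k^3)
        k = self.k
        pad = k // 2
        c_in = self.c_in
        gcols = gcols.reshape(b, d, h, w_, c_in, k, k, k)
        gx = np.zeros((b, c_in, d + 2 * pad, h + 2 * pad, w_ + 2 * pad))
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    gx[:, :, a:a + d, bb:bb + h, cc:cc + w_] += \
                        gcols[:, :, :, :, :, a, bb, cc].transpose(0, 4, 1, 2, 3)
        return gx[:, :, pad:pad + d, pad:pad + h, pad:pad + w_]

    def params(self) -> list[dict]:
        return [{"layer": self, "name": "w"}, {"layer": self, "name": "b"}]


class MaxPool3d(Layer):
    """Max pooling with pool size = stride = 2 on every axis of size >= 2.

    Axes already of size 1 are left untouched; trailing odd samples are
    cropped (floor division), matching common CNN practice.
    """

    def __init__(self):
        self._cache = None

    @staticmethod
    def out_shape(shape):
        return tuple(max(s // 2, 1) if s >= 2 else s for s in shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, d, h, w_ = x.shape
        wd, wh, ww = (2 if d >= 2 else 1), (2 if h >= 2 else 1), (2 if w_ >= 2 else 1)
        d2, h2, w2 = d // wd, h // wh, w_ // ww
        xc = x[:, :, :d2 * wd, :h2 * wh, :w2 * ww]
        win = xc.reshape(b, c, d2, wd, h2, wh, w2, ww)
        win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d2, h2, w2, wd * wh * ww)
        arg = win.argmax(axis=-1)
        out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, (wd, wh, ww), arg)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, (wd, wh, ww), arg = self._cache
        b, c, d, h, w_ = x_shape
        d2, h2, w2 = grad.shape[2:]
        gwin = np.zeros((b, c, d2, h2, w2, wd * wh * ww))
        np.put_along_axis(gwin, arg[..., None], grad[..., None], axis=-1)
        gwin = gwin.reshape(b, c, d2, h2, w2, wd, wh, ww).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        gx = np.zeros(x_shape)
        gx[:, :, :d2 * wd, :h2 * wh, :w2 * ww] = gwin.reshape(b, c, d2 * wd, h2 * wh, w2 * ww)
        return gx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [{"layer": self, "name": "w"}, {"layer": self, "name": "b"}]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class SGD:
    """SGD with momentum, L2 weight decay and stepped learning-rate decay.

    The learning rate is ``lr * decay ** (iteration // decay_every)``, i.e. a
    stepped schedule applied every ``decay_every`` parameter updates.
    """

    def __init__(self, params: list[dict], lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 1e-4, decay: float = 0.8,
                 decay_every: int = 1000):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.weight_decay = weight_decay
        self.decay, self.decay_every = decay, decay_every
        self.iteration = 0
        self._velocity = [np.zeros_like(getattr(p["layer"], p["name"])) for p in params]

    @property
    def current_lr(self) -> float:
        return self.lr * self.decay ** (self.iteration // self.decay_every)

    def step(self) -> None:
        lr = self.current_lr
        for p, v in zip(self.params, self._velocity):
            w = getattr(p["layer"], p["name"])
            g = getattr(p["layer"], "g" + p["name"])
            v *= self.momentum
            v -= lr * (g + self.weight_decay * w)
            w += v
        self.iteration += 1
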