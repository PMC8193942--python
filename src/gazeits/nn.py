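"""Minimal CPU neural-network layers with exact-gradient backprop.

Just enough machinery for the two CNN architectures used on image panels:
im2col convolution (arbitrary stride/padding), 2-D max and adaptive average
pooling, linear layers, ReLU, inverted dropout, softmax cross-entropy and
Adam.  Arrays are float32 NCHW; every layer exposes ``forward``/``backward``
and its ``(param, grad)`` pairs.  All randomness (init, dropout, batch
order) flows from one seeded generator, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "ReLU", "MaxPool2d", "AdaptiveAvgPool2d", "Flatten",
    "Linear", "Dropout", "Sequential", "softmax_cross_entropy", "Adam",
]


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, L, C*k*k) patch matrix, L = oh*ow."""
    n, c, h, w = x.shape
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]
    oh, ow = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.padding = kernel, stride, padding
        fan_in = c_in * kernel * kernel
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in),
                            (c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        oh = (h + 2 * self.padding - self.k) // self.stride + 1
        ow = (w + 2 * self.padding - self.k) // self.stride + 1
        return oh, ow

    def forward(self, x, train=False):
        if self.padding:
            p = self.padding
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, h, w = x.shape
        oh, ow = (h - self.k) // self.stride + 1, (w - self.k) // self.stride + 1
        if oh < 1 or ow < 1:
            raise ValueError(f"input {h}x{w} too small for kernel {self.k}")
        self._xshape = x.shape
        self._cols = _im2col(x, self.k, self.stride)
        out = self._cols @ self.W.T + self.b
        self._oh, self._ow = oh, ow
        return out.transpose(0, 2, 1).reshape(n, self.c_out, oh, ow)

    def backward(self, grad):
        n = grad.shape[0]
        g = grad.reshape(n, self.c_out, -1).transpose(0, 2, 1)  # (N, L, c_out)
        self.dW[...] = np.tensordot(g, self._cols, axes=([0, 1], [0, 1]))
        self.db[...] = g.sum(axis=(0, 1))
        dcols = g @ self.W  # (N, L, C*k*k)
        _, c, h, w = self._xshape
        dx = np.zeros(self._xshape, dtype=np.float32)
        k, s = self.k, self.stride
        dcols = dcols.reshape(n, self._oh, self._ow, c, k, k)
        for di in range(k):
            for dj in range(k):
                dx[:, :, di:di + s * self._oh:s, dj:dj + s * self._ow:s] += \
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        if self.padding:
            p = self.padding
            dx = dx[:, :, p:-p, p:-p]
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class MaxPool2d(Layer):
    def __init__(self, size: int = 2, stride: int | None = None):
        self.size = size
        self.stride = stride or size

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s = self.size, self.stride
        oh, ow = (h - k) // s + 1, (w - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s].reshape(n, c, oh, ow, k * k)
        self._arg = win.argmax(axis=-1)
        self._xshape = x.shape
        self._oh, self._ow = oh, ow
        return win.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._xshape
        k, s = self.size, self.stride
        dx = np.zeros(self._xshape, dtype=np.float32)
        oh, ow = self._oh, self._ow
        ii, jj = np.divmod(self._arg, k)
        ni, ci, oi, oj = np.indices((n, c, oh, ow))
        np.add.at(dx, (ni, ci, oi * s + ii, oj * s + jj), grad)
        return dx


class AdaptiveAvgPool2d(Layer):
    """Average pooling to a fixed output grid (regions as in torch)."""

    def __init__(self, out_hw: tuple[int, int] = (6, 6)):
        self.oh, self.ow = out_hw

    @staticmethod
    def _bounds(n_in: int, n_out: int) -> list[tuple[int, int]]:
        return [(int(np.floor(i * n_in / n_out)),
                 int(np.ceil((i + 1) * n_in / n_out))) for i in range(n_out)]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        self._xshape = x.shape
        self._hb = self._bounds(h, self.oh)
        self._wb = self._bounds(w, self.ow)
        out = np.empty((n, c, self.oh, self.ow), dtype=np.float32)
        for i, (h0, h1) in enumerate(self._hb):
            for j, (w0, w1) in enumerate(self._wb):
                out[:, :, i, j] = x[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
        return out

    def backward(self, grad):
        dx = np.zeros(self._xshape, dtype=np.float32)
        for i, (h0, h1) in enumerate(self._hb):
            for j, (w0, w1) in enumerate(self._wb):
                area = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += grad[:, :, i:i + 1, j:j + 1] / area
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0, np.sqrt(2.0 / n_in),
                            (n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1 - self.p)
        return x * self._mask.astype(np.float32)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [pg for layer in self.layers for pg in layer.params()]

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())


def softmax_cross_entropy(scores: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the scores."""
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adam with optional decoupled weight decay (AdamW when > 0)."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.wd > 0 and p.ndim > 1:  # decay weights, not biases
                p -= self.lr * self.wd * p
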