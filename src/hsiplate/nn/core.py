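"""Minimal feed-forward NN core: layers with explicit backprop and Adam.

Written for the two small networks in this package (a 2-D U-net for droplet
masking and a 1-D CNN for spectral classification).  Conventions:

* tensors are channels-last: ``(N, L, C)`` in 1-D, ``(N, H, W, C)`` in 2-D;
* ``forward(x, train)`` caches what ``backward(grad)`` needs;
* ``backward`` returns the gradient w.r.t. the layer input and fills
  per-parameter gradients, consumed by :class:`Adam`;
* all randomness (init, dropout) flows from one ``numpy.random.Generator``.

Layers default to float32 arithmetic; a dtype argument exists so unit tests
can run finite-difference gradient checks in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "Conv1D", "Conv2D", "ConvTranspose2D",
    "MaxPool1D", "AvgPool1D", "MaxPool2D", "ReLU", "Dropout", "Flatten",
    "Sequential", "Adam", "TrainHistory", "sigmoid", "softmax",
    "sigmoid_bce_loss", "softmax_ce_loss",
]


class TrainHistory:
    """Per-epoch training record: loss plus one named auxiliary metric."""

    def __init__(self, metric_name: str = "metric"):
        self.metric_name = metric_name
        self.loss: list[float] = []
        self.metric: list[float] = []

    def append(self, loss: float, metric: float) -> None:
        self.loss.append(float(loss))
        self.metric.append(float(metric))

    def __len__(self) -> int:
        return len(self.loss)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch": range(1, len(self) + 1), "loss": self.loss,
             self.metric_name: self.metric}
        )


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base layer; parameterless layers inherit the empty param API."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = _he_init(rng, (n_in, n_out), n_in, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution, stride 1, input (N, L, C_in)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.kernel = kernel
        self.W = _he_init(rng, (kernel, c_in, c_out), kernel * c_in, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def out_length(self, L: int) -> int:
        return L - self.kernel + 1

    def forward(self, x, train=False):
        self._x = x
        N, L, C = x.shape
        Lo = self.out_length(L)
        out = np.broadcast_to(self.b, (N, Lo, self.W.shape[2])).copy()
        for k in range(self.kernel):
            out += x[:, k : k + Lo, :] @ self.W[k]
        return out

    def backward(self, grad):
        x = self._x
        N, L, C = x.shape
        Lo = grad.shape[1]
        gx = np.zeros_like(x)
        for k in range(self.kernel):
            xs = x[:, k : k + Lo, :].reshape(-1, C)
            self.gW[k] = xs.T @ grad.reshape(-1, grad.shape[2])
            gx[:, k : k + Lo, :] += grad @ self.W[k].T
        self.gb[...] = grad.sum(axis=(0, 1))
        return gx


class Conv2D(Layer):
    """Same-padded k x k 2-D convolution, stride 1, input (N, H, W, C_in)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        assert kernel % 2 == 1, "same padding needs an odd kernel"
        self.kernel = kernel
        self.pad = kernel // 2
        self.W = _he_init(rng, (kernel, kernel, c_in, c_out), kernel * kernel * c_in, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=False):
        p = self.pad
        xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xpad = xpad
        N, H, W_, C = x.shape
        out = np.broadcast_to(self.b, (N, H, W_, self.W.shape[3])).copy()
        for di in range(self.kernel):
            for dj in range(self.kernel):
                out += xpad[:, di : di + H, dj : dj + W_, :] @ self.W[di, dj]
        return out

    def backward(self, grad):
        xpad = self._xpad
        N, H, W_, Co = grad.shape
        Ci = self.W.shape[2]
        gxpad = np.zeros_like(xpad)
        gflat = grad.reshape(-1, Co)
        for di in range(self.kernel):
            for dj in range(self.kernel):
                xs = xpad[:, di : di + H, dj : dj + W_, :].reshape(-1, Ci)
                self.gW[di, dj] = xs.T @ gflat
                gxpad[:, di : di + H, dj : dj + W_, :] += grad @ self.W[di, dj].T
        self.gb[...] = grad.sum(axis=(0, 1, 2))
        p = self.pad
        return gxpad[:, p:-p or None, p:-p or None, :]


class ConvTranspose2D(Layer):
    """2 x 2 stride-2 transposed convolution (learned up-sampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = _he_init(rng, (2, 2, c_in, c_out), c_in, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=False):
        self._x = x
        N, H, W_, C = x.shape
        out = np.empty((N, 2 * H, 2 * W_, self.W.shape[3]), dtype=x.dtype)
        for di in range(2):
            for dj in range(2):
                out[:, di::2, dj::2, :] = x @ self.W[di, dj] + self.b
        return out

    def backward(self, grad):
        x = self._x
        C = x.shape[3]
        gx = np.zeros_like(x)
        self.gb[...] = 0
        for di in range(2):
            for dj in range(2):
                gs = grad[:, di::2, dj::2, :]
                self.gW[di, dj] = x.reshape(-1, C).T @ gs.reshape(-1, gs.shape[3])
                self.gb += gs.sum(axis=(0, 1, 2))
                gx += gs @ self.W[di, dj].T
        return gx


class MaxPool2D(Layer):
    """2 x 2 max pooling, stride 2."""

    def forward(self, x, train=False):
        N, H, W_, C = x.shape
        xr = (
            x.reshape(N, H // 2, 2, W_ // 2, 2, C)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(N, H // 2, W_ // 2, C, 4)
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        N, H, W_, C = self._shape
        g = np.zeros((N, H // 2, W_ // 2, C, 4), dtype=grad.dtype)
        np.put_along_axis(g, self._idx[..., None], grad[..., None], axis=-1)
        return (
            g.reshape(N, H // 2, W_ // 2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(N, H, W_, C)
        )


class MaxPool1D(Layer):
    """Size-2 max pooling, stride 2 (odd trailing element dropped)."""

    def forward(self, x, train=False):
        N, L, C = x.shape
        Lo = L // 2
        xr = x[:, : 2 * Lo, :].reshape(N, Lo, 2, C)
        self._idx = xr.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        N, L, C = self._shape
        Lo = L // 2
        g = np.zeros((N, Lo, 2, C), dtype=grad.dtype)
        np.put_along_axis(g, self._idx[:, :, None, :], grad[:, :, None, :], axis=2)
        out = np.zeros((N, L, C), dtype=grad.dtype)
        out[:, : 2 * Lo, :] = g.reshape(N, 2 * Lo, C)
        return out


class AvgPool1D(Layer):
    """Size-2 average pooling, stride 2 (odd trailing element dropped)."""

    def forward(self, x, train=False):
        N, L, C = x.shape
        Lo = L // 2
        self._shape = x.shape
        return x[:, : 2 * Lo, :].reshape(N, Lo, 2, C).mean(axis=2)

    def backward(self, grad):
        N, L, C = self._shape
        Lo = L // 2
        out = np.zeros((N, L, C), dtype=grad.dtype)
        out[:, : 2 * Lo, :] = np.repeat(grad / 2.0, 2, axis=1)
        return out


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        assert 0.0 <= rate < 1.0
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask.astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Adam:
    """Adam optimizer over a module's (params, grads) pairs."""

    def __init__(self, module: Layer, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = module.params()
        self.grads = module.grads()
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def sigmoid_bce_loss(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    p = sigmoid(logits)
    # numerically stable BCE: max(z,0) - z*t + log(1 + exp(-|z|))
    z, t = logits, targets
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    grad = (p - t) / t.size
    return loss, grad.astype(logits.dtype)


def softmax_ce_loss(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy on logits; returns (loss, grad)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.sum(onehot * np.log(np.clip(p, 1e-12, None))) / n)
    return loss, ((p - onehot) / n).astype(logits.dtype)
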