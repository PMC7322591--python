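"""Minimal CPU neural-network engine (float32, numpy only).

Implements exactly the pieces the bichannel classifier needs: stride-1
'same' 2-D convolution (im2col + BLAS matmul), ReLU, 2x2 max-pooling,
inverted dropout, dense layers, a sigmoid/binary-cross-entropy head and the
Adam optimizer.  All randomness (initialization, dropout masks) comes from
generators passed in by the caller, so runs are reproducible bit-for-bit
under a fixed seed and thread count.

Array convention: activations are channels-last ``(N, H, W, C)`` float32,
which keeps convolution outputs and input gradients contiguous without
transposes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2dSame",
    "ReLU",
    "MaxPool2",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.astype(np.float64).ravel()
    y = labels.astype(np.float64).ravel()
    # log(1 + e^-|z|) formulation avoids overflow
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).astype(np.float32).reshape(logits.shape)
    return loss, grad


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2dSame(Layer):
    """Stride-1 5x5 (or kxk) convolution with zero 'same' padding.

    Computed as one GEMM per kernel tap over shifted views of the padded
    input — no patch matrix is materialized.  ``input_layer=True`` skips
    the (unused) gradient w.r.t. the network input during backprop.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 input_layer: bool = False):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.input_layer = input_layer
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init, ReLU follows every conv
        w = rng.normal(0.0, scale, size=(c_out, fan_in)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def _kernel(self):
        return self.params[0].reshape(self.c_out, self.c_in, self.k, self.k)

    def forward(self, x, train):
        n, h, w, c = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        self._xp, self._shape = xp, (n, h, w, c)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N, H, W, C, k, k)
        out = np.einsum("nhwcij,fcij->nhwf", win, self._kernel(), optimize=True)
        out += self.params[1]
        return out

    def backward(self, dout):
        n, h, w, c = self._shape
        k, pad = self.k, self.k // 2
        win = sliding_window_view(self._xp, (k, k), axis=(1, 2))
        self.grads[0][...] = np.einsum(
            "nhwf,nhwcij->fcij", dout, win, optimize=True
        ).reshape(self.c_out, -1)
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        self._xp = None
        if self.input_layer:
            return np.zeros((n, h, w, c), dtype=dout.dtype)
        # input gradient = 'same' convolution of dout with flipped kernels
        doutp = np.pad(dout, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        win_d = sliding_window_view(doutp, (k, k), axis=(1, 2))
        return np.einsum(
            "nhwfij,fcij->nhwc", win_d, self._kernel()[:, :, ::-1, ::-1], optimize=True
        )


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class MaxPool2(Layer):
    """Non-overlapping 2x2 max pool; a trailing odd row/column is dropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        # -> (N, h2, w2, 4, C): window elements on one axis for argmax
        xr = np.ascontiguousarray(
            x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(n, h2, w2, 4, c)
        self._idx = xr.argmax(axis=3).astype(np.uint8)
        self._in_shape = (n, h, w, c)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, h2, w2, 4, c), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dxr = dxr.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, : h2 * 2, : w2 * 2, :] = dxr.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu_follows=True):
        super().__init__()
        scale = np.sqrt((2.0 if relu_follows else 1.0) / n_in)
        w = rng.normal(0.0, scale, size=(n_out, n_in)).astype(np.float32)
        b = np.zeros(n_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.params[0].T + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = dout.T @ self._x
        self.grads[1][...] = dout.sum(axis=0)
        self._x = None
        return dout @ self.params[0]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def gradients(self):
        out = []
        for layer in self.layers:
            out.extend(layer.grads)
        return out


class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
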