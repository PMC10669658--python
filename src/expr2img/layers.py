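"""A small numpy neural-network core.

Implements exactly the pieces the model zoo needs: dense and 3x3
same-padded convolutional layers (im2col + BLAS matmul), 2x2 max pooling,
inverted dropout, ReLU, L1/L2 kernel regularization, the Adam optimizer and
a numerically stable binary cross-entropy on logits.  Everything runs in
float32, is single-threaded-deterministic given a seeded generator, and
exposes explicit forward/backward passes so training loops stay plain
loops.

Conventions: activations are (batch, features) for dense stacks and
(batch, height, width, channels) for convolutional stacks.  Regularization
follows the Keras convention ``l1*sum|w| + l2*sum(w^2)`` on kernels only.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def reg_loss(self) -> float:
        return 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 l1: float = 0.0, l2: float = 0.0):
        scale = np.sqrt(2.0 / n_in)  # He initialization for ReLU stacks
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self.l1, self.l2 = l1, l2

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        if self.l1:
            self.W.grad += DTYPE(self.l1) * np.sign(self.W.value)
        if self.l2:
            self.W.grad += DTYPE(2.0 * self.l2) * self.W.value
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def params(self):
        return [self.W, self.b]

    def reg_loss(self):
        loss = 0.0
        if self.l1:
            loss += self.l1 * float(np.abs(self.W.value).sum())
        if self.l2:
            loss += self.l2 * float((self.W.value**2).sum())
        return loss


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Conv2D(Layer):
    """3x3 convolution, stride 1, zero ('same') padding, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 l1: float = 0.0, l2: float = 0.0):
        k = 3
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(k, k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        self.l1, self.l2 = l1, l2

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        """(N,H,W,C) -> (N*H*W, 9*C) patches under same-padding."""
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
        win = win.transpose(0, 1, 2, 4, 5, 3)  # (N,H,W,3,3,C)
        return np.ascontiguousarray(win).reshape(n * h * w, 9 * c)

    def forward(self, x, training, rng):
        n, h, w, _ = x.shape
        self._cols = self._im2col(x)
        self._in_shape = x.shape
        out = self._cols @ self.W.value.reshape(9 * self.c_in, self.c_out)
        return out.reshape(n, h, w, self.c_out) + self.b.value

    def backward(self, dy):
        n, h, w, _ = self._in_shape
        dy_flat = dy.reshape(n * h * w, self.c_out)
        self.W.grad += (self._cols.T @ dy_flat).reshape(self.W.value.shape)
        if self.l1:
            self.W.grad += DTYPE(self.l1) * np.sign(self.W.value)
        if self.l2:
            self.W.grad += DTYPE(2.0 * self.l2) * self.W.value
        self.b.grad += dy_flat.sum(axis=0)
        # dx = "full" correlation of dy with the spatially flipped kernels
        w_flip = self.W.value[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,c_out,c_in)
        cols_dy = self._im2col(dy)
        dx = cols_dy @ w_flip.reshape(9 * self.c_out, self.c_in)
        return dx.reshape(n, h, w, self.c_in)

    def params(self):
        return [self.W, self.b]

    def reg_loss(self):
        loss = 0.0
        if self.l1:
            loss += self.l1 * float(np.abs(self.W.value).sum())
        if self.l2:
            loss += self.l2 * float((self.W.value**2).sum())
        return loss


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; trailing odd row/col is dropped."""

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        hh, ww = h // 2, w // 2
        self._in_shape = x.shape
        x = x[:, : hh * 2, : ww * 2, :]
        win = x.reshape(n, hh, 2, ww, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, hh, ww, c, 4)
        self._argmax = win.argmax(axis=-1)
        return win.max(axis=-1)

    def backward(self, dy):
        n, h, w, c = self._in_shape
        hh, ww = h // 2, w // 2
        grad_win = np.zeros((n, hh, ww, c, 4), dtype=dy.dtype)
        np.put_along_axis(grad_win, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : hh * 2, : ww * 2, :] = (
            grad_win.reshape(n, hh, ww, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, hh * 2, ww * 2, c)
        )
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training, rng):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def reg_loss(self):
        return sum(layer.reg_loss() for layer in self.layers)


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= DTYPE(lr_t) * m / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient wrt z."""
    z = z.reshape(-1).astype(np.float64)
    y = y.reshape(-1).astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = ((sigmoid(z) - y) / len(z)).astype(DTYPE).reshape(-1, 1)
    return loss, grad


def get_weights(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_weights(params: list[Param], weights: list[np.ndarray]) -> None:
    for p, w in zip(params, weights):
        p.value = w.copy()
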