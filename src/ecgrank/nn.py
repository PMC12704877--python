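"""Minimal seeded neural-network building blocks on numpy.

Layers implement ``forward(x, train)`` / ``backward(grad)`` and expose their
(parameter, gradient) pairs; :class:`Adam` updates them in place.  Shapes:
dense layers take (n, features); 1-D convolutional layers take
(n, length, channels).  Everything is deterministic given the
``np.random.Generator`` used at construction, and serial execution.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "BatchNorm", "LeakyReLU", "ReLU", "Conv1D", "MaxPool1D",
    "Dropout", "Flatten", "Sequential", "Adam",
    "mse_loss_grad", "softmax_xent_loss_grad", "pooled_output_length",
]


class Layer:
    def params(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style scaling; fine for both leaky-ReLU and linear outputs
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics for eval."""

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        self.dgamma[...] = (grad * self._xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        gx = grad * self.gamma
        if not self._train:
            return gx / self._std
        n = grad.shape[0]
        # standard batch-norm backward through batch mean/var
        return (gx - gx.mean(axis=0)
                - self._xhat * (gx * self._xhat).mean(axis=0)) / self._std


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Conv1D(Layer):
    """Same-padded, stride-1 1-D convolution over (n, length, channels)."""

    def __init__(self, n_in: int, n_filters: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        fan_in = kernel * n_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(kernel * n_in, n_filters))
        self.b = np.zeros(n_filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.n_in = n_in

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, xp, length):
        k = self.kernel
        # (n, length, k, channels) gathered windows of the padded input
        cols = np.stack([xp[:, i:i + length, :] for i in range(k)], axis=2)
        return cols.reshape(xp.shape[0], length, k * self.n_in)

    def forward(self, x, train=False):
        n, length, _ = x.shape
        pad = (self.kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        self._cols = self._im2col(xp, length)
        self._in_shape = x.shape
        return self._cols @ self.W + self.b

    def backward(self, grad):
        n, length, _ = self._in_shape
        k, pad = self.kernel, (self.kernel - 1) // 2
        flat_cols = self._cols.reshape(-1, k * self.n_in)
        flat_grad = grad.reshape(-1, grad.shape[-1])
        self.dW[...] = flat_cols.T @ flat_grad
        self.db[...] = flat_grad.sum(axis=0)
        dcols = (grad @ self.W.T).reshape(n, length, k, self.n_in)
        dxp = np.zeros((n, length + 2 * pad, self.n_in))
        for i in range(k):
            dxp[:, i:i + length, :] += dcols[:, :, i, :]
        return dxp[:, pad:pad + length, :]


def pooled_output_length(length: int, stride: int = 2) -> int:
    """Temporal length after one same-padded pooling stage: ceil(L/stride)."""
    return -(-length // stride)


class MaxPool1D(Layer):
    """Same-padded max pooling over (n, length, channels)."""

    def __init__(self, pool: int = 3, stride: int = 2):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.pool, self.stride = pool, stride

    def forward(self, x, train=False):
        n, length, ch = x.shape
        out_len = pooled_output_length(length, self.stride)
        pad_total = max((out_len - 1) * self.stride + self.pool - length, 0)
        pl = pad_total // 2
        pr = pad_total - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)),
                    constant_values=-np.inf)
        starts = np.arange(out_len) * self.stride
        # (n, out_len, pool, ch) candidate windows
        wins = np.stack([xp[:, starts + i, :] for i in range(self.pool)],
                        axis=2)
        self._argmax = wins.argmax(axis=2)
        self._in_shape = x.shape
        self._pl = pl
        self._starts = starts
        return wins.max(axis=2)

    def backward(self, grad):
        n, length, ch = self._in_shape
        pl = self._pl
        out_len = grad.shape[1]
        dxp = np.zeros((n, length + pl + self.pool, ch))
        ni, ci = np.ogrid[:n, :ch]
        for j in range(out_len):
            pos = self._starts[j] + self._argmax[:, j, :]
            np.add.at(dxp, (ni, pos, ci), grad[:, j, :])
        return dxp[:, pl:pl + length, :]


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with the usual defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-3, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss_grad(pred, target):
    """Mean-squared-error loss and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / diff.size


def softmax_xent_loss_grad(logits, labels):
    """Softmax cross-entropy (mean over rows) and gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
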