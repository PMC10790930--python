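"""Minimal NumPy neural-network toolkit: layers, backprop, Adam.

Implements exactly what the package's three network families need — dense
layers, ReLU/ELU, batch normalization, dropout, softmax heads, max-norm
weight constraints, and the Adam optimizer — with explicit forward/backward
passes.  The networks here are tiny (thousands of parameters), so clarity is
preferred over generality.

Conventions: inputs are float64 ``(batch, features)`` unless a layer states
otherwise; every layer exposes ``forward(x, training)``, ``backward(dy)``
(which accumulates parameter gradients and returns the input gradient) and
``params()``.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # bias-corrected step size (avoids forming mhat/vhat arrays)
        alpha = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        eps = self.eps * np.sqrt(1 - b2 ** self.t)
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= alpha * m / (np.sqrt(v) + eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


# ------------------------------------------------------------------ layers

class Dense:
    """Affine layer, optionally with a max-norm constraint on each unit's
    incoming weight vector (applied after every optimizer step via
    :meth:`apply_constraints`)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 max_norm: float | None = None, bias: bool = True):
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.W = Param(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out)) if bias else None
        self.max_norm = max_norm

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def apply_constraints(self) -> None:
        if self.max_norm is not None:
            norms = np.linalg.norm(self.W.value, axis=0, keepdims=True)
            factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
            self.W.value *= factor


class ReLU:
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class ELU:
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training=False):
        self._neg = x <= 0
        self._y = np.where(self._neg, self.alpha * np.expm1(x), x)
        return self._y

    def backward(self, dy):
        return dy * np.where(self._neg, self._y + self.alpha, 1.0)

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity when not training or rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class BatchNorm:
    """Batch normalization over all axes except ``feature_axis``.

    Works on arrays of any rank; keeps running statistics for inference.
    """

    def __init__(self, n_features: int, feature_axis: int = 1,
                 momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.axis = feature_axis
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def _shape(self, ndim):
        shape = [1] * ndim
        shape[self.axis] = -1
        return shape

    def forward(self, x, training=False):
        axes = tuple(i for i in range(x.ndim) if i != self.axis)
        shape = self._shape(x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._std = np.sqrt(var + self.eps).reshape(shape)
        self._xhat = (x - mean.reshape(shape)) / self._std
        self._m = x.size // x.shape[self.axis]
        self._training = training
        return self.gamma.value.reshape(shape) * self._xhat \
            + self.beta.value.reshape(shape)

    def backward(self, dy):
        shape = self._shape(dy.ndim)
        axes = self._axes
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        if not self._training:
            return dy * g / self._std
        dxhat = dy * g
        m = self._m
        term = (dxhat
                - dxhat.mean(axis=axes, keepdims=True)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes,
                                                         keepdims=True))
        return term / self._std

    def params(self):
        return [self.gamma, self.beta]


# ---------------------------------------------------------------- softmax

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent_grad(p: np.ndarray, y_onehot: np.ndarray) -> np.ndarray:
    """Gradient of mean categorical cross-entropy w.r.t. the logits."""
    return (p - y_onehot) / p.shape[0]


def xent_loss(p: np.ndarray, y_onehot: np.ndarray) -> float:
    return float(-(y_onehot * np.log(np.clip(p, 1e-12, None))).sum(axis=1).mean())


# ------------------------------------------------------------------- MLP

class MLP:
    """Fully connected network with ReLU hidden layers.

    ``head``: ``"softmax"`` (probability simplex output), ``"linear"``
    (raw output).  ``forward`` returns probabilities or raw values;
    ``backward`` expects the gradient w.r.t. the *logits* / raw output and
    returns the gradient w.r.t. the input (useful for critic-through-actor
    gradients).
    """

    def __init__(self, sizes, rng: np.random.Generator,
                 head: str = "linear"):
        if head not in ("softmax", "linear"):
            raise ValueError("head must be 'softmax' or 'linear'")
        self.head = head
        self.layers = []
        for i in range(len(sizes) - 1):
            self.layers.append(Dense(sizes[i], sizes[i + 1], rng))
            if i < len(sizes) - 2:
                self.layers.append(ReLU())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = np.atleast_2d(np.asarray(x, dtype=np.float64))
        for layer in self.layers:
            h = layer.forward(h, training)
        self._logits = h
        return softmax(h) if self.head == "softmax" else h

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # ---- state helpers (target networks, checkpoints) ----
    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params(), weights):
            p.value[...] = w

    def clone(self) -> "MLP":
        import copy
        return copy.deepcopy(self)


def soft_update_params(target: MLP, online: MLP, tau: float) -> None:
    """Polyak update: target <- tau * online + (1 - tau) * target."""
    for pt, po in zip(target.params(), online.params()):
        pt.value *= (1.0 - tau)
        pt.value += tau * po.value
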