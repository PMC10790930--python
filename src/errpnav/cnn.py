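"""Compact depthwise/separable convolutional network for single-trial EEG.

Three-block architecture for epochs of shape (channels, samples):

Block 1: temporal convolution (F1 filters, kernel = rate/2 samples, same
         padding, no bias) -> batch norm -> depthwise spatial convolution
         across channels (depth multiplier D, max-norm 1.0) -> batch norm ->
         ELU -> average pool (4) -> dropout (0.5).
Block 2: separable convolution = depthwise temporal (kernel 16) + pointwise
         to F2 maps, no bias -> batch norm -> ELU -> average pool (8) ->
         dropout.
Block 3: flatten -> dense softmax over 2 classes (max-norm 0.25).

Training: categorical cross-entropy, Adam (lr 0.01), mini-batch 16, up to a
configurable number of epochs with plateau learning-rate decay (divide by 10
when validation loss fails to improve for 5 consecutive epochs) and optional
early stopping; the best-validation-loss weights are restored at the end.

The whole network is implemented with the NumPy layers in
:mod:`errpnav.nn`; parameter counts are small (about 2,000 weights at 20
channels) and training runs comfortably on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import (Adam, BatchNorm, Dense, Dropout, ELU, Param, softmax,
                 softmax_xent_grad, xent_loss)


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters (defaults = study values)."""

    n_channels: int = 20
    n_samples: int = 150
    n_classes: int = 2
    F1: int = 8                  # temporal filters
    F2: int = 16                 # pointwise filters
    D: int = 2                   # depth multiplier (spatial filters per F1)
    kernel_length: int = 125     # sampling rate / 2 at 250 Hz
    sep_kernel_length: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.5
    lr: float = 0.01
    batch_size: int = 16
    epochs: int = 300
    plateau_factor: float = 10.0
    plateau_patience: int = 5
    early_stop_patience: int | None = None  # epochs without val improvement

    def __post_init__(self):
        for name in ("F1", "F2", "D", "kernel_length", "pool1", "pool2",
                     "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_samples // self.pool1 // self.pool2 < 1:
            raise ValueError("window too short for the pooling chain")


def expected_parameter_count(cfg: CNNConfig) -> int:
    """Layer-by-layer hand count of trainable parameters (independent of the
    layer implementations; used as an architecture-arithmetic oracle)."""
    temporal = cfg.F1 * cfg.kernel_length
    bn1 = 2 * cfg.F1
    depthwise = cfg.F1 * cfg.D * cfg.n_channels
    bn2 = 2 * cfg.F1 * cfg.D
    sep_depth = cfg.F1 * cfg.D * cfg.sep_kernel_length
    sep_point = cfg.F1 * cfg.D * cfg.F2
    bn3 = 2 * cfg.F2
    t_out = (cfg.n_samples // cfg.pool1) // cfg.pool2
    dense = cfg.F2 * t_out * cfg.n_classes + cfg.n_classes
    return temporal + bn1 + depthwise + bn2 + sep_depth + sep_point + bn3 + dense


# ----------------------------------------------------------- conv layers

def _same_pad(k: int):
    left = (k - 1) // 2
    return left, k - 1 - left


class TemporalConv:
    """Shared 1-D temporal convolution: (N, C, T) -> (N, F1, C, T).

    Computed in the frequency domain (the kernel spans most of the window,
    so FFT convolution is much cheaper than im2col); gradients use the
    standard conv/correlation duality and are exact.
    """

    def __init__(self, f1: int, kernel: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (kernel + f1))
        self.W = Param(rng.uniform(-limit, limit, size=(kernel, f1)))
        self.k = kernel

    def _nfft(self, t):
        from scipy.fft import next_fast_len
        return next_fast_len(t + self.k - 1)

    def forward(self, x, training=False):
        from scipy.fft import irfft, rfft
        n, c, t = x.shape
        k = self.k
        lpad, _ = _same_pad(k)
        nfft = self._nfft(t)
        # cross-correlation: y[t] = sum_k x_pad[t + k] W[k]
        xp = np.pad(x, ((0, 0), (0, 0), (lpad, k - 1 - lpad)))
        self._xf = rfft(xp, nfft, axis=-1)              # (N, C, nf)
        wf = rfft(self.W.value, nfft, axis=0)           # (nf, F1)
        prod = self._xf[:, :, None, :] * np.conj(wf.T)[None, None, :, :]
        y = irfft(prod, nfft, axis=-1)[..., :t]         # (N, C, F1, T)
        self._shape = (n, c, t)
        self._nfft_used = nfft
        return y.transpose(0, 2, 1, 3)

    def backward(self, dy):
        from scipy.fft import irfft, rfft
        n, c, t = self._shape
        k = self.k
        lpad, _ = _same_pad(k)
        nfft = self._nfft_used
        dyb = dy.transpose(0, 2, 1, 3)                  # (N, C, F1, T)
        dyf = rfft(dyb, nfft, axis=-1)                  # (N, C, F1, nf)
        # dW[k] = sum_{n,c,t} x_pad[t + k] dy[t]  (correlation with x_pad)
        acc = np.einsum("ncq,ncfq->fq", self._xf, np.conj(dyf))
        dw = irfft(acc, nfft, axis=-1)[:, :k].T         # (K, F1)
        self.W.grad += dw
        # dx_pad[m] = sum_f conv(dy[f], W[:, f])[m]
        wf = rfft(self.W.value, nfft, axis=0)           # (nf, F1)
        dxpf = np.einsum("ncfq,qf->ncq", dyf, wf)
        dxp = irfft(dxpf, nfft, axis=-1)
        return dxp[:, :, lpad:lpad + t]

    def params(self):
        return [self.W]

    def apply_constraints(self):
        pass


class DepthwiseSpatialConv:
    """Spatial filtering across channels: (N, F1, C, T) -> (N, F1*D, T).

    One length-C filter per (temporal filter, depth) pair, max-norm 1.0.
    """

    def __init__(self, f1: int, d: int, n_channels: int,
                 rng: np.random.Generator, max_norm: float = 1.0):
        limit = np.sqrt(6.0 / (n_channels + 1))
        self.W = Param(rng.uniform(-limit, limit, size=(f1, d, n_channels)))
        self.max_norm = max_norm

    def forward(self, x, training=False):
        self._x = x
        y = np.einsum("fdc,nfct->nfdt", self.W.value, x)
        n, f, d, t = y.shape
        return y.reshape(n, f * d, t)

    def backward(self, dy):
        n, _, t = dy.shape
        f, d, _ = self.W.value.shape
        dyr = dy.reshape(n, f, d, t)
        self.W.grad += np.einsum("nfdt,nfct->fdc", dyr, self._x)
        return np.einsum("fdc,nfdt->nfct", self.W.value, dyr)

    def params(self):
        return [self.W]

    def apply_constraints(self):
        norms = np.linalg.norm(self.W.value, axis=2, keepdims=True)
        factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        self.W.value *= factor


class DepthwiseTemporalConv:
    """Per-map temporal convolution: (N, M, T) -> (N, M, T), kernel per map."""

    def __init__(self, n_maps: int, kernel: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (kernel + 1))
        self.W = Param(rng.uniform(-limit, limit, size=(n_maps, kernel)))
        self.k = kernel

    def forward(self, x, training=False):
        lpad, rpad = _same_pad(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (lpad, rpad)))
        self._col = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        self._t = x.shape[2]
        return np.einsum("nmtk,mk->nmt", self._col, self.W.value)

    def backward(self, dy):
        n, m, t = dy.shape
        self.W.grad += np.einsum("nmtk,nmt->mk", self._col, dy)
        lpad, _ = _same_pad(self.k)
        dxp = np.zeros((n, m, t + self.k - 1))
        for k in range(self.k):
            dxp[:, :, k:k + t] += dy * self.W.value[None, :, k, None]
        return dxp[:, :, lpad:lpad + t]

    def params(self):
        return [self.W]

    def apply_constraints(self):
        pass


class PointwiseConv:
    """1x1 mixing of feature maps: (N, M, T) -> (N, F2, T)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-limit, limit, size=(n_in, n_out)))

    def forward(self, x, training=False):
        self._x = x
        return np.einsum("mf,nmt->nft", self.W.value, x)

    def backward(self, dy):
        self.W.grad += np.einsum("nmt,nft->mf", self._x, dy)
        return np.einsum("mf,nft->nmt", self.W.value, dy)

    def params(self):
        return [self.W]

    def apply_constraints(self):
        pass


class AvgPool1d:
    """Non-overlapping average pooling along the last axis (floor division)."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, training=False):
        t = x.shape[-1]
        self._t_in = t
        t_out = t // self.size
        self._t_used = t_out * self.size
        xr = x[..., :self._t_used].reshape(*x.shape[:-1], t_out, self.size)
        return xr.mean(axis=-1)

    def backward(self, dy):
        rep = np.repeat(dy, self.size, axis=-1) / self.size
        if self._t_used < self._t_in:
            pad = self._t_in - self._t_used
            rep = np.pad(rep, [(0, 0)] * (rep.ndim - 1) + [(0, pad)])
        return rep

    def params(self):
        return []

    def apply_constraints(self):
        pass


class Flatten:
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []

    def apply_constraints(self):
        pass


# ------------------------------------------------------------ classifier

class EEGNetClassifier:
    """Compact CNN classifier with a scikit-learn-like surface.

    ``fit(X, y, X_val, y_val)`` expects epochs ``(n, channels, samples)``
    and binary labels (1 = error).  ``predict_proba`` returns ``(n, 2)``
    with column 1 the error-class probability.
    """

    def __init__(self, cfg: CNNConfig = CNNConfig(), seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0])
        c = cfg
        self.layers = [
            TemporalConv(c.F1, c.kernel_length, rng),
            BatchNorm(c.F1, feature_axis=1),
            DepthwiseSpatialConv(c.F1, c.D, c.n_channels, rng, max_norm=1.0),
            BatchNorm(c.F1 * c.D, feature_axis=1),
            ELU(),
            AvgPool1d(c.pool1),
            Dropout(c.dropout, self._dropout_rng),
            DepthwiseTemporalConv(c.F1 * c.D, c.sep_kernel_length, rng),
            PointwiseConv(c.F1 * c.D, c.F2, rng),
            BatchNorm(c.F2, feature_axis=1),
            ELU(),
            AvgPool1d(c.pool2),
            Dropout(c.dropout, self._dropout_rng),
            Flatten(),
            Dense(c.F2 * ((c.n_samples // c.pool1) // c.pool2), c.n_classes,
                  rng, max_norm=0.25),
        ]
        self._params = [p for l in self.layers for p in l.params()]
        self._fitted = False

    # ----- plumbing -----
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self._params))

    def _forward(self, x, training):
        h = x
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def _backward(self, dlogits):
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def _apply_constraints(self):
        for layer in self.layers:
            if hasattr(layer, "apply_constraints"):
                layer.apply_constraints()

    def get_weights(self):
        return [p.value.copy() for p in self._params]

    def set_weights(self, weights):
        for p, w in zip(self._params, weights):
            p.value[...] = w

    # ----- training -----
    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> "EEGNetClassifier":
        cfg = self.cfg
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        if X.shape[1] != cfg.n_channels or X.shape[2] != cfg.n_samples:
            raise ValueError(
                f"epochs must be (n, {cfg.n_channels}, {cfg.n_samples}); "
                f"got {X.shape}")
        # standardize by the global training std so Adam at lr 0.01 is stable
        self._scale = X.std() or 1.0
        X = X / self._scale
        Xv = None if X_val is None else np.asarray(X_val) / self._scale
        onehot = np.eye(cfg.n_classes)[y]

        opt = Adam(self._params, lr=cfg.lr)
        shuffle_rng = np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(2)[1])
        best_val, best_weights, since_improve, since_plateau = (
            np.inf, self.get_weights(), 0, 0)
        n = len(X)
        history = []
        for epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                p = softmax(self._forward(X[idx], training=True))
                opt.zero_grad()
                self._backward(softmax_xent_grad(p, onehot[idx]))
                opt.step()
                self._apply_constraints()
            if Xv is not None and len(Xv):
                pv = softmax(self._forward(Xv, training=False))
                val_loss = xent_loss(pv, np.eye(cfg.n_classes)[y_val])
            else:  # fall back to training loss
                pt = softmax(self._forward(X, training=False))
                val_loss = xent_loss(pt, onehot)
            history.append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = self.get_weights()
                since_improve = 0
                since_plateau = 0
            else:
                since_improve += 1
                since_plateau += 1
            if since_plateau >= cfg.plateau_patience:
                opt.lr /= cfg.plateau_factor
                since_plateau = 0
            if (cfg.early_stop_patience is not None
                    and since_improve >= cfg.early_stop_patience):
                break
        self.set_weights(best_weights)
        self.history_ = history
        self._fitted = True
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64) / self._scale
        return softmax(self._forward(X, training=False))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Error-class probability (column 1 of predict_proba)."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def fit_cnn(X: np.ndarray, y: np.ndarray, cfg: CNNConfig | None = None,
            seed: int = 0, X_val=None, y_val=None) -> EEGNetClassifier:
    """Fit the compact CNN on interest-window epochs (n, channels, samples)."""
    if cfg is None:
        cfg = CNNConfig(n_channels=X.shape[1], n_samples=X.shape[2])
    elif cfg.n_channels != X.shape[1] or cfg.n_samples != X.shape[2]:
        cfg = replace(cfg, n_channels=X.shape[1], n_samples=X.shape[2])
    return EEGNetClassifier(cfg, seed=seed).fit(X, y, X_val, y_val)
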