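"""Riemannian tangent-space classification of ERP epochs.

Single-trial epochs are represented as *augmented* ERP covariance matrices:
each trial is stacked with the xDAWN-filtered class-prototype responses
(error and true evoked means passed through their xDAWN spatial filters)
before the spatial covariance is taken.  The resulting symmetric
positive-definite (SPD) matrices live on a curved manifold; they are mapped
into a Euclidean tangent space at the Riemannian (geometric) mean of the
training covariances, where a plain LDA (svd solver, no tuning) separates the
classes.

xDAWN filters maximize the evoked-signal-to-signal-plus-noise ratio and are
obtained from the generalized eigenvalue problem between the evoked-response
covariance and the full-data covariance.

All linear-algebra primitives (matrix log/exp/sqrt via eigendecomposition,
geometric mean by fixed-point iteration) are implemented here on top of
``numpy``/``scipy``; the classifier presents the scikit-learn estimator
surface (fit / decision_function / predict / predict_proba).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


# ---------------------------------------------------------------- SPD tools

def _symmetrize(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + m.T)


def spd_fun(m: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a symmetric matrix."""
    w, v = linalg.eigh(_symmetrize(m))
    return _symmetrize((v * fun(w)) @ v.T)


def spd_logm(m):  # noqa: D103
    return spd_fun(m, np.log)


def spd_expm(m):  # noqa: D103
    return spd_fun(m, np.exp)


def spd_sqrtm(m):  # noqa: D103
    return spd_fun(m, np.sqrt)


def spd_invsqrtm(m):  # noqa: D103
    return spd_fun(m, lambda w: 1.0 / np.sqrt(w))


def geometric_mean(covs: np.ndarray, tol: float = 1e-10,
                   max_iter: int = 50) -> np.ndarray:
    """Riemannian (Karcher) mean of a stack of SPD matrices.

    Fixed-point iteration: G <- G^1/2 exp(mean_i log(G^-1/2 C_i G^-1/2)) G^1/2.
    """
    g = covs.mean(axis=0)
    for _ in range(max_iter):
        g_sqrt = spd_sqrtm(g)
        g_isqrt = spd_invsqrtm(g)
        logs = np.array([spd_logm(g_isqrt @ c @ g_isqrt) for c in covs])
        step = logs.mean(axis=0)
        g = _symmetrize(g_sqrt @ spd_expm(step) @ g_sqrt)
        if np.linalg.norm(step, "fro") < tol:
            break
    return g


def tangent_space(covs: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Project SPD matrices to tangent vectors at ``reference``.

    v = upper-tri vectorization of log(G^-1/2 C G^-1/2), off-diagonal terms
    weighted by sqrt(2) so that Euclidean distance between vectors equals the
    affine-invariant Riemannian distance to first order.
    """
    g_isqrt = spd_invsqrtm(reference)
    n = reference.shape[0]
    iu = np.triu_indices(n)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    out = np.empty((len(covs), len(iu[0])))
    for i, c in enumerate(covs):
        l = spd_logm(g_isqrt @ c @ g_isqrt)
        out[i] = l[iu] * weights
    return out


def untangent_space(vectors: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tangent_space` (exponential map at the reference)."""
    n = reference.shape[0]
    iu = np.triu_indices(n)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    g_sqrt = spd_sqrtm(reference)
    covs = np.empty((len(vectors), n, n))
    for i, v in enumerate(vectors):
        l = np.zeros((n, n))
        l[iu] = v / weights
        l = l + l.T - np.diag(np.diag(l))
        covs[i] = _symmetrize(g_sqrt @ spd_expm(l) @ g_sqrt)
    return covs


# ---------------------------------------------------------------- xDAWN

def xdawn_filters(X: np.ndarray, y: np.ndarray, n_filters: int = 4,
                  reg: float = 1e-9) -> dict:
    """Per-class xDAWN spatial filters.

    For class c with evoked mean E_c (channels x time), solve the
    generalized eigenvalue problem  (E_c E_c^T / T) v = lambda (Sigma_x) v
    with Sigma_x the covariance of the whole data, and keep the ``n_filters``
    leading eigenvectors (columns of the returned channels x n_filters
    arrays).  Filter sign is fixed so the largest-magnitude coefficient is
    positive (deterministic output).
    """
    n, c, t = X.shape
    flat = X.transpose(1, 0, 2).reshape(c, n * t)
    sigma_x = flat @ flat.T / flat.shape[1]
    sigma_x += reg * np.trace(sigma_x) / c * np.eye(c)
    out = {}
    for cls in np.unique(y):
        evoked = X[y == cls].mean(axis=0)
        sigma_e = evoked @ evoked.T / t
        w, v = linalg.eigh(sigma_e, sigma_x)
        order = np.argsort(w)[::-1][:n_filters]
        filt = v[:, order]
        for j in range(filt.shape[1]):
            k = np.argmax(np.abs(filt[:, j]))
            if filt[k, j] < 0:
                filt[:, j] *= -1
        out[int(cls)] = filt
    return out


def augmented_covariances(X: np.ndarray, prototypes: np.ndarray,
                          shrinkage: float = 1e-2) -> np.ndarray:
    """ERP covariances of trials stacked with xDAWN-filtered prototypes.

    Each trial X_i (channels x time) becomes the super-trial
    [P; X_i] with P the stacked filtered class prototypes; the sample
    covariance over time is regularized by ``shrinkage`` toward the scaled
    identity so every output is SPD.
    """
    n = X.shape[0]
    d = prototypes.shape[0] + X.shape[1]
    covs = np.empty((n, d, d))
    eye = np.eye(d)
    for i in range(n):
        s = np.vstack([prototypes, X[i]])
        c = s @ s.T / s.shape[1]
        tr = np.trace(c) / d
        covs[i] = _symmetrize((1 - shrinkage) * c + shrinkage * tr * eye)
    return covs


class XdawnTangentSpaceLDA:
    """xDAWN-augmented covariance -> tangent space -> LDA classifier.

    Parameters
    ----------
    n_filters : int
        xDAWN spatial filters per class (default 4).
    shrinkage : float
        Ridge toward the scaled identity applied to every covariance.
    filter_data : bool
        Also reduce each trial to its xDAWN-filtered components (both
        classes' filters stacked) before covariance estimation; keeps the
        augmented matrices small and well-conditioned.
    """

    def __init__(self, n_filters: int = 4, shrinkage: float = 1e-2,
                 filter_data: bool = True):
        self.n_filters = n_filters
        self.shrinkage = shrinkage
        self.filter_data = filter_data

    def _super_trials(self, X: np.ndarray) -> np.ndarray:
        if self.filter_data:
            v = np.hstack([self._filters[c] for c in self._classes])
            return np.einsum("cf,ncs->nfs", v, X)
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "XdawnTangentSpaceLDA":
        """Fit on epochs X (trials x channels x time) and binary labels y."""
        y = np.asarray(y)
        self._classes = sorted(int(c) for c in np.unique(y))
        if len(self._classes) != 2:
            raise ValueError("binary classification requires two classes")
        self._filters = xdawn_filters(X, y, self.n_filters)
        protos = []
        for cls in self._classes:
            evoked = X[y == cls].mean(axis=0)
            protos.append(self._filters[cls].T @ evoked)
        self._prototypes = np.vstack(protos)
        covs = augmented_covariances(self._super_trials(X), self._prototypes,
                                     self.shrinkage)
        self._reference = geometric_mean(covs)
        vecs = tangent_space(covs, self._reference)
        self._lda = LinearDiscriminantAnalysis(solver="svd")
        self._lda.fit(vecs, y)
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        covs = augmented_covariances(self._super_trials(X), self._prototypes,
                                     self.shrinkage)
        return tangent_space(covs, self._reference)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._lda.decision_function(self._transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._lda.predict(self._transform(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._lda.predict_proba(self._transform(X))


def fit_riemann(X: np.ndarray, y: np.ndarray, seed: int = 0,
                n_filters: int = 4) -> XdawnTangentSpaceLDA:
    """Fit the Riemannian pipeline on interest-window epochs.

    ``seed`` is accepted for interface symmetry; the pipeline is
    deterministic.
    """
    return XdawnTangentSpaceLDA(n_filters=n_filters).fit(X, y)
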