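"""Conventional linear classifiers on time-domain features.

Both families share the preprocessing head — standardization and PCA keeping
the minimal leading set of components whose explained variance sums to at
least 95% — followed by a hyperparameter-tuned classifier:

* LDA, solver tuned over {svd, lsqr, eigen};
* SVC with an RBF kernel, regularization strength C and kernel coefficient
  gamma tuned on logarithmic grids.

Tuning uses an inner 5-fold cross-validated grid search with ROC-AUC scoring.
Everything (scaler, PCA, grid search) is fitted strictly on training data.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

SVC_GRID = {
    "clf__C": np.logspace(-2, 3, 6),
    "clf__gamma": np.logspace(-4, 1, 6),
}
LDA_GRID = {"clf__solver": ["svd", "lsqr", "eigen"]}


def build_linear_model(model: str, seed: int = 0,
                       inner_splits: int = 5) -> GridSearchCV:
    """Unfitted scaler -> PCA(95%) -> grid-searched LDA or RBF-SVC."""
    if model == "lda":
        clf, grid = LinearDiscriminantAnalysis(), LDA_GRID
    elif model == "svc":
        clf, grid = SVC(kernel="rbf"), SVC_GRID
    else:
        raise ValueError(f"unknown linear model '{model}' (lda or svc)")
    pipe = Pipeline([
        ("scaler", StandardScaler()),
        ("pca", PCA(n_components=0.95, svd_solver="full")),
        ("clf", clf),
    ])
    inner = StratifiedKFold(n_splits=inner_splits, shuffle=True,
                            random_state=seed)
    return GridSearchCV(pipe, grid, cv=inner, scoring="roc_auc", n_jobs=1)


def fit_linear(features: FeatureMatrix, model: str, seed: int = 0):
    """Fit a tuned linear pipeline on a feature matrix.

    Returns the fitted :class:`~sklearn.model_selection.GridSearchCV`; use
    ``decision_function`` for ROC scoring.
    """
    y = features.y()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    est = build_linear_model(model, seed=seed)
    est.fit(features.X, y)
    return est
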