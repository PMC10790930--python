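"""Cross-validation and calibration harnesses for the four ErrP classifiers.

``evaluate_cv`` runs the outer repeated stratified k-fold protocol (5 splits,
10 repeats by default -> 50 train/test ROC-AUC pairs) for any of the four
model families and summarizes the score distributions with a percentile
bootstrap (5,000 iterations, optionally Bonferroni-corrected).

``calibrate_bci`` performs the stratified 70/15/15 train/validation/test
split used to calibrate the online BCI: the validation set drives the CNN's
plateau schedule and model selection, and the held-out test ROC-AUC is
reported as the BCI's decoding quality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .cnn import CNNConfig, EEGNetClassifier
from .containers import EpochSet
from .erpstats import BootstrapSummary, bootstrap_mean
from .features import extract_features
from .linear import build_linear_model
from .riemann import XdawnTangentSpaceLDA

MODELS = ("lda", "svc", "riemann", "cnn")


@dataclass
class CVScores:
    """Per-fold train/test ROC-AUC for one (model, montage) pair."""

    model: str
    montage: str
    train_scores: list
    test_scores: list
    train_summary: BootstrapSummary | None = None
    test_summary: BootstrapSummary | None = None
    n_splits: int = 5
    n_repeats: int = 10

    def __post_init__(self):
        for s in list(self.train_scores) + list(self.test_scores):
            if not (0.0 <= s <= 1.0):
                raise ValueError("ROC-AUC scores must lie in [0, 1]")
        expected = self.n_splits * self.n_repeats
        if len(self.test_scores) != expected:
            raise ValueError(
                f"expected {expected} scores, got {len(self.test_scores)}")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, default=float)


def _score_model(model: str, seed: int, cnn_cfg: CNNConfig | None):
    """Return (fit_fn, score_fn) closures for one model family.

    ``fit_fn(Xtr, ytr) -> fitted``; ``score_fn(fitted, X) -> scores``
    where X is a feature matrix (lda/svc) or epochs array (riemann/cnn).
    """
    if model in ("lda", "svc"):
        from .linear import build_linear_model

        def fit_fn(X, y, fold_seed):
            est = build_linear_model(model, seed=fold_seed)
            est.fit(X, y)
            return est

        def score_fn(est, X):
            return est.decision_function(X)

    elif model == "riemann":
        def fit_fn(X, y, fold_seed):
            return XdawnTangentSpaceLDA().fit(X, y)

        def score_fn(est, X):
            return est.decision_function(X)

    elif model == "cnn":
        def fit_fn(X, y, fold_seed):
            cfg = cnn_cfg or CNNConfig(n_channels=X.shape[1],
                                       n_samples=X.shape[2])
            cfg = replace(cfg, n_channels=X.shape[1], n_samples=X.shape[2])
            # inner stratified validation split drives the plateau schedule
            idx_tr, idx_val = train_test_split(
                np.arange(len(y)), test_size=0.15, stratify=y,
                random_state=fold_seed)
            clf = EEGNetClassifier(cfg, seed=fold_seed)
            clf.fit(X[idx_tr], y[idx_tr], X[idx_val], y[idx_val])
            return clf

        def score_fn(est, X):
            return est.decision_function(X)

    else:
        raise ValueError(f"unknown model '{model}' (expected one of {MODELS})")
    return fit_fn, score_fn


def evaluate_cv(epochs: EpochSet, model: str, seed: int = 0,
                n_splits: int = 5, n_repeats: int = 10,
                n_boot: int = 5000, bonferroni_m: int = 1,
                montage: str = "custom",
                cnn_cfg: CNNConfig | None = None) -> CVScores:
    """Repeated stratified k-fold evaluation of one classifier family.

    ``epochs`` must already be cut to the interest window.  All fitting
    (scaling, PCA, grid search, xDAWN, network weights) happens strictly
    inside training folds.  Returns per-fold train and test ROC-AUC plus
    bootstrap summaries of both distributions.
    """
    y = epochs.y()
    if min(np.bincount(y)) < n_splits:
        raise ValueError("fewer minority-class trials than folds")
    if model in ("lda", "svc"):
        X = extract_features(epochs).X
    else:
        X = epochs.data
    fit_fn, score_fn = _score_model(model, seed, cnn_cfg)
    splitter = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                       random_state=seed)
    train_scores, test_scores = [], []
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        fold_seed = (seed * 10007 + fold) % (2 ** 31)
        est = fit_fn(X[tr], y[tr], fold_seed)
        train_scores.append(roc_auc_score(y[tr], score_fn(est, X[tr])))
        test_scores.append(roc_auc_score(y[te], score_fn(est, X[te])))
    scores = CVScores(model=model, montage=montage,
                      train_scores=train_scores, test_scores=test_scores,
                      n_splits=n_splits, n_repeats=n_repeats)
    scores.train_summary = bootstrap_mean(train_scores, n_boot=n_boot,
                                          bonferroni_m=bonferroni_m, seed=seed)
    scores.test_summary = bootstrap_mean(test_scores, n_boot=n_boot,
                                         bonferroni_m=bonferroni_m, seed=seed)
    return scores


def calibration_split_sizes(n: int) -> tuple:
    """Sizes of the stratified 70/15/15 train/validation/test split."""
    n_test = int(round(n * 0.15))
    n_val = int(round(n * 0.15))
    return n - n_val - n_test, n_val, n_test


def calibrate_bci(epochs: EpochSet, cfg: CNNConfig | None = None,
                  seed: int = 0):
    """Calibrate the CNN-based BCI with a stratified 70/15/15 split.

    Returns ``(fitted EEGNetClassifier, test ROC-AUC)``.  The classifier's
    ``decision_function`` gives the per-trial error probability.
    """
    y = epochs.y()
    if min(np.bincount(y)) < 3:
        raise ValueError("too few trials per class to stratify a 70/15/15 split")
    X = epochs.data
    n = len(y)
    n_train, n_val, n_test = calibration_split_sizes(n)
    idx = np.arange(n)
    idx_rest, idx_test = train_test_split(idx, test_size=n_test, stratify=y,
                                          random_state=seed)
    idx_train, idx_val = train_test_split(idx_rest, test_size=n_val,
                                          stratify=y[idx_rest],
                                          random_state=seed)
    if cfg is None:
        cfg = CNNConfig(n_channels=X.shape[1], n_samples=X.shape[2])
    else:
        cfg = replace(cfg, n_channels=X.shape[1], n_samples=X.shape[2])
    clf = EEGNetClassifier(cfg, seed=seed)
    clf.fit(X[idx_train], y[idx_train], X[idx_val], y[idx_val])
    test_auc = float(roc_auc_score(y[idx_test],
                                   clf.decision_function(X[idx_test])))
    clf.split_indices_ = {"train": idx_train.tolist(), "val": idx_val.tolist(),
                          "test": idx_test.tolist()}
    return clf, test_auc
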