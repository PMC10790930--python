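"""Per-channel time-domain feature extraction for the linear classifiers.

For every trial and channel, five statistics of the interest-window signal:
mean amplitude, skewness, kurtosis, standard deviation (sample, n-1), and
peak-to-peak amplitude — channel-major column order, 5 x n_channels columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import EpochSet

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("mean", "skewness", "kurtosis", "std", "ptp")


@dataclass
class FeatureMatrix:
    """Trials x (5 * channels) feature array with aligned labels."""

    X: np.ndarray
    labels: np.ndarray
    column_names: list

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def y(self) -> np.ndarray:
        return np.array([1 if l == "error" else 0 for l in self.labels])


def extract_features(epochs: EpochSet) -> FeatureMatrix:
    """Extract the five time-domain statistics per channel and trial.

    Skewness and kurtosis of a constant channel are undefined; they are set
    to 0 by convention with a logged warning.  Standard deviation uses the
    sample (n-1) convention.
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot extract features from an empty EpochSet")
    x = epochs.data  # (n, C, T)
    mean = x.mean(axis=2)
    std = x.std(axis=2, ddof=1)
    ptp = x.max(axis=2) - x.min(axis=2)
    constant = std == 0
    import warnings as _warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            _warnings.catch_warnings():
        # constant channels trigger a scipy precision warning; they are
        # handled by the 0-by-convention rule below
        _warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(x, axis=2)
        kurt = stats.kurtosis(x, axis=2)
    if constant.any():
        logger.warning("constant channel(s) in %d trial-channel pairs; "
                       "skewness/kurtosis set to 0", int(constant.sum()))
        skew = np.where(constant, 0.0, skew)
        kurt = np.where(constant, 0.0, kurt)
    skew = np.nan_to_num(skew, nan=0.0)
    kurt = np.nan_to_num(kurt, nan=0.0)

    # channel-major ordering: [ch0_mean, ch0_skew, ..., ch0_ptp, ch1_mean, ...]
    per_stat = np.stack([mean, skew, kurt, std, ptp], axis=2)  # (n, C, 5)
    X = per_stat.reshape(epochs.n_trials, -1)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values after degenerate handling")
    names = [f"{ch}_{feat}" for ch in epochs.channel_names
             for feat in FEATURE_NAMES]
    return FeatureMatrix(X=X, labels=epochs.labels.copy(), column_names=names)
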