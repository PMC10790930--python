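"""Grand averages, difference waves, SNR, and bootstrap-CI statistics.

The statistical machinery is deliberately simple and mirrors common ERP
practice: percentile bootstrap of means with optional Bonferroni correction,
and a CI-overlap rule for qualitative significance statements
(disjoint CIs -> p < 0.01; overlapping CIs with both means excluded from the
other interval -> p < 0.05; otherwise not significant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet


@dataclass(frozen=True)
class ERPWaveform:
    """Trial- and channel-group-averaged ERP trace for one condition."""

    mean_trace: np.ndarray            # 1-D, microvolts, group-averaged
    condition: str                    # "error" | "true" | "difference"
    n_trials: int
    rate: float

    def __post_init__(self):
        if self.condition not in ("error", "true", "difference"):
            raise ValueError(f"unknown condition '{self.condition}'")
        if self.condition != "difference" and self.n_trials <= 0:
            raise ValueError("n_trials must be positive")


@dataclass(frozen=True)
class BootstrapSummary:
    """Percentile-bootstrap mean and (Bonferroni-corrected) CI."""

    mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    alpha: float = 0.05
    bonferroni_m: int = 1

    def __post_init__(self):
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("CI must bracket the mean")


def grand_average(epochs: EpochSet, channel_group) -> dict:
    """Grand-average waveforms per condition plus the difference wave.

    Averages over trials, then over the named channel group.  Returns a dict
    with keys ``error``, ``true`` and ``difference`` (difference =
    error - true, exactly).
    """
    for name in channel_group:
        if name not in epochs.channel_names:
            raise KeyError(f"channel '{name}' not present in the epochs")
    sub = epochs.select_channels(channel_group)
    out = {}
    traces = {}
    for cond in ("error", "true"):
        mask = sub.labels == cond
        if not mask.any():
            raise ValueError(f"no '{cond}' trials present")
        trace = sub.data[mask].mean(axis=0).mean(axis=0)
        traces[cond] = trace
        out[cond] = ERPWaveform(trace, cond, int(mask.sum()), sub.rate)
    out["difference"] = ERPWaveform(traces["error"] - traces["true"],
                                    "difference", 0, sub.rate)
    return out


def difference_trace(epochs: EpochSet, channel_group) -> np.ndarray:
    """Error-minus-true grand-average trace over a channel group."""
    return grand_average(epochs, channel_group)["difference"].mean_trace


def snr(epochs: EpochSet, channel_group, interval: tuple,
        amplitude_mode: str = "absolute") -> float:
    """Signal-to-noise ratio of the ErrP difference wave in a time interval.

    The error-minus-true difference of trial-averaged signals is averaged
    over the channel group; within ``interval`` (seconds, half-open), the
    amplitude (mean of the trace, magnitude by default) is divided by the
    standard deviation of the trace across the interval's time samples.
    Dimensionless.  ``amplitude_mode``: ``absolute`` (default) or ``signed``.
    """
    if amplitude_mode not in ("absolute", "signed"):
        raise ValueError("amplitude_mode must be 'absolute' or 'signed'")
    diff = difference_trace(epochs, channel_group)
    t = epochs.times
    mask = (t >= interval[0]) & (t < interval[1])
    if mask.sum() < 3:
        raise ValueError("interval must contain at least 3 samples")
    seg = diff[mask]
    noise = seg.std(ddof=0)
    amp = seg.mean()
    if amplitude_mode == "absolute":
        amp = abs(amp)
    if noise == 0:
        if amp == 0:
            return 0.0
        raise ZeroDivisionError(
            "zero temporal variability in the interval; SNR undefined")
    return float(amp / noise)


def bootstrap_mean(values, n_boot: int = 5000, alpha: float = 0.05,
                   bonferroni_m: int = 1, seed: int = 0) -> BootstrapSummary:
    """Percentile bootstrap of the mean with Bonferroni-corrected quantiles.

    Quantile levels are alpha/(2 m) and 1 - alpha/(2 m) for ``m`` planned
    comparisons.  Deterministic under a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if values.size < 2:
        raise ValueError("bootstrap requires at least 2 values")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot_means = values[idx].mean(axis=1)
    lo_q = alpha / (2 * bonferroni_m)
    ci_low, ci_high = np.quantile(boot_means, [lo_q, 1 - lo_q])
    mean = float(boot_means.mean())
    # guard against degenerate float ordering in the all-equal case
    ci_low = min(float(ci_low), mean)
    ci_high = max(float(ci_high), mean)
    return BootstrapSummary(mean=mean, ci_low=ci_low, ci_high=ci_high,
                            n_boot=n_boot, alpha=alpha,
                            bonferroni_m=bonferroni_m)


def ci_overlap_verdict(a: BootstrapSummary, b: BootstrapSummary) -> str:
    """CI-overlap significance rule.  Returns 'p<0.01', 'p<0.05' or 'n.s.'.

    Disjoint CIs indicate strong evidence (p < 0.01); overlapping CIs with
    neither mean inside the other's CI indicate moderate evidence (p < 0.05);
    anything else is not significant.  Symmetric in its arguments.
    """
    if a.alpha != b.alpha:
        raise ValueError("summaries must use the same alpha")
    disjoint = a.ci_high < b.ci_low or b.ci_high < a.ci_low
    if disjoint:
        return "p<0.01"
    a_mean_inside_b = b.ci_low <= a.mean <= b.ci_high
    b_mean_inside_a = a.ci_low <= b.mean <= a.ci_high
    if not a_mean_inside_b and not b_mean_inside_a:
        return "p<0.05"
    return "n.s."
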