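"""SPL navigation metric and learning-curve aggregation.

SPL (success weighted by normalized path length) for one episode is
``S * l / max(p, l)`` with S the success flag, l the shortest-path length
from the episode's start to its goal, and p the path length actually taken
(executed moves, *including* collision-blocked attempts, which therefore
penalize the score).  A set of episodes is summarized by the arithmetic
mean.

``aggregate_runs`` compares collections of per-episode SPL traces (one per
trained model/seed): pointwise bootstrap over whole runs for the mean curve
and its 95% band (1,000 iterations by default), plus a final-window summary
per run bootstrapped across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .erpstats import BootstrapSummary, bootstrap_mean


def spl(success: bool, shortest: int, taken: int) -> float:
    """Single-episode SPL: S * l / max(p, l)."""
    if not success:
        return 0.0
    if shortest < 0 or taken < 0:
        raise ValueError("path lengths must be non-negative")
    if shortest == 0:  # started on the goal
        return 1.0
    if taken == 0:
        raise ValueError("successful episode with zero executed moves "
                         "but a positive shortest path")
    return float(shortest / max(taken, shortest))


@dataclass
class EpisodeRecord:
    episode: int
    success: bool
    shortest: int
    taken: int
    spl: float


@dataclass
class RunCurve:
    """Per-episode SPL trace of one trained RL model."""

    mode: str
    seed: int
    records: list = field(default_factory=list)
    config_hash: str = ""

    def append(self, success: bool, shortest: int, taken: int) -> None:
        value = spl(success, shortest, taken)
        self.records.append(EpisodeRecord(len(self.records), bool(success),
                                          int(shortest), int(taken), value))

    @property
    def spl_values(self) -> np.ndarray:
        return np.array([r.spl for r in self.records])

    def final_window_mean(self, window: int) -> float:
        values = self.spl_values
        if len(values) == 0:
            raise ValueError("empty run curve")
        return float(values[-window:].mean())

    def to_json(self) -> str:
        return json.dumps({"mode": self.mode, "seed": self.seed,
                           "config_hash": self.config_hash,
                           "records": [asdict(r) for r in self.records]})

    @classmethod
    def from_json(cls, text: str) -> "RunCurve":
        d = json.loads(text)
        rc = cls(mode=d["mode"], seed=d["seed"],
                 config_hash=d.get("config_hash", ""))
        rc.records = [EpisodeRecord(**r) for r in d["records"]]
        return rc


@dataclass
class ComparisonReport:
    """Bootstrap summary of a collection of runs for one mode."""

    mode: str
    n_runs: int
    n_episodes: int
    mean_curve: list
    band_low: list
    band_high: list
    final_summary: BootstrapSummary
    overall_summary: BootstrapSummary
    n_boot: int
    final_window: int

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, default=float)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        d = json.loads(text)
        d["final_summary"] = BootstrapSummary(**d["final_summary"])
        d["overall_summary"] = BootstrapSummary(**d["overall_summary"])
        d["final_summary"] = d["final_summary"]
        return cls(**d)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def aggregate_runs(curves: list, n_boot: int = 1000,
                   smoothing_window: int = 1, final_window: int = 50,
                   seed: int = 0) -> ComparisonReport:
    """Aggregate >= 2 equal-length runs of one mode into a ComparisonReport.

    The mean curve and its 95% band come from a pointwise bootstrap that
    resamples whole runs; final performance is the mean SPL over the last
    ``final_window`` episodes per run, bootstrapped across runs.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 runs to aggregate")
    lengths = {len(c.records) for c in curves}
    if len(lengths) != 1:
        raise ValueError("runs must have equal episode counts")
    n_episodes = lengths.pop()
    if n_episodes == 0:
        raise ValueError("runs are empty")
    mode = curves[0].mode
    mat = np.stack([_moving_average(c.spl_values, smoothing_window)
                    for c in curves])          # (runs, episodes)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(curves), size=(n_boot, len(curves)))
    boot_curves = mat[idx].mean(axis=1)        # (n_boot, episodes)
    mean_curve = boot_curves.mean(axis=0)
    band_low, band_high = np.quantile(boot_curves, [0.025, 0.975], axis=0)
    band_low = np.minimum(band_low, mean_curve)
    band_high = np.maximum(band_high, mean_curve)

    finals = [c.final_window_mean(final_window) for c in curves]
    final_summary = bootstrap_mean(finals, n_boot=n_boot, seed=seed)
    overall = [float(c.spl_values.mean()) for c in curves]
    overall_summary = bootstrap_mean(overall, n_boot=n_boot, seed=seed)
    return ComparisonReport(mode=mode, n_runs=len(curves),
                            n_episodes=n_episodes,
                            mean_curve=mean_curve.tolist(),
                            band_low=band_low.tolist(),
                            band_high=band_high.tolist(),
                            final_summary=final_summary,
                            overall_summary=overall_summary,
                            n_boot=n_boot, final_window=final_window)
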