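"""Synthetic ErrP EEG generator.

Emulates the statistical structure of EEG recorded while a person watches a
robot act: every observed action evokes a small shared visual/motor-onset
response; *erroneous* actions additionally evoke an error-related potential
(ErrP) — a frontocentral negativity around 200 ms (N200) followed by a delayed
positivity around 300–600 ms.  The two components are modelled as Gaussian
bumps in time, projected across the scalp by the montage's frontocentral
weights, and buried in 1/f (or white) background noise.

Amplitude and noise defaults are free parameters of the generator (single-trial
ErrP amplitudes are not published); they are set so that the downstream
classifiers reach plausible, clearly-above-chance but imperfect single-trial
accuracy.  See docs/methods.md.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .containers import EpochSet, SubjectRecording
from .montages import MontageSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErrPModel:
    """Parametric ErrP template plus background-noise model.

    All latencies/widths in seconds, amplitudes in microvolts.  ``n200``
    parameters describe the early negativity, ``p300`` the delayed positivity.
    Setting both amplitudes to 0 gives the null model (no class difference).
    """

    n200_latency: float = 0.20
    n200_width: float = 0.045
    n200_amplitude: float = -5.0
    p300_latency: float = 0.45
    p300_width: float = 0.09
    p300_amplitude: float = 6.0
    trial_latency_jitter_sd: float = 0.02
    subject_amplitude_scale: float = 1.0
    noise_sd: float = 6.0
    noise_spectrum: str = "one_over_f"
    # shared evoked response present in BOTH classes (action-onset potential)
    shared_amplitude: float = 1.5
    shared_latency: float = 0.30
    shared_width: float = 0.12

    def __post_init__(self):
        if self.n200_width <= 0 or self.p300_width <= 0 or self.shared_width <= 0:
            raise ValueError("component widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for a in (self.n200_amplitude, self.p300_amplitude, self.shared_amplitude):
            if not np.isfinite(a):
                raise ValueError("amplitudes must be finite")
        if self.noise_spectrum not in ("white", "one_over_f"):
            raise ValueError("noise_spectrum must be 'white' or 'one_over_f'")

    def null(self) -> "ErrPModel":
        """Copy with zero error-related amplitudes (no class difference)."""
        return replace(self, n200_amplitude=0.0, p300_amplitude=0.0)

    def scaled(self, factor: float) -> "ErrPModel":
        """Copy with both ErrP amplitudes scaled by ``factor`` (effect size)."""
        return replace(self,
                       n200_amplitude=self.n200_amplitude * factor,
                       p300_amplitude=self.p300_amplitude * factor)


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def errp_template(errp: ErrPModel, rate: float, duration: float = 1.0,
                  jitter: float = 0.0) -> np.ndarray:
    """Error-minus-true template (1-D, microvolts) over [0, duration) s."""
    t = np.arange(int(round(duration * rate))) / rate
    scale = errp.subject_amplitude_scale
    return scale * (
        errp.n200_amplitude * _gauss(t, errp.n200_latency + jitter, errp.n200_width)
        + errp.p300_amplitude * _gauss(t, errp.p300_latency + jitter, errp.p300_width)
    )


def _shared_template(errp: ErrPModel, rate: float, duration: float = 1.0,
                     jitter: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration * rate))) / rate
    return (errp.subject_amplitude_scale * errp.shared_amplitude
            * _gauss(t, errp.shared_latency + jitter, errp.shared_width))


def _background_noise(rng: np.random.Generator, n_channels: int, n_times: int,
                      sd: float, spectrum: str) -> np.ndarray:
    """Channel-independent background noise with white or 1/f spectrum."""
    if sd == 0:
        return np.zeros((n_channels, n_times))
    white = rng.standard_normal((n_channels, n_times))
    if spectrum == "white":
        return sd * white
    # 1/f: shape the amplitude spectrum of white noise by f^-0.5 (power ~ 1/f)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_times)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** -0.5
    shaping[0] = 0.0  # no DC drift term
    shaped = np.fft.irfft(spec * shaping, n=n_times, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    return sd * shaped


def error_schedule(n_trials: int, error_fraction: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Fixed-count error schedule: exactly round(n*f) error trials, shuffled.

    Returns a boolean array of length ``n_trials`` (True = error trial).
    A fixed count, rather than Bernoulli sampling, reproduces exact trial
    totals (e.g. 100 errors of 500 at 20%).
    """
    if not (0.0 <= error_fraction <= 1.0):
        raise ValueError("error_fraction must lie in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n_err = int(round(n_trials * error_fraction))
    flags = np.zeros(n_trials, dtype=bool)
    flags[:n_err] = True
    rng.shuffle(flags)
    return flags


def generate_recording(montage: MontageSpec, errp: ErrPModel = ErrPModel(),
                       n_trials: int = 500, error_fraction: float = 0.20,
                       inter_trial_interval: float = 2.0,
                       seed: int = 0,
                       error_flags: np.ndarray | None = None) -> SubjectRecording:
    """Simulate one continuous recording of observed robot actions.

    Trials are spaced ``inter_trial_interval`` seconds apart; each action
    onset is an event.  Error trials carry the ErrP template (spatially
    weighted by ``montage.frontocentral_weights``) on top of background
    noise; both classes carry a small shared evoked component.  Identical
    ``(seed, parameters)`` give identical output.

    ``error_flags`` optionally overrides the internal fixed-count schedule
    with a caller-supplied boolean trial sequence (e.g. from the environment
    trial scheduler), keeping EEG labels aligned with simulated behaviour.
    """
    rate = montage.sampling_rate
    epoch_span = 1.0  # template support after onset, s
    if inter_trial_interval < epoch_span + 0.2:
        raise ValueError("inter_trial_interval shorter than the epoch span")
    rng = np.random.default_rng(seed)
    if error_flags is None:
        flags = error_schedule(n_trials, error_fraction, rng)
    else:
        flags = np.asarray(error_flags, dtype=bool)
        if len(flags) != n_trials:
            raise ValueError("error_flags length must equal n_trials")

    pre_roll = 1.0  # s of signal before the first and after the last trial
    n_times = int(round((2 * pre_roll + n_trials * inter_trial_interval) * rate))
    samples = _background_noise(rng, montage.n_channels, n_times,
                                errp.noise_sd, errp.noise_spectrum)

    weights = np.asarray(montage.frontocentral_weights)[:, None]
    n_template = int(round(epoch_span * rate))
    events = []
    for i, is_error in enumerate(flags):
        onset = int(round((pre_roll + i * inter_trial_interval) * rate))
        jitter = rng.normal(0.0, errp.trial_latency_jitter_sd)
        evoked = _shared_template(errp, rate, epoch_span, jitter)
        if is_error:
            evoked = evoked + errp_template(errp, rate, epoch_span, jitter)
        samples[:, onset:onset + n_template] += weights * evoked[None, :]
        events.append((onset, "error" if is_error else "true"))

    return SubjectRecording(samples=samples, events=events, montage=montage,
                            seed=seed)


def epoch_ground_truth(recording: SubjectRecording,
                       window: tuple = (-0.2, 1.0)) -> EpochSet:
    """Cut epochs directly from the raw recording (no preprocessing).

    Windows are half-open ``[start, stop)`` in seconds relative to each
    event; at 250 Hz the default window yields 300 samples.  Events whose
    window would leave the recording are dropped with a warning.
    """
    rate = recording.rate
    start = int(round(window[0] * rate))
    stop = int(round(window[1] * rate))
    if stop <= start:
        raise ValueError("window stop must exceed window start")
    n_times = recording.n_times
    data, labels = [], []
    dropped = 0
    for idx, label in recording.events:
        lo, hi = idx + start, idx + stop
        if lo < 0 or hi > n_times:
            dropped += 1
            continue
        data.append(recording.samples[:, lo:hi])
        labels.append(label)
    if dropped:
        msg = f"dropped {dropped} epoch(s) exceeding recording bounds"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    n_samp = stop - start
    arr = (np.array(data) if data
           else np.zeros((0, recording.n_channels, n_samp)))
    return EpochSet(data=arr, labels=np.array(labels, dtype=object),
                    rate=rate, channel_names=list(recording.montage.channel_names),
                    time_zero_index=-start)
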