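"""Offline EEG preprocessing chain for ErrP decoding.

Pipeline order (applied to the continuous recording):

1. linear detrend
2. zero-pad both ends (suppresses filter edge transients)
3. 50 Hz power-line notch — 4th-order IIR Butterworth band-stop, 2 Hz wide
4. [1, 10] Hz band-pass — 4th-order IIR Butterworth
5. remove the padding
6. common average reference (CAR)
7. downsample to 250 Hz when recorded faster (polyphase)
8. cut stimulus-locked epochs of 1.2 s (-0.2 to 1.0 s around action onset)
9. baseline-correct each trial/channel by the mean of the -0.2–0 s window

Filters are applied zero-phase (forward-backward), which preserves component
latencies in offline analysis.  The decoding window of interest (0.2–0.8 s) is
cut afterwards with :func:`extract_interest_window`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EpochSet, SubjectRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocConfig:
    """Parameters of the preprocessing chain (defaults = study settings)."""

    notch_hz: float = 50.0
    notch_order: int = 4
    notch_width_hz: float = 2.0
    band: tuple = (1.0, 10.0)
    band_order: int = 4
    target_rate: float = 250.0
    epoch_window: tuple = (-0.2, 1.0)
    baseline_window: tuple = (-0.2, 0.0)
    interest_window: tuple = (0.2, 0.8)
    pad_seconds: float = 1.0

    def __post_init__(self):
        if self.band[0] >= self.band[1]:
            raise ValueError("band low cut must be below high cut")
        if not (self.epoch_window[0] <= self.interest_window[0]
                and self.interest_window[1] <= self.epoch_window[1]):
            raise ValueError("interest window must lie inside the epoch window")
        if self.notch_order % 2 or self.band_order % 2:
            raise ValueError("IIR orders must be even (band-stop/band-pass designs)")


def _filter_sos(cfg: PreprocConfig, rate: float):
    """Second-order sections for notch (band-stop) and band-pass filters.

    ``scipy.signal.butter`` takes the design order N; a band-stop/band-pass of
    design order N has overall filter order 2N, so N = order // 2.
    """
    half = cfg.notch_width_hz / 2.0
    notch = signal.butter(cfg.notch_order // 2,
                          [cfg.notch_hz - half, cfg.notch_hz + half],
                          btype="bandstop", fs=rate, output="sos")
    band = signal.butter(cfg.band_order // 2, list(cfg.band),
                         btype="bandpass", fs=rate, output="sos")
    return notch, band


def filter_chain_attenuation_db(cfg: PreprocConfig, rate: float,
                                freq_hz: float) -> float:
    """Magnitude attenuation (dB, positive = attenuated) of the composed
    zero-phase notch + band-pass chain at ``freq_hz``."""
    notch, band = _filter_sos(cfg, rate)
    w = [2 * np.pi * freq_hz / rate]
    _, h1 = signal.sosfreqz(notch, worN=w)
    _, h2 = signal.sosfreqz(band, worN=w)
    # filtfilt applies each filter twice -> squared magnitude response
    mag = (np.abs(h1[0]) * np.abs(h2[0])) ** 2
    return float(-20 * np.log10(max(mag, 1e-300)))


def baseline_correct(epochs: EpochSet, baseline_window: tuple) -> EpochSet:
    """Subtract the per-trial per-channel mean of the baseline window.

    Idempotent: applying it twice equals applying it once.
    """
    t = epochs.times
    mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(epochs.data - base, epochs.labels.copy(), epochs.rate,
                    list(epochs.channel_names), epochs.time_zero_index)


def preprocess_recording(recording: SubjectRecording,
                         cfg: PreprocConfig = PreprocConfig()) -> EpochSet:
    """Run the full preprocessing chain and return baseline-corrected epochs."""
    rate = recording.rate
    if rate not in (250.0, 500.0):
        warnings.warn(f"unusual sampling rate {rate} Hz; pipeline proceeds",
                      stacklevel=2)
    x = recording.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("recording contains non-finite samples")

    # 1. detrend the continuous signal
    x = signal.detrend(x, axis=1, type="linear")

    # 2. zero-pad, 3-4. zero-phase notch + band-pass, 5. unpad
    pad = int(round(cfg.pad_seconds * rate))
    xp = np.pad(x, ((0, 0), (pad, pad)))
    notch, band = _filter_sos(cfg, rate)
    xp = signal.sosfiltfilt(notch, xp, axis=1)
    xp = signal.sosfiltfilt(band, xp, axis=1)
    x = xp[:, pad:-pad] if pad else xp

    # 6. common average reference
    x = x - x.mean(axis=0, keepdims=True)

    # 7. downsample (after CAR) when recorded faster than the target rate
    events = list(recording.events)
    if rate > cfg.target_rate:
        up, down = (int(cfg.target_rate), int(rate))
        from math import gcd
        g = gcd(up, down)
        up, down = up // g, down // g
        x = signal.resample_poly(x, up, down, axis=1)
        scale = cfg.target_rate / rate
        events = [(int(round(i * scale)), l) for i, l in events]
        rate = cfg.target_rate

    # 8. epoch (half-open windows)
    start = int(round(cfg.epoch_window[0] * rate))
    stop = int(round(cfg.epoch_window[1] * rate))
    n_times = x.shape[1]
    data, labels, dropped = [], [], 0
    for idx, label in events:
        lo, hi = idx + start, idx + stop
        if lo < 0 or hi > n_times:
            dropped += 1
            continue
        data.append(x[:, lo:hi])
        labels.append(label)
    if dropped:
        logger.warning("dropped %d epoch(s) too close to the recording edge",
                       dropped)
    arr = (np.array(data) if data
           else np.zeros((0, x.shape[0], stop - start)))
    epochs = EpochSet(arr, np.array(labels, dtype=object), rate,
                      list(recording.montage.channel_names),
                      time_zero_index=-start)

    # 9. baseline correction on the full epoch
    return baseline_correct(epochs, cfg.baseline_window)


def extract_interest_window(epochs: EpochSet,
                            cfg: PreprocConfig = PreprocConfig()) -> EpochSet:
    """Cut the decoding window of interest (default 0.2–0.8 s, half-open).

    At 250 Hz the default window is 150 samples.  Labels are carried through
    unchanged; ``time_zero_index`` becomes relative to the new first sample
    (negative when onset precedes the window).
    """
    rate = epochs.rate
    lo = epochs.time_zero_index + int(round(cfg.interest_window[0] * rate))
    hi = epochs.time_zero_index + int(round(cfg.interest_window[1] * rate))
    if epochs.n_trials and (lo < 0 or hi > epochs.n_times):
        raise ValueError("interest window lies outside the epoch span")
    return EpochSet(epochs.data[:, :, lo:hi], epochs.labels.copy(), rate,
                    list(epochs.channel_names),
                    time_zero_index=epochs.time_zero_index - lo)
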