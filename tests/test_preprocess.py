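"""Preprocessing chain: filter responses, CAR, resampling, baselines."""

import numpy as np
import pytest

from errpnav.containers import SubjectRecording
from errpnav.montages import get_montage
from errpnav.preprocess import (PreprocConfig, baseline_correct,
                                extract_interest_window,
                                filter_chain_attenuation_db,
                                preprocess_recording)
from errpnav.simulate import ErrPModel, generate_recording


def _recording_from_array(x, montage, events):
    return SubjectRecording(samples=x, events=events, montage=montage)


class TestFilterChain:
    def test_powerline_attenuated_at_least_40db(self):
        for rate in (250.0, 500.0):
            assert filter_chain_attenuation_db(PreprocConfig(), rate, 50.0) >= 40.0

    def test_50hz_sinusoid_suppressed_in_signal_domain(self):
        montage = get_montage("gel16")
        rate = montage.sampling_rate
        t = np.arange(int(20 * rate)) / rate
        sine = 10.0 * np.sin(2 * np.pi * 50.0 * t)
        x = np.tile(sine, (montage.n_channels, 1))
        # make channels differ so CAR does not annihilate the comparison
        x *= np.linspace(0.5, 1.5, montage.n_channels)[:, None]
        rec = _recording_from_array(x, montage, [(int(5 * rate), "true"),
                                                 (int(10 * rate), "error")])
        epochs = preprocess_recording(rec)
        in_rms = np.sqrt(np.mean(x ** 2))
        out_rms = np.sqrt(np.mean(epochs.data ** 2))
        assert out_rms < in_rms * 10 ** (-40 / 20)

    def test_dc_rejected(self):
        montage = get_montage("gel16")
        rate = montage.sampling_rate
        x = np.full((montage.n_channels, int(10 * rate)), 42.0)
        x *= np.linspace(0.5, 1.5, montage.n_channels)[:, None]
        rec = _recording_from_array(x, montage, [(int(5 * rate), "true"),
                                                 (int(6 * rate), "error")])
        epochs = preprocess_recording(rec)
        assert np.abs(epochs.data).max() < 1e-6

    def test_stable_on_long_white_noise(self):
        montage = get_montage("gel16")
        rng = np.random.default_rng(0)
        n = 10 ** 6 // montage.n_channels * montage.n_channels
        x = rng.standard_normal((montage.n_channels, 10 ** 6 // 16))
        rec = _recording_from_array(x, montage, [(1000, "true"),
                                                 (2000, "error")])
        epochs = preprocess_recording(rec)
        assert np.all(np.isfinite(epochs.data))


class TestPipeline:
    def test_downsampling_dry20(self, default_recording):
        epochs = preprocess_recording(default_recording)
        assert default_recording.rate == 500.0
        assert epochs.rate == 250.0
        assert epochs.n_times == 300           # (-0.2, 1.0) s at 250 Hz
        assert epochs.time_zero_index == 50

    def test_class_counts_preserved(self, default_recording, default_epochs):
        in_counts = {l: sum(1 for _, ll in default_recording.events if ll == l)
                     for l in ("error", "true")}
        out = default_epochs.labels
        assert {"error": (out == "error").sum(),
                "true": (out == "true").sum()} == in_counts

    def test_car_zero_mean_across_channels(self, dry20):
        """After CAR (and before trial baselining skews it), the channel
        mean is zero at every sample: check on a symmetric-baseline config."""
        rec = generate_recording(dry20, ErrPModel(), n_trials=20,
                                 error_fraction=0.5, seed=4)
        cfg = PreprocConfig(baseline_window=(-0.2, 1.0))  # full-epoch baseline
        epochs = preprocess_recording(rec, cfg)
        chan_mean = epochs.data.mean(axis=1)
        # baseline subtraction is per-channel constant, so the channel mean
        # stays zero within numerical tolerance
        assert np.abs(chan_mean).max() < 1e-9 * np.abs(epochs.data).max() + 1e-9

    def test_baseline_mean_zero_and_idempotent(self, default_epochs):
        cfg = PreprocConfig()
        t = default_epochs.times
        mask = (t >= -0.2) & (t < 0.0)
        base = default_epochs.data[:, :, mask].mean(axis=2)
        assert np.abs(base).max() < 1e-9
        again = baseline_correct(default_epochs, cfg.baseline_window)
        np.testing.assert_allclose(again.data, default_epochs.data, atol=1e-12)

    def test_nonfinite_input_rejected(self, dry20):
        x = np.zeros((20, 5000))
        x[3, 100] = np.nan
        rec = _recording_from_array(x, dry20, [(1000, "true")])
        with pytest.raises(ValueError, match="non-finite"):
            preprocess_recording(rec)


class TestInterestWindow:
    def test_index_arithmetic(self, default_epochs):
        wi = extract_interest_window(default_epochs)
        assert wi.n_times == 150               # [0.2, 0.8) s at 250 Hz
        assert wi.time_zero_index == -50       # onset 50 samples before window
        np.testing.assert_allclose(wi.times[0], 0.2)
        np.testing.assert_array_equal(wi.labels, default_epochs.labels)
        np.testing.assert_array_equal(
            wi.data, default_epochs.data[:, :, 100:250])

    def test_identity_when_interest_equals_epoch(self, default_epochs):
        cfg = PreprocConfig(epoch_window=(-0.2, 1.0),
                            interest_window=(-0.2, 1.0))
        wi = extract_interest_window(default_epochs, cfg)
        np.testing.assert_array_equal(wi.data, default_epochs.data)

    def test_empty_epochset_passes_through(self):
        from errpnav.containers import EpochSet
        empty = EpochSet(data=np.zeros((0, 4, 300)),
                         labels=np.array([], dtype=object), rate=250.0,
                         channel_names=list("abcd"), time_zero_index=50)
        wi = extract_interest_window(empty)
        assert wi.n_trials == 0
        assert wi.data.shape[2] == 150

    def test_window_outside_epoch_rejected(self, default_epochs):
        short = extract_interest_window(default_epochs)  # covers [0.2, 0.8)
        late = PreprocConfig(epoch_window=(-0.2, 1.0),
                             interest_window=(0.5, 1.0))
        with pytest.raises(ValueError, match="outside"):
            extract_interest_window(short, late)
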