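"""ERP statistics: grand averages, SNR, bootstrap CIs, overlap rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from errpnav.erpstats import (BootstrapSummary, bootstrap_mean,
                              ci_overlap_verdict, grand_average, snr)
from tests.conftest import make_epochs


def constant_epochs(err_value, true_value, n_each=5, n_ch=2, n_t=100):
    data = np.concatenate([np.full((n_each, n_ch, n_t), err_value),
                           np.full((n_each, n_ch, n_t), true_value)])
    labels = ["error"] * n_each + ["true"] * n_each
    return make_epochs(data, labels, tz=0)


class TestGrandAverage:
    def test_constant_conditions_give_constant_difference(self):
        epochs = constant_epochs(+1.0, -1.0)
        ga = grand_average(epochs, ["ch0", "ch1"])
        np.testing.assert_allclose(ga["difference"].mean_trace, 2.0)
        np.testing.assert_allclose(
            ga["difference"].mean_trace,
            ga["error"].mean_trace - ga["true"].mean_trace)

    def test_single_trial_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, 1, 50))
        epochs = make_epochs(data, ["error", "true"])
        ga = grand_average(epochs, ["ch0"])
        np.testing.assert_allclose(ga["error"].mean_trace, data[0, 0])

    def test_missing_channel_named_in_error(self):
        epochs = constant_epochs(1, 0)
        with pytest.raises(KeyError, match="Pz"):
            grand_average(epochs, ["Pz"])

    def test_synthetic_difference_wave_morphology(self, default_epochs):
        """Error-minus-true wave: negative extremum in 100-300 ms, positive
        extremum in 300-600 ms over frontocentral channels (sign and
        latency only; magnitudes are generator free parameters)."""
        ga = grand_average(default_epochs, ["Fz", "Cz"])
        d = ga["difference"].mean_trace
        t = default_epochs.times
        i_neg, i_pos = np.argmin(d), np.argmax(d)
        assert d[i_neg] < 0 and 0.1 <= t[i_neg] < 0.3
        assert d[i_pos] > 0 and 0.3 <= t[i_pos] < 0.6


class TestSNR:
    def test_zero_difference_gives_zero(self):
        epochs = constant_epochs(0.5, 0.5)
        assert snr(epochs, ["ch0"], (0.0, 0.2)) == 0.0

    def test_constant_nonzero_difference_raises(self):
        epochs = constant_epochs(1.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            snr(epochs, ["ch0"], (0.0, 0.2))

    def test_half_sine_closed_form(self):
        """SNR of a half-sine difference equals |mean|/std computed by
        direct arithmetic on the sampled trace."""
        rate, n_t = 250.0, 150
        t = np.arange(n_t) / rate
        half_sine = np.sin(np.pi * t / t[-1])
        data = np.stack([np.tile(half_sine, (1, 1)),
                         np.zeros((1, n_t))])
        epochs = make_epochs(data, ["error", "true"], rate=rate, tz=0)
        interval = (0.0, n_t / rate)
        seg = half_sine  # whole trace inside the interval
        expected = abs(seg.mean()) / seg.std(ddof=0)
        assert snr(epochs, ["ch0"], interval) == pytest.approx(expected)

    def test_scale_invariance(self, default_epochs):
        base = snr(default_epochs, ["Fz", "Cz"], (0.1, 0.3))
        scaled = make_epochs(default_epochs.data * 7.3,
                             list(default_epochs.labels),
                             rate=default_epochs.rate,
                             names=default_epochs.channel_names,
                             tz=default_epochs.time_zero_index)
        assert snr(scaled, ["Fz", "Cz"], (0.1, 0.3)) == pytest.approx(base)

    def test_tiny_interval_rejected(self, default_epochs):
        with pytest.raises(ValueError, match="3 samples"):
            snr(default_epochs, ["Fz"], (0.1, 0.105))


class TestBootstrapMean:
    def test_degenerate_distribution(self):
        s = bootstrap_mean([3.0] * 10, n_boot=200, seed=0)
        assert s.mean == pytest.approx(3.0)
        assert s.ci_low == pytest.approx(3.0)
        assert s.ci_high == pytest.approx(3.0)

    def test_binomial_oracle(self):
        """Bootstrap of a {0,1} sample: mean ~ 0.5, CI close to the binomial
        normal approximation +-1.96*sqrt(p(1-p)/n)."""
        values = [0.0] * 50 + [1.0] * 50
        s = bootstrap_mean(values, n_boot=5000, seed=1)
        se = np.sqrt(0.25 / 100)
        assert s.mean == pytest.approx(0.5, abs=0.01)
        assert s.ci_low == pytest.approx(0.5 - 1.96 * se, abs=0.02)
        assert s.ci_high == pytest.approx(0.5 + 1.96 * se, abs=0.02)
        assert s.ci_low < 0.5 < s.ci_high

    def test_bonferroni_quantile_levels(self):
        """m=2 at alpha=0.05 -> 1.25% / 98.75% quantiles (wider CI)."""
        rng = np.random.default_rng(2)
        values = rng.standard_normal(200)
        plain = bootstrap_mean(values, n_boot=4000, seed=3)
        corrected = bootstrap_mean(values, n_boot=4000, seed=3, bonferroni_m=2)
        assert corrected.ci_low < plain.ci_low
        assert corrected.ci_high > plain.ci_high

    def test_deterministic_under_seed(self):
        values = list(np.random.default_rng(4).standard_normal(30))
        a = bootstrap_mean(values, n_boot=500, seed=9)
        b = bootstrap_mean(values, n_boot=500, seed=9)
        assert (a.mean, a.ci_low, a.ci_high) == (b.mean, b.ci_low, b.ci_high)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_ci_brackets_mean_property(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.standard_normal(rng.integers(2, 40))
        s = bootstrap_mean(values, n_boot=200, seed=seed)
        assert s.ci_low <= s.mean <= s.ci_high

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (20, 200, 2000):
            values = rng.standard_normal(n)
            s = bootstrap_mean(values, n_boot=2000, seed=6)
            widths.append(s.ci_high - s.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean([], n_boot=10)


class TestCIOverlapVerdict:
    def _s(self, lo, mean, hi):
        return BootstrapSummary(mean=mean, ci_low=lo, ci_high=hi, n_boot=100)

    @pytest.mark.parametrize("a,b,verdict", [
        ((0, 0.5, 1), (2, 2.5, 3), "p<0.01"),
        ((0, 1, 2), (1.5, 2.5, 3.5), "p<0.05"),
        ((0, 1, 2), (0.5, 1.5, 2.5), "n.s."),
    ])
    def test_rule(self, a, b, verdict):
        assert ci_overlap_verdict(self._s(*a), self._s(*b)) == verdict
        assert ci_overlap_verdict(self._s(*b), self._s(*a)) == verdict
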