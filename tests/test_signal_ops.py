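"""Signal-processing primitives against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fallkin.signal_ops import (
    FilterSpec,
    FlatSignalError,
    Series,
    central_difference,
    energy_fraction_above,
    lowpass_dualpass,
    resample_to,
    sync_lag,
)


def _sinusoid(freq, rate, duration, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return Series(np.sin(2 * np.pi * freq * t + phase), rate)


class TestLowpassDualpass:
    def test_dc_gain_is_one(self):
        s = Series(np.full(200, 3.7), 600.0)
        out = lowpass_dualpass(s, FilterSpec(20.0))
        np.testing.assert_allclose(out.values, 3.7, rtol=1e-9)

    @pytest.mark.parametrize(
        "freq_ratio,expected,atol",
        [
            # dual-pass 4th-order Butterworth: |H|^2 = 1/(1 + (f/fc)^8)
            (1.0, 0.5, 0.02),
            (0.25, 1.0, 0.01),
            (2.0, 1.0 / (1 + 2.0**8), 0.02),
        ],
    )
    def test_magnitude_response_matches_analytic(self, freq_ratio, expected, atol):
        fc = 10.0
        s = _sinusoid(fc * freq_ratio, 600.0, 10.0)
        out = lowpass_dualpass(s, FilterSpec(fc))
        # drop 1 s of transient at each end before measuring amplitude
        core = out.values[600:-600]
        amplitude = (core.max() - core.min()) / 2
        assert amplitude == pytest.approx(expected, abs=atol)

    def test_zero_phase(self):
        # aperiodic band-limited signal: no period ambiguity in the
        # cross-correlation, so the peak must sit exactly at zero lag
        t = np.arange(int(4 * 600)) / 600.0
        x = np.exp(-((t - 2.0) ** 2) / 0.3) * (
            np.sin(2 * np.pi * 2.1 * t) + 0.5 * np.sin(2 * np.pi * 3.7 * t)
        )
        s = Series(x, 600.0)
        out = lowpass_dualpass(s, FilterSpec(10.0))
        assert sync_lag(s, out, max_lag=0.5) == 0.0

    def test_cutoff_at_nyquist_rejected(self):
        s = _sinusoid(2.0, 30.0, 4.0)
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_dualpass(s, FilterSpec(15.0))

    def test_short_series_rejected(self):
        s = Series(np.zeros(10), 30.0)
        with pytest.raises(ValueError, match="too short"):
            lowpass_dualpass(s, FilterSpec(5.0))

    def test_sequential_cutoffs_equivalent_to_smaller(self):
        rng = np.random.default_rng(0)
        t = np.arange(1200) / 600.0
        x = np.sin(2 * np.pi * 2 * t) + 0.3 * np.sin(2 * np.pi * 8 * t)
        s = Series(x, 600.0)
        once = lowpass_dualpass(s, FilterSpec(5.0))
        twice = lowpass_dualpass(lowpass_dualpass(s, FilterSpec(18.0)), FilterSpec(5.0))
        diff = np.sqrt(np.mean((once.values - twice.values) ** 2))
        assert diff < 0.02  # < 2% of unit amplitude


class TestResample:
    def test_ramp_stays_linear(self):
        s = Series(np.linspace(0.0, 2.0, 31), 30.0)
        up = resample_to(s, 600.0)
        expected = np.linspace(0.0, 2.0, 601)
        np.testing.assert_allclose(up.values, expected, atol=1e-9)

    def test_same_rate_is_identity(self):
        s = Series(np.arange(10.0), 30.0)
        assert resample_to(s, 30.0) is s

    def test_sinusoid_matches_analytic_within_1pct_rms(self):
        rate, dur = 30.0, 3.0
        t = np.arange(int(dur * rate)) / rate
        s = Series(np.sin(2 * np.pi * 5.0 * t), rate)
        up = resample_to(s, 600.0)
        analytic = np.sin(2 * np.pi * 5.0 * up.times)
        # ignore the extrapolation-prone final original interval
        n = len(up) - 20
        rms = np.sqrt(np.mean((up.values[:n] - analytic[:n]) ** 2))
        assert rms < 0.01

    def test_original_instants_reproduced_for_integer_multiple(self):
        rng = np.random.default_rng(1)
        s = Series(rng.normal(size=40), 30.0)
        up = resample_to(s, 600.0)
        np.testing.assert_allclose(up.values[::20], s.values, atol=1e-9)

    def test_duration_preserved(self):
        s = Series(np.zeros(31), 30.0)
        up = resample_to(s, 600.0)
        assert up.duration == pytest.approx(s.duration)


class TestSyncLag:
    def test_identical_signals_zero_lag(self):
        s = _sinusoid(2.0, 600.0, 2.0)
        assert sync_lag(s, s) == 0.0

    def test_constructed_delay_recovered(self):
        rate = 600.0
        t = np.arange(1800) / rate
        x = np.exp(-((t - 1.0) ** 2) / 0.05)
        delay = int(0.25 * rate)
        y = np.roll(x, delay)  # circular shift keeps full signal content
        lag = sync_lag(Series(x, rate), Series(y, rate), max_lag=1.0)
        assert lag == pytest.approx(0.25, abs=1.0 / rate)

    def test_noisy_shift_within_one_sample_of_bruteforce(self, rng):
        rate = 600.0
        t = np.arange(1200) / rate
        x = np.sin(2 * np.pi * 3 * t) * np.exp(-((t - 1.0) ** 2))
        delay = 57
        y = np.concatenate([np.zeros(delay), x[:-delay]])
        y = y + rng.normal(0, np.std(x) / np.sqrt(10), size=y.size)  # SNR 10
        lag = sync_lag(Series(x, rate), Series(y, rate), max_lag=0.5)

        # brute-force oracle over integer lags
        a = x - x.mean()
        b = y - y.mean()
        best, best_k = -np.inf, 0
        for k in range(-300, 301):
            bb = np.roll(b, -k)
            c = np.dot(a, bb)
            if c > best:
                best, best_k = c, k
        assert abs(lag * rate - best_k) <= 1

    def test_flat_signal_rejected(self):
        s = Series(np.ones(100), 600.0)
        with pytest.raises(FlatSignalError):
            sync_lag(s, s)

    def test_rate_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample rate"):
            sync_lag(Series(np.arange(10.0), 30.0), Series(np.arange(10.0), 600.0))


class TestCentralDifference:
    def test_affine_signal_exact(self):
        t = np.arange(100) / 600.0
        v = central_difference(Series(3.0 * t + 1.0, 600.0))
        np.testing.assert_allclose(v.values, 3.0, rtol=1e-9)

    def test_constant_gives_zero(self):
        v = central_difference(Series(np.full(50, 2.2), 600.0))
        np.testing.assert_allclose(v.values, 0.0, atol=1e-12)

    def test_sinusoid_derivative_within_01pct(self):
        rate = 600.0
        t = np.arange(int(2 * rate)) / rate
        v = central_difference(Series(np.sin(2 * np.pi * 2 * t), rate))
        analytic = 4 * np.pi * np.cos(2 * np.pi * 2 * t)
        err = np.abs(v.values[1:-1] - analytic[1:-1]).max()
        assert err < 1e-3 * np.abs(analytic).max()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            central_difference(Series(np.array([1.0, 2.0]), 30.0))


class TestEnergyFraction:
    def test_pure_tone_below_threshold(self):
        frac = energy_fraction_above(_sinusoid(5.0, 600.0, 2.0), 20.0)
        assert frac == pytest.approx(0.0, abs=1e-12)

    def test_pure_tone_above_threshold(self):
        frac = energy_fraction_above(_sinusoid(25.0, 600.0, 2.0), 20.0)
        assert frac == pytest.approx(1.0, abs=1e-9)

    def test_equal_energy_mixture_splits_evenly(self):
        rate, dur = 600.0, 2.0
        t = np.arange(int(dur * rate)) / rate
        s = Series(np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 25 * t), rate)
        assert energy_fraction_above(s, 20.0) == pytest.approx(0.5, abs=0.01)

    def test_above_nyquist_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert energy_fraction_above(_sinusoid(5.0, 30.0, 2.0), 15.0) == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.floats(2.0, 250.0))
    def test_complementary_bands_sum_to_one(self, seed, f):
        rng = np.random.default_rng(seed)
        s = Series(rng.normal(size=256), 600.0)
        above = energy_fraction_above(s, f)
        # "below or equal" band = complement of the strict-above band
        spec = np.abs(np.fft.rfft(s.values)[1:]) ** 2
        freqs = np.fft.rfftfreq(256, 1 / 600.0)[1:]
        below = spec[freqs <= f].sum() / spec.sum()
        assert above + below == pytest.approx(1.0, abs=1e-9)
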