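import numpy as np
import pytest
from scipy import stats as sp_stats

from ipidyn.predictor import ErrorRecord
from ipidyn.signal_io import SignalTrace
from ipidyn.stats import (LOG_EPSILON, alpha_band_power, band_power_fraction,
                          compare_states, log_transform, power_spectrum,
                          sample_skewness, summarize_errors)


def skewness_by_hand(x):
    """Brute-force moment computation m3 / m2^1.5."""
    x = np.asarray(x, dtype=float)
    m = sum(x) / len(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    m3 = sum((v - m) ** 3 for v in x) / len(x)
    return m3 / m2**1.5


class TestSummaries:
    def test_symmetric_errors_have_zero_skewness(self):
        s = summarize_errors(ErrorRecord(np.array([-1.0, 1.0, -2.0, 2.0])))
        assert s.skewness_signed == pytest.approx(0.0, abs=1e-12)

    def test_mean_abs(self):
        s = summarize_errors(ErrorRecord(np.array([0.0, 0.0, 3.0])))
        assert s.mean_abs == pytest.approx(1.0)

    def test_skewness_matches_brute_force(self, rng):
        for _ in range(5):
            x = rng.normal(size=rng.integers(10, 200)) ** 3
            assert sample_skewness(x) == pytest.approx(skewness_by_hand(x),
                                                       abs=1e-12)

    def test_exponential_sample_skewness_is_two(self, rng):
        x = rng.exponential(1.0, size=400_000)
        assert sample_skewness(x) == pytest.approx(2.0, abs=0.05)

    def test_histogram_covers_all_errors_with_integer_bins(self, rng):
        e = rng.normal(0, 3, 500)
        s = summarize_errors(ErrorRecord(e))
        assert s.hist_counts.sum() == e.size
        assert np.allclose(np.diff(s.hist_edges), 1.0)


class TestLogTransform:
    def test_log_of_one_is_zero(self):
        assert log_transform(np.array([1.0]))[0] == pytest.approx(0.0, abs=1e-8)

    def test_zero_is_guarded(self):
        assert log_transform(np.array([0.0]))[0] == pytest.approx(
            np.log(LOG_EPSILON))

    def test_monotone(self, rng):
        a = np.sort(rng.exponential(1.0, 50))
        out = log_transform(a)
        assert np.all(np.diff(out) >= 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([-0.1]))


class TestCompareStates:
    def test_identical_groups_give_zero_effect(self, rng):
        a = rng.normal(size=40)
        eff = compare_states(a, a.copy())
        assert eff.d == 0.0
        assert eff.p_value == pytest.approx(1.0)

    def test_unit_effect_when_difference_equals_common_sd(self):
        base = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0]) * np.sqrt(6 / 5)
        # groups share SD s; means differ by exactly s
        s = base.std(ddof=1)
        eff = compare_states(base + s, base)
        assert eff.d == pytest.approx(1.0)

    def test_matches_hand_computed_welch_and_pooled_d(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 6.0])
        # hand computation from the defining formulas
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va / 4 + vb / 4)
        df_hand = (va / 4 + vb / 4) ** 2 / (
            (va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        p_hand = 2 * sp_stats.t.sf(abs(t_hand), df_hand)
        pooled = np.sqrt((3 * va + 3 * vb) / 6)
        d_hand = (a.mean() - b.mean()) / pooled
        eff = compare_states(a, b)
        assert eff.t_stat == pytest.approx(t_hand, abs=1e-10)
        assert eff.df == pytest.approx(df_hand, abs=1e-10)
        assert eff.p_value == pytest.approx(p_hand, abs=1e-10)
        assert eff.d == pytest.approx(d_hand, abs=1e-10)
        # frozen values from the same formulas, computed once by hand
        assert eff.t_stat == pytest.approx(-2.1908902300206643, abs=1e-10)
        assert eff.d == pytest.approx(-1.5491933384829668, abs=1e-10)
        assert eff.df == pytest.approx(6.0, abs=1e-10)

    def test_antisymmetric_under_group_swap(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.3, 40)
        ab, ba = compare_states(a, b), compare_states(b, a)
        assert ab.d == pytest.approx(-ba.d, abs=1e-12)
        assert ab.t_stat == pytest.approx(-ba.t_stat, abs=1e-12)

    def test_degenerate_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_states(np.array([1.0, 1.0]), np.array([2.0, 2.0]))


class TestSpectrum:
    def test_pure_tone_peaks_at_its_frequency(self):
        fs, f = 100.0, 2.0
        t = np.arange(10_000) / fs
        spec = power_spectrum(SignalTrace(np.sin(2 * np.pi * f * t), fs=fs))
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(f, abs=0.05)

    def test_two_tones_give_two_local_maxima(self):
        fs = 100.0
        t = np.arange(20_000) / fs
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 2.0 * t)
        spec = power_spectrum(SignalTrace(x, fs=fs))
        # the two largest spectral values sit at the bins nearest 1 and 2 Hz
        top2 = spec.freqs[np.argsort(spec.power)[-2:]]
        assert sorted(np.round(top2, 1).tolist()) == [1.0, 2.0]

    def test_white_noise_spectrum_is_flat(self):
        for seed in range(3):
            gen = np.random.default_rng(seed)
            spec = power_spectrum(SignalTrace(gen.normal(size=50_000)))
            assert spec.power.max() < 10 * np.median(spec.power)

    def test_parseval_total_power_tracks_variance(self, rng):
        x = rng.normal(size=20_000)
        trace = SignalTrace(x)
        spec = power_spectrum(trace)
        df = spec.freqs[1] - spec.freqs[0]
        total = np.sum(spec.power) * df
        assert 0.5 < total / x.var() < 2.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(SignalTrace(np.arange(10.0)))


class TestBandPower:
    def test_alpha_tone_has_unit_alpha_fraction(self):
        t = np.arange(20_000) / 100.0
        spec = power_spectrum(SignalTrace(np.sin(2 * np.pi * 10.0 * t), fs=100.0))
        assert alpha_band_power(spec) > 0.99

    def test_slow_tone_has_negligible_alpha_fraction(self):
        t = np.arange(20_000) / 100.0
        spec = power_spectrum(SignalTrace(np.sin(2 * np.pi * 2.0 * t), fs=100.0))
        assert alpha_band_power(spec) < 0.01

    def test_exhaustive_bands_partition_total_power(self, rng):
        spec = power_spectrum(SignalTrace(rng.normal(size=10_000), fs=100.0))
        edges = [0.0, 3.0, 7.5, 12.5, 30.0, 50.0]
        fractions = [band_power_fraction(spec, lo, hi)
                     for lo, hi in zip(edges, edges[1:])]
        assert sum(fractions) == pytest.approx(1.0, abs=1e-9)

    def test_band_beyond_nyquist_rejected(self, rng):
        spec = power_spectrum(SignalTrace(rng.normal(size=1000), fs=100.0))
        with pytest.raises(ValueError, match="Nyquist"):
            band_power_fraction(spec, 40.0, 60.0)
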