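import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as o
from gaitdemog import (BANDS, PeakSet, band_features, detect_peaks, extract_all,
                       fft_spectrum, jerk, peak_features, spearman,
                       spectral_features, time_domain_features, welch_psd)
from gaitdemog.errors import DataError
from gaitdemog.features import Spectrum, feature_unit

RATE = 100.0


class TestDetectPeaks:
    def test_sinusoid_peak_count_and_spacing(self):
        t = np.arange(300) / RATE
        peaks = detect_peaks(np.sin(2 * np.pi * 2.0 * t), RATE, "positive")
        assert len(peaks) == 6
        np.testing.assert_allclose(np.diff(peaks.times), 0.5, atol=0.011)

    def test_constant_channel_yields_no_peaks(self):
        assert len(detect_peaks(np.ones(300), RATE, "positive")) == 0

    def test_negative_polarity_finds_minima(self):
        t = np.arange(300) / RATE
        peaks = detect_peaks(np.sin(2 * np.pi * 2.0 * t), RATE, "negative")
        assert len(peaks) == 6
        assert (peaks.values < 0).all()


class TestPeakFeatures:
    def test_uniform_train_interval_mean_and_zero_std(self):
        peaks = PeakSet(np.array([0.0, 0.45, 0.90, 1.35]),
                        np.ones(4), "positive")
        fv = peak_features(peaks, 3.0, "p-")
        assert fv["p-interval-mean"] == pytest.approx(450.0)
        assert fv["p-interval-std"] == pytest.approx(0.0, abs=1e-9)

    def test_population_std_of_unequal_intervals(self):
        peaks = PeakSet(np.array([0.0, 0.4, 1.0]), np.ones(3), "positive")
        fv = peak_features(peaks, 3.0, "p-")
        assert fv["p-interval-mean"] == pytest.approx(500.0)
        assert fv["p-interval-std"] == pytest.approx(100.0)

    def test_single_peak_yields_missing_interval_stats(self):
        peaks = PeakSet(np.array([1.0]), np.array([2.0]), "positive")
        fv = peak_features(peaks, 3.0, "p-")
        assert np.isnan(fv["p-interval-mean"])
        assert np.isnan(fv["p-interval-std"])

    def test_phase_invariance_of_periodic_interval_mean(self):
        for phase in (0.0, 0.13, 0.31):
            times = phase + 0.45 * np.arange(5)
            fv = peak_features(PeakSet(times, np.ones(5), "positive"), 3.0, "p-")
            assert fv["p-interval-mean"] == pytest.approx(450.0)


class TestTimeDomain:
    def test_worked_mad_example(self):
        fv = time_domain_features([1, 2, 3, 4], RATE, "x-")
        assert fv["x-mean"] == pytest.approx(2.5)
        assert fv["x-mad"] == pytest.approx(1.0)

    def test_worked_iqr_example(self):
        fv = time_domain_features([1, 2, 3, 4, 5], RATE, "x-")
        assert fv["x-iqr"] == pytest.approx(2.0)

    def test_constant_channel_degenerates(self):
        fv = time_domain_features(np.full(50, 3.0), RATE, "x-")
        assert fv["x-std"] == 0.0
        assert fv["x-iqr"] == 0.0
        assert fv["x-mad"] == 0.0
        assert np.isnan(fv["x-skewness"]) and np.isnan(fv["x-kurtosis"])

    def test_matches_from_definition_oracle(self, rng):
        for _ in range(50):
            xs = rng.normal(size=rng.integers(10, 80)).tolist()
            fv = time_domain_features(xs, RATE, "x-")
            assert fv["x-mean"] == pytest.approx(o.o_mean(xs), abs=1e-10)
            assert fv["x-std"] == pytest.approx(o.o_std(xs), abs=1e-10)
            assert fv["x-mad"] == pytest.approx(o.o_mad(xs), abs=1e-10)
            assert fv["x-iqr"] == pytest.approx(o.o_iqr(xs), abs=1e-10)
            assert fv["x-skewness"] == pytest.approx(o.o_skewness(xs), abs=1e-10)
            assert fv["x-kurtosis"] == pytest.approx(o.o_kurtosis(xs), abs=1e-10)
            assert fv["x-energy-per-second"] == pytest.approx(
                o.o_energy_per_second(xs, RATE), rel=1e-10)


class TestJerk:
    def test_linear_ramp(self):
        t = np.arange(200) / RATE
        np.testing.assert_allclose(jerk(2.0 * t, RATE), 2.0, atol=1e-9)

    def test_constant_channel(self):
        np.testing.assert_array_equal(jerk(np.full(100, 5.0), RATE), np.zeros(99))

    def test_sinusoid_derivative_amplitude(self):
        t = np.arange(300) / RATE
        j = jerk(np.sin(2 * np.pi * 1.0 * t), RATE)
        assert np.max(np.abs(j)) == pytest.approx(2 * np.pi, rel=0.02)


class TestSpectra:
    def test_tone_peak_location(self):
        t = np.arange(300) / RATE
        x = np.sin(2 * np.pi * 10.0 * t)
        for spec in (fft_spectrum(x, RATE), welch_psd(x, RATE)):
            assert spec.freqs[np.argmax(spec.power)] == pytest.approx(
                10.0, abs=spec.resolution)

    def test_zero_signal_zero_power(self):
        assert fft_spectrum(np.zeros(300), RATE).power.sum() == 0.0
        assert welch_psd(np.zeros(300), RATE).power.sum() == 0.0

    def test_fft_parseval(self, rng):
        x = rng.normal(size=300)
        spec = fft_spectrum(x, RATE)
        assert spec.power.sum() == pytest.approx(np.sum(x**2), rel=1e-6)

    def test_welch_too_short_names_minimum(self):
        with pytest.raises(DataError, match="128"):
            welch_psd(np.zeros(64), RATE)


class TestSpectralFeatures:
    def _make(self, freqs, power):
        return Spectrum(np.asarray(freqs, float), np.asarray(power, float),
                        "welch-psd")

    def test_single_bin_degenerate_distribution(self):
        freqs = np.arange(0, 21, 1.0)
        power = np.zeros(21)
        power[10] = 5.0
        fv = spectral_features(self._make(freqs, power), "x-")
        assert fv["x-mean-freq-psd"] == pytest.approx(10.0)
        assert fv["x-spectral-entropy-psd"] == pytest.approx(0.0, abs=1e-12)
        assert fv["x-bandwidth-psd-lower-bound"] == 10.0
        assert fv["x-bandwidth-psd-upper-bound"] == 10.0

    def test_uniform_power_maximum_entropy(self):
        freqs = np.arange(0, 16, 1.0)
        fv = spectral_features(self._make(freqs, np.ones(16)), "x-")
        assert fv["x-spectral-entropy-psd"] == pytest.approx(1.0)

    def test_two_equal_bins(self):
        freqs = np.arange(0, 11, 1.0)
        power = np.zeros(11)
        power[2] = power[8] = 1.0
        fv = spectral_features(self._make(freqs, power), "x-")
        assert fv["x-mean-freq-psd"] == pytest.approx(5.0)
        assert fv["x-bandwidth-psd-lower-bound"] == 2.0
        assert fv["x-bandwidth-psd-upper-bound"] == 8.0

    def test_zero_power_all_missing(self):
        fv = spectral_features(self._make(np.arange(5.0), np.zeros(5)), "x-")
        assert all(np.isnan(v) for v in fv.values())

    def test_moments_match_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=300)
            spec = fft_spectrum(x, RATE)
            mean, skew, kurt, ent = o.o_spectral_moments(
                spec.freqs.tolist(), spec.power.tolist())
            fv = spectral_features(spec, "x-")
            assert fv["x-mean-freq"] == pytest.approx(mean, abs=1e-10)
            assert fv["x-skewness-freq"] == pytest.approx(skew, abs=1e-10)
            assert fv["x-kurtosis-freq"] == pytest.approx(kurt, abs=1e-10)
            assert fv["x-spectral-entropy-freq"] == pytest.approx(ent, abs=1e-10)


class TestBandFeatures:
    def test_pure_tones_land_in_their_bands(self):
        t = np.arange(300) / RATE
        for f0, band in ((1.0, "delta"), (10.0, "beta")):
            spec = welch_psd(np.sin(2 * np.pi * f0 * t), RATE)
            fv = band_features(spec, BANDS, "x-")
            assert fv[f"x-percentage-power-{band}-band-psd"] >= 95.0

    def test_band_percentages_sum_below_total(self, rng):
        spec = welch_psd(rng.normal(size=300), RATE)
        fv = band_features(spec, BANDS, "x-")
        total = sum(fv[f"x-percentage-power-{b}-band-psd"] for b in BANDS)
        assert total <= 100.0 + 1e-9

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(0.1, 50.0), st.integers(0, 2**32 - 1))
    def test_percentage_features_scale_invariant(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=300)
        fv1 = band_features(welch_psd(x, RATE), BANDS, "x-")
        fv2 = band_features(welch_psd(scale * x, RATE), BANDS, "x-")
        for b in BANDS:
            key = f"x-percentage-power-{b}-band-psd"
            assert fv2[key] == pytest.approx(fv1[key], rel=1e-9, abs=1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_worked_example(self):
        assert spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_constant_input_is_missing(self):
        assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))

    def test_matches_scipy_with_ties(self, rng):
        import scipy.stats
        for _ in range(30):
            x = rng.integers(0, 8, size=40).astype(float)
            y = x + rng.normal(0, 2, size=40)
            expected = scipy.stats.spearmanr(x, y).statistic
            assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3.0 * y + 7.0) == pytest.approx(base, abs=1e-12)


# Published selected-feature sets; extract_all must emit every one of them.
TABLE1_SEX = [
    "accl-net-positive-peak-interval-mean", "accl-net-positive-peak-interval-std",
    "accl-x-skewness", "accl-y-kurtosis", "accl-y-res-std",
    "accl-y-positive-peak-interval-mean", "accl-y-peak-interval-std",
    "accl-z-negative-peak-val-mean", "accl-z-negative-peak-interval-std",
    "gyro-x-positive-peak-val-mean", "gyro-y-positive-peak-interval-mean",
    "gyro-y-negative-peak-val-mean", "gyro-z-positive-peak-val-mean",
    "gyro-z-negative-peak-interval-std", "accl-net-skew-freq-psd",
    "accl-x-percentage-power-alpha-band-psd", "accl-x-skewness-freq",
    "accl-y-percentage-power-beta-band-psd",
    "accl-z-percentage-power-delta-band-psd",
    "accl-z-percentage-power-beta-band-psd", "gyro-y-bandwidth-psd-lower-bound",
    "gyro-z-percentage-power-alpha-band-psd", "accl-x-accl-y-spearman",
    "accl-x-accl-z-spearman", "accl-x-gyro-z-spearman", "accl-y-accl-z-spearman",
    "accl-y-gyro-z-spearman", "accl-net-gyro-x-spearman",
    "gyro-x-gyro-y-spearman", "gyro-x-gyro-z-spearman",
]
TABLE1_AGE = [
    "accl-net-positive-peak-interval-mean", "accl-x-mean", "accl-y-mad",
    "accl-z-mad", "gyro-x-iqr", "gyro-y-negative-peak-val-mean",
    "gyro-z-kurtosis", "accl-net-percentage-power-delta-band-psd",
    "accl-x-percentage-power-alpha-band-psd",
    "accl-x-percentage-power-beta-band-psd", "accl-x-skewness-freq",
    "accl-y-percentage-power-alpha-band-psd", "accl-z-kurt-freq-psd",
    "accl-z-percentage-power-theta-band-psd",
    "gyro-y-percentage-power-theta-band-psd",
    "gyro-y-percentage-power-gamma-band-psd",
    "gyro-z-percentage-power-theta-band-psd", "gyro-z-jerk-iqr",
    "gyro-z-jerk-skewness", "accl-x-accl-y-spearman", "accl-x-accl-z-spearman",
    "accl-x-gyro-x-spearman", "accl-x-gyro-y-spearman", "accl-x-gyro-z-spearman",
    "accl-y-gyro-x-spearman", "accl-y-gyro-z-spearman",
    "accl-z-accl-net-spearman", "accl-z-gyro-x-spearman",
    "gyro-x-gyro-y-spearman", "gyro-y-gyro-z-spearman",
]


class TestExtractAll:
    def test_published_feature_names_present(self, clean_window):
        fv = extract_all(clean_window)
        missing = [n for n in set(TABLE1_SEX + TABLE1_AGE) if n not in fv]
        assert not missing, f"missing features: {missing}"

    def test_deterministic(self, clean_window):
        fv1 = extract_all(clean_window)
        fv2 = extract_all(clean_window)
        assert list(fv1) == list(fv2)
        for k in fv1:
            assert fv1[k] == fv2[k] or (np.isnan(fv1[k]) and np.isnan(fv2[k]))

    def test_names_unique_and_finite_or_nan(self, clean_window):
        fv = extract_all(clean_window)
        assert len(fv) == len(set(fv))
        assert all(np.isfinite(v) or np.isnan(v) for v in fv.values())

    def test_unit_registry(self, clean_window):
        fv = extract_all(clean_window)
        for name in fv:
            unit = feature_unit(name)
            if "interval" in name:
                assert unit == "ms", name
            elif name.endswith("-spearman"):
                assert unit == "dimensionless", name
            elif "percentage-power" in name:
                assert unit == "percent", name
            elif "bandwidth" in name or "peak-freq" in name or "mean-freq" in name:
                assert unit == "Hz", name
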