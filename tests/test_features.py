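import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tremorsim.features import (FEATURE_NAMES, WindowFeatureExtractor,
                                autocorr_first_peak, band_energy,
                                extract_features, extract_features_batch,
                                spectral_features, zscore_normalize)
from reference_features import reference_features

FS = 100.0


def _sine(f, fs=FS, dur=2.0, amp=1.0, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * f * t + phase)


class TestBandEnergy:
    def test_constant_window_rejects_dc(self):
        x = np.full(200, 3.0)
        total = np.sum((x - x.mean()) ** 2) + 1e-30
        assert band_energy(x, FS, "high") <= 1e-6 * max(total, 1.0)
        assert band_energy(np.zeros(200), FS, "low") == 0.0

    def test_pure_6hz_is_high_band(self):
        x = _sine(6.0)
        total = np.sum((x - x.mean()) ** 2)
        assert band_energy(x, FS, "high") >= 0.95 * total
        assert band_energy(x, FS, "low") <= 0.05 * total

    def test_pure_1hz_is_low_band(self):
        x = _sine(1.0)
        total = np.sum((x - x.mean()) ** 2)
        assert band_energy(x, FS, "low") >= 0.9 * total

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_energy(np.zeros(10), 4.0, "high")


class TestAutocorr:
    def test_5hz_sine_period_recovered(self):
        lag, height = autocorr_first_peak(_sine(5.0), FS)
        assert lag == pytest.approx(0.20, abs=1 / FS)
        assert height >= 0.9

    def test_white_noise_height_small(self, rng):
        heights = [autocorr_first_peak(rng.normal(size=500), FS)[1]
                   for _ in range(50)]
        assert np.mean(heights) <= 0.2
        assert np.quantile(heights, 0.95) <= 0.35

    def test_zero_variance_flagged_as_no_peak(self):
        lag, height = autocorr_first_peak(np.ones(200), FS)
        assert lag == pytest.approx(2.0)
        assert height == 0.0

    def test_lag_consistent_with_dominant_frequency(self):
        for f in (3.0, 5.0, 8.0):
            x = _sine(f) + 0.1 * _sine(2 * f)
            lag, _ = autocorr_first_peak(x, FS)
            dom, _, _ = spectral_features(x, FS)
            assert 1.0 / lag == pytest.approx(dom, abs=0.5)


class TestSpectral:
    def test_pure_tone_dominant_frequency(self):
        dom, _, _ = spectral_features(_sine(6.0), FS)
        assert dom == pytest.approx(6.0, abs=0.25)

    def test_two_low_tones_two_peaks(self):
        x = _sine(3.0, dur=4.0) + _sine(4.0, dur=4.0)
        dom, amp_sum, n_peaks = spectral_features(x, FS)
        assert n_peaks == 2
        assert amp_sum > 1.0  # both ~unit-amplitude tones lie below 5 Hz

    def test_zero_signal_all_zero(self):
        dom, amp_sum, n_peaks = spectral_features(np.zeros(400), FS)
        assert (dom, amp_sum, n_peaks) == (0.0, 0.0, 0)


class TestExtractFeatures:
    def test_constant_window(self):
        out = extract_features(np.full(200, 2.5), FS)
        assert out["ch0__mean"] == pytest.approx(2.5)
        assert out["ch0__abs_mean"] == pytest.approx(2.5)
        assert out["ch0__highpass_energy"] <= 1e-12
        assert out["ch0__n_peaks_below_5hz"] == 0

    def test_matches_naive_reference_on_random_windows(self, rng):
        n_windows = 1000
        windows = rng.normal(size=(n_windows, 200))
        # mix in some structured windows
        for i in range(0, n_windows, 4):
            f = rng.uniform(0.5, 20.0)
            windows[i] += 3 * _sine(f, phase=rng.uniform(0, 6.28))
        got = extract_features_batch(windows[:, None, :], FS)
        for i in range(n_windows):
            expect = reference_features(windows[i], FS)
            np.testing.assert_allclose(got[i], expect, rtol=1e-10, atol=1e-10)

    def test_batch_equals_per_window_path(self, rng):
        windows = rng.normal(size=(8, 3, 200))
        batch = extract_features_batch(windows, FS)
        for i in range(8):
            single = extract_features(windows[i], FS).to_numpy()
            np.testing.assert_allclose(batch[i], single, rtol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-5, 5), st.integers(0, 2 ** 31 - 1))
    def test_translation_changes_only_amplitude_features(self, c, seed):
        x = np.random.default_rng(seed).normal(size=(1, 1, 200))
        base = extract_features_batch(x, FS)[0]
        shifted = extract_features_batch(x + c, FS)[0]
        invariant = [FEATURE_NAMES.index(f) for f in
                     ("lowpass_energy", "highpass_energy", "autocorr_peak_lag",
                      "autocorr_peak_height", "dominant_freq",
                      "amp_sum_below_5hz", "n_peaks_below_5hz")]
        np.testing.assert_allclose(shifted[invariant], base[invariant],
                                   rtol=1e-8, atol=1e-9)

    def test_tremor_windows_have_more_highband_energy(self, rng):
        quiet = rng.normal(0, 1.3e-3, size=(100, 200))
        tremor = quiet + np.array([_sine(rng.uniform(4, 7), amp=rng.uniform(0.05, 0.3))
                                   for _ in range(100)])
        eq = band_energy(quiet, FS, "high")
        et = band_energy(tremor, FS, "high")
        assert np.mean(et > eq) >= 0.95

    def test_nonfinite_rejected(self):
        bad = np.zeros((1, 1, 200))
        bad[0, 0, 5] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            extract_features_batch(bad, FS)


class TestZScore:
    def test_two_point_population_convention(self):
        train = np.array([[1.0], [3.0]])
        tz, _, mu, sigma = zscore_normalize(train)
        assert mu[0] == pytest.approx(2.0)
        assert sigma[0] == pytest.approx(1.0)  # population sd of {1, 3}
        np.testing.assert_allclose(tz[:, 0], [-1.0, 1.0])

    def test_train_columns_standardized(self, rng):
        train = rng.normal(5, 3, size=(500, 4))
        tz, _, _, _ = zscore_normalize(train)
        np.testing.assert_allclose(tz.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(tz.std(axis=0), 1.0, atol=1e-9)

    def test_idempotent_on_standardized_data(self, rng):
        train = rng.normal(size=(200, 3))
        tz, _, _, _ = zscore_normalize(train)
        tz2, _, _, _ = zscore_normalize(tz)
        np.testing.assert_allclose(tz2, tz, atol=1e-9)

    def test_test_point_at_train_mean_maps_to_zero(self):
        train = np.array([[0.0, 10.0], [2.0, 14.0], [4.0, 18.0]])
        _, test_z, _, _ = zscore_normalize(train, train.mean(axis=0)[None, :])
        np.testing.assert_allclose(test_z, 0.0, atol=1e-12)

    def test_zero_variance_warns_and_zeroes(self):
        train = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            tz, _, _, _ = zscore_normalize(train)
        assert np.all(tz[:, 1] == 0.0)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize(np.empty((1, 3)))


def test_transformer_composes_with_sklearn_pipeline(rng):
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from tremorsim.classify import FineTreeClassifier

    quiet = rng.normal(0, 0.01, size=(40, 2, 200))
    shaky = quiet + _sine(6.0, amp=0.2)
    X = np.concatenate([quiet, shaky])
    y = np.repeat([1, 2], 40)
    pipe = Pipeline([
        ("features", WindowFeatureExtractor(fs=FS)),
        ("scale", StandardScaler()),
        ("tree", FineTreeClassifier(max_splits=5, random_state=0)),
    ])
    assert pipe.fit(X, y).score(X, y) == 1.0
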