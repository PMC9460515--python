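import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
import hypothesis.extra.numpy as hnp

from tremorsim.sensor_model import (InertialRecord, SensorSpec, quantize,
                                    synth_noise, resample, apply_sensor_model,
                                    get_preset, misalignment_from_angles)
from conftest import make_static_record


class TestQuantize:
    def test_zero_is_grid_point(self):
        assert quantize(0.0, 12, 4.0) == 0.0

    def test_lsb_16bit_16g(self):
        # +/-16 g full scale over 16 bit -> LSB = 32 / 65536 g
        lsb = 2 * 16.0 / 2 ** 16
        assert np.isclose(lsb, 4.8828e-4, rtol=1e-3)
        assert quantize(0.6 * lsb, 16, 16.0) == pytest.approx(lsb)
        assert quantize(0.4 * lsb, 16, 16.0) == 0.0

    def test_matches_bruteforce_code_search(self, rng):
        bits, fs = 4, 2.0
        lsb = 2 * fs / 2 ** bits
        codes = np.arange(-(2 ** (bits - 1)), 2 ** (bits - 1)) * lsb
        x = rng.uniform(-fs, fs, size=500)
        got = quantize(x, bits, fs)
        for xi, gi in zip(x, got):
            d = np.abs(codes - xi)
            best = d.min()
            # half-away-from-zero tie break: among nearest codes take the
            # one with the largest magnitude
            cand = codes[np.isclose(d, best)]
            expect = cand[np.argmax(np.abs(cand))]
            assert gi == pytest.approx(expect)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hnp.arrays(float, st.integers(1, 30),
                      elements=st.floats(-20, 20)))
    def test_idempotent_and_monotone(self, x):
        q1 = quantize(x, 6, 8.0)
        assert np.array_equal(quantize(q1, 6, 8.0), q1)
        order = np.argsort(x)
        assert np.all(np.diff(q1[order]) >= 0)

    def test_saturation(self):
        bits, fs = 8, 16.0
        lsb = 2 * fs / 2 ** bits
        assert quantize(100.0, bits, fs) == (2 ** 7 - 1) * lsb
        assert quantize(-100.0, bits, fs) == -(2 ** 7) * lsb

    def test_within_half_lsb_of_clipped_input(self, rng):
        bits, fs = 8, 2.0
        lsb = 2 * fs / 2 ** bits
        x = rng.uniform(-3, 3, 1000)
        q = quantize(x, bits, fs)
        clipped = np.clip(x, -(2 ** 7) * lsb, (2 ** 7 - 1) * lsb)
        assert np.all(np.abs(q - clipped) <= lsb / 2 + 1e-12)

    def test_nonfinite_input_named(self):
        x = np.array([0.0, np.nan, 1.0])
        with pytest.raises(ValueError, match="index 1"):
            quantize(x, 8, 1.0)


class TestSynthNoise:
    def test_zero_coeff_all_zero(self):
        assert np.array_equal(synth_noise("white", 0.0, 50, 100.0, 0),
                              np.zeros(50))

    def test_unknown_kind_lists_valid(self):
        with pytest.raises(ValueError, match="random_walk"):
            synth_noise("pink", 1.0, 10, 100.0, 0)

    def test_white_sigma_from_density(self):
        # MMR accelerometer density 180 ug/sqrt(Hz) at 100 Hz
        coeff, fs, n = 180e-6, 100.0, 100_000
        x = synth_noise("white", coeff, n, fs, 7)
        assert x.std() == pytest.approx(coeff * np.sqrt(fs / 2), rel=0.02)
        assert abs(x.mean()) < 5 * x.std() / np.sqrt(n)

    def test_random_walk_variance_grows_linearly(self):
        coeff, fs, n = 0.3, 100.0, 100_000
        x = synth_noise("random_walk", coeff, n, fs, 8)
        lags = np.array([10, 20, 50, 100, 200])
        # non-overlapping increments at lag k are i.i.d. N(0, k sigma^2)
        var = np.array([np.diff(x[::k]).var() for k in lags])
        w = 1.0 / lags.astype(float) ** 3  # inverse variance of var_k
        slope = np.sum(w * lags * var) / np.sum(w * lags ** 2)
        assert slope == pytest.approx(coeff ** 2 / fs, rel=0.05)

    def test_gauss_markov_stationary_sigma_and_tau(self):
        coeff, fs, n, tau = 2.0, 100.0, 100_000, 1.0
        x = synth_noise("bias_instability", coeff, n, fs, 9, tau=tau)
        assert x.std() == pytest.approx(coeff, rel=0.1)
        xm = x - x.mean()
        k = int(tau * fs)
        rho = np.dot(xm[:-k], xm[k:]) / np.dot(xm, xm)
        assert rho == pytest.approx(np.exp(-1), abs=0.1)

    def test_deterministic_under_seed(self):
        a = synth_noise("white", 1.0, 1000, 50.0, 42)
        b = synth_noise("white", 1.0, 1000, 50.0, 42)
        assert np.array_equal(a, b)


class TestResample:
    def test_identity_at_same_rate(self, static_record):
        out = resample(static_record, static_record.sample_rate)
        assert np.array_equal(out.accel, static_record.accel)

    def test_dc_preserved(self, static_record):
        out = resample(static_record, 100.0)
        assert out.sample_rate == 100.0
        assert np.allclose(out.accel[2], 1.0, rtol=1e-3)

    def test_sine_survives_decimation(self):
        fs, f0 = 1000.0, 3.0
        n = 10_000
        t = np.arange(n) / fs
        rec = make_static_record(fs, n / fs)
        rec.accel[0] = np.sin(2 * np.pi * f0 * t)
        out = resample(rec, 100.0)
        spec = np.abs(np.fft.rfft(out.accel[0] - out.accel[0].mean()))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 100.0)
        assert freqs[np.argmax(spec)] == pytest.approx(f0, abs=0.1)

    def test_upsampling_rejected(self, static_record):
        with pytest.raises(ValueError, match="[Uu]psampling"):
            resample(static_record, 2 * static_record.sample_rate)


class TestApplySensorModel:
    def test_null_model_up_to_quantization(self, static_record):
        spec = SensorSpec(name="null", sample_rate=1000.0, adc_bits=16,
                          accel_range=16.0, gyro_range=2000.0)
        out = apply_sensor_model(static_record, spec, 0)
        lsb = 2 * 16.0 / 2 ** 16
        assert np.all(np.abs(out.accel - static_record.accel) <= lsb / 2)
        assert np.all(np.abs(out.gyro - static_record.gyro)
                      <= (2 * 2000.0 / 2 ** 16) / 2)

    def test_constant_bias_additive(self, static_record):
        spec = SensorSpec(name="b", sample_rate=1000.0,
                          accel_bias=(0.0, 0.0, 0.1))
        out = apply_sensor_model(static_record, spec, 0)
        lsb = 2 * 16.0 / 2 ** 16
        assert abs(out.accel[2].mean() - 1.1) <= lsb

    def test_temperature_scale_and_bias(self, static_record):
        spec = SensorSpec(name="t", sample_rate=1000.0, temp_offset=10.0,
                          temp_scale_coeff=1e-3, accel_temp_bias_coeff=2e-3)
        out = apply_sensor_model(static_record, spec, 0)
        # z reads 1 g * (1 + 0.01) + 0.02 g thermal bias
        assert out.accel[2].mean() == pytest.approx(1.03, abs=1e-3)

    def test_misalignment_mixes_axes(self, static_record):
        mis = misalignment_from_angles(xz=0.01)
        spec = SensorSpec(name="m", sample_rate=1000.0, accel_misalignment=mis)
        out = apply_sensor_model(static_record, spec, 0)
        assert out.accel[0].mean() == pytest.approx(np.sin(0.01), abs=1e-3)

    def test_rate_conversion_mmr(self, static_record):
        out = apply_sensor_model(static_record, get_preset("mmr"), 1)
        assert out.sample_rate == 100.0
        assert abs(out.n_samples - static_record.n_samples / 10) <= 1

    def test_noise_floor_ratio_mmr_vs_sbg(self):
        from scipy.signal import welch
        rec = make_static_record(fs=1000.0, duration=40.0)
        out_mmr = apply_sensor_model(rec, get_preset("mmr"), 3)
        out_sbg = apply_sensor_model(rec, get_preset("sbg"), 3)

        def density(rec_out):
            # in-band PSD level, away from DC and the anti-alias roll-off
            f, p = welch(rec_out.accel[0], fs=rec_out.sample_rate, nperseg=1024)
            band = (f >= 5.0) & (f <= 30.0)
            return np.sqrt(np.median(p[band]))

        assert density(out_mmr) / density(out_sbg) == pytest.approx(
            180 / 57, rel=0.10)

    def test_bit_identical_under_seed(self, static_record):
        a = apply_sensor_model(static_record, get_preset("mmr"), 5)
        b = apply_sensor_model(static_record, get_preset("mmr"), 5)
        assert np.array_equal(a.accel, b.accel)
        assert np.array_equal(a.gyro, b.gyro)

    def test_spec_validation_before_compute(self, static_record):
        bad = SensorSpec(name="bad", accel_misalignment=np.eye(3) * 1.5)
        with pytest.raises(ValueError, match="misalignment"):
            apply_sensor_model(static_record, bad, 0)

    def test_upsampling_spec_rejected(self):
        rec = make_static_record(fs=50.0, duration=2.0)
        with pytest.raises(ValueError, match="sample_rate"):
            apply_sensor_model(rec, get_preset("mmr"), 0)


def test_preset_degradations():
    mmr = get_preset("mmr")
    nb = get_preset("mmr_8bit")
    noisy = get_preset("mmr_8bit_noisy")
    assert (mmr.adc_bits, nb.adc_bits, noisy.adc_bits) == (16, 8, 8)
    assert noisy.accel_noise_density == pytest.approx(mmr.accel_noise_density * 1.1)
    assert noisy.gyro_noise_density == pytest.approx(mmr.gyro_noise_density * 1.1)
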