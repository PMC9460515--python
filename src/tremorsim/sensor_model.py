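"""IMU metrological error model.

Perturbs ideal inertial signals with the error sources of a specified
sensor: ADC quantization (rADC), axis misalignment (aMIS), constant bias
(bVAL), stochastic noise (white, random walk, bias instability), and
temperature effects (bias offset bTEMP and scale factor sfTEMP).  The
composition order mimics a physical signal chain: analog effects first,
digitization last —

    misalignment -> temperature scale -> bias (constant + thermal)
    -> stochastic noise -> rate conversion -> saturation + quantization

Accelerometer channels are kept in g, gyroscope in deg/s, magnetometer in
microtesla throughout, matching the units the sensor datasheet parameters
are quoted in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "SensorSpec", "InertialRecord", "quantize", "synth_noise", "resample",
    "apply_sensor_model", "misalignment_from_angles", "get_preset", "PRESETS",
]

NOISE_KINDS = ("white", "random_walk", "bias_instability")

#: Frobenius-norm budget for how far a misalignment matrix may sit from
#: the identity (small-angle cross-coupling only).
MISALIGNMENT_BUDGET = 0.05


def _as_matrix3(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"expected 3x3 matrix, got shape {m.shape}")
    return m


def misalignment_from_angles(xy: float = 0.0, xz: float = 0.0, yz: float = 0.0) -> np.ndarray:
    """Near-identity cross-coupling matrix from three small angles (rad).

    Each angle leaks a fraction sin(angle) of one axis into another;
    diagonal terms are cos-compensated so a unit vector stays near unit.
    """
    c = np.eye(3)
    c[0, 1] = np.sin(xy)
    c[0, 2] = np.sin(xz)
    c[1, 2] = np.sin(yz)
    c[1, 0] = -np.sin(xy)
    c[2, 0] = -np.sin(xz)
    c[2, 1] = -np.sin(yz)
    c[0, 0] = np.cos(xy) * np.cos(xz)
    c[1, 1] = np.cos(xy) * np.cos(yz)
    c[2, 2] = np.cos(xz) * np.cos(yz)
    return c


@dataclass
class SensorSpec:
    """Full metrological description of a (real or hypothetical) IMU.

    Noise densities are white-noise amplitudes per root-hertz; the
    per-sample standard deviation at sampling rate ``fs`` is
    ``density * sqrt(fs / 2)`` (Nyquist bandwidth).  Random-walk
    coefficients give a drift standard deviation of ``coeff * sqrt(t)``
    after ``t`` seconds; bias-instability coefficients are the stationary
    sigma of a first-order Gauss-Markov (flicker-like) process with
    correlation time ``bias_instability_tau``.
    """

    name: str = "custom"
    sample_rate: float = 100.0            # Hz
    adc_bits: int = 16                    # rADC
    accel_range: float = 16.0             # +/- g full scale
    gyro_range: float = 2000.0            # +/- deg/s full scale
    mag_range: float = 1300.0             # +/- uT full scale
    accel_noise_density: float = 0.0      # g/sqrt(Hz)
    gyro_noise_density: float = 0.0       # deg/s/sqrt(Hz)
    accel_misalignment: np.ndarray = field(default_factory=lambda: np.eye(3))
    gyro_misalignment: np.ndarray = field(default_factory=lambda: np.eye(3))
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))   # g
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))    # deg/s
    accel_random_walk: float = 0.0        # g/sqrt(s)
    gyro_random_walk: float = 0.0         # deg/s/sqrt(s)
    accel_bias_instability: float = 0.0   # g (stationary sigma)
    gyro_bias_instability: float = 0.0    # deg/s (stationary sigma)
    bias_instability_tau: float = 100.0   # s, Gauss-Markov correlation time
    temp_offset: float = 0.0              # degC from nominal (bTEMP)
    accel_temp_bias_coeff: float = 0.0    # g/degC
    gyro_temp_bias_coeff: float = 0.0     # deg/s/degC
    temp_scale_coeff: float = 0.0         # fraction/degC (sfTEMP)

    def __post_init__(self) -> None:
        self.accel_misalignment = _as_matrix3(self.accel_misalignment)
        self.gyro_misalignment = _as_matrix3(self.gyro_misalignment)
        self.accel_bias = np.asarray(self.accel_bias, dtype=float).reshape(3)
        self.gyro_bias = np.asarray(self.gyro_bias, dtype=float).reshape(3)

    def validate(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        if int(self.adc_bits) < 1:
            raise ValueError("adc_bits must be >= 1")
        for nm in ("accel_range", "gyro_range", "mag_range"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be > 0")
        for nm in ("accel_noise_density", "gyro_noise_density",
                   "accel_random_walk", "gyro_random_walk",
                   "accel_bias_instability", "gyro_bias_instability"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if not self.bias_instability_tau > 0:
            raise ValueError("bias_instability_tau must be > 0")
        for nm in ("accel_misalignment", "gyro_misalignment"):
            m = getattr(self, nm)
            dev = float(np.linalg.norm(m - np.eye(3)))
            if dev > MISALIGNMENT_BUDGET:
                raise ValueError(
                    f"{nm} deviates from identity by {dev:.3g} "
                    f"(budget {MISALIGNMENT_BUDGET})")

    def replace(self, **kw) -> "SensorSpec":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SensorSpec":
        return cls(**d)


@dataclass
class InertialRecord:
    """Uniformly sampled 9-axis time series.

    accel is 3xN in g, gyro 3xN in deg/s, mag 3xN in uT; all channels share
    the sample count and the time base ``t = arange(N) / sample_rate``.
    """

    sample_rate: float
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray

    def __post_init__(self) -> None:
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        self.mag = np.atleast_2d(np.asarray(self.mag, dtype=float))
        n = self.accel.shape[1]
        if self.accel.shape != (3, n) or self.gyro.shape != (3, n) or self.mag.shape != (3, n):
            raise ValueError("accel, gyro, mag must all be 3xN with a shared N")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def copy(self) -> "InertialRecord":
        return InertialRecord(self.sample_rate, self.accel.copy(),
                              self.gyro.copy(), self.mag.copy())

    def validate(self) -> None:
        for nm in ("accel", "gyro", "mag"):
            x = getattr(self, nm)
            if not np.all(np.isfinite(x)):
                idx = np.argwhere(~np.isfinite(x))[0]
                raise ValueError(f"non-finite value in {nm} at {tuple(idx)}")


def _check_finite(x: np.ndarray, what: str = "input") -> None:
    if not np.all(np.isfinite(x)):
        idx = int(np.flatnonzero(~np.isfinite(np.ravel(x)))[0])
        raise ValueError(f"non-finite {what} at flat index {idx}")


def quantize(x, bits: int, full_scale: float) -> np.ndarray:
    """Mid-tread uniform quantizer with saturation.

    LSB = 2 * full_scale / 2**bits; codes span [-(2**(bits-1)),
    2**(bits-1) - 1] (two's complement), so the positive rail saturates at
    full_scale - LSB.  Rounding is half-away-from-zero, making zero a grid
    point and the map odd-symmetric away from the rails.
    """
    if int(bits) < 1:
        raise ValueError("bits must be >= 1")
    if not full_scale > 0:
        raise ValueError("full_scale must be > 0")
    x = np.asarray(x, dtype=float)
    _check_finite(x)
    lsb = 2.0 * full_scale / (2 ** int(bits))
    # round half away from zero
    codes = np.sign(x) * np.floor(np.abs(x) / lsb + 0.5)
    lo = -(2 ** (int(bits) - 1))
    hi = 2 ** (int(bits) - 1) - 1
    codes = np.clip(codes, lo, hi)
    return codes * lsb


def synth_noise(kind: str, coeff: float, n: int, fs: float, seed,
                tau: float = 100.0) -> np.ndarray:
    """Synthesize one realization of a sensor noise process.

    white            i.i.d. N(0, sigma^2) with sigma = coeff * sqrt(fs/2)
                     (coeff is a density in units/sqrt(Hz))
    random_walk      cumulative sum of N(0, (coeff/sqrt(fs))^2) steps, so the
                     drift sigma grows as coeff * sqrt(t)
    bias_instability first-order Gauss-Markov process with stationary sigma
                     = coeff and correlation time tau (flicker-noise stand-in)

    ``seed`` may be an int or a numpy Generator; identical seeds give
    bit-identical output.
    """
    if kind not in NOISE_KINDS:
        raise ValueError(f"unknown noise kind {kind!r}; valid kinds: {NOISE_KINDS}")
    if coeff < 0:
        raise ValueError("coeff must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not fs > 0:
        raise ValueError("fs must be > 0")
    if coeff == 0.0:
        return np.zeros(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "white":
        return rng.normal(0.0, coeff * np.sqrt(fs / 2.0), size=n)
    if kind == "random_walk":
        steps = rng.normal(0.0, coeff / np.sqrt(fs), size=n)
        return np.cumsum(steps)
    # bias_instability: x[k] = phi x[k-1] + w[k], stationary sigma = coeff
    phi = np.exp(-1.0 / (fs * tau))
    w_sigma = coeff * np.sqrt(1.0 - phi ** 2)
    w = rng.normal(0.0, w_sigma, size=n)
    x0 = rng.normal(0.0, coeff)
    # lfilter implements the AR(1) recursion efficiently
    out = sp_signal.lfilter([1.0], [1.0, -phi], w, zi=[phi * x0])[0]
    return out


def _decimating_filter(x: np.ndarray, fs: float, target_rate: float) -> np.ndarray:
    """Zero-phase FIR anti-alias low-pass with cutoff 0.45 * target_rate."""
    cutoff = 0.45 * target_rate
    numtaps = int(max(31, 10 * fs / target_rate)) | 1  # odd
    taps = sp_signal.firwin(numtaps, cutoff, fs=fs)
    return sp_signal.filtfilt(taps, [1.0], x, axis=-1)


def resample(record: InertialRecord, target_rate: float) -> InertialRecord:
    """Anti-alias low-pass then decimate a record to a lower sample rate.

    Upsampling is unsupported.  DC levels are preserved (FIR filter has
    unit gain at DC).
    """
    if target_rate > record.sample_rate:
        raise ValueError("upsampling is unsupported: "
                         f"target {target_rate} Hz > record {record.sample_rate} Hz")
    if target_rate == record.sample_rate:
        return record.copy()
    ratio = record.sample_rate / target_rate
    chans = np.vstack([record.accel, record.gyro, record.mag])
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        filt = _decimating_filter(chans, record.sample_rate, target_rate)
        out = filt[:, ::q]
    else:
        from fractions import Fraction
        frac = Fraction(target_rate / record.sample_rate).limit_denominator(1000)
        filt = _decimating_filter(chans, record.sample_rate, target_rate)
        out = sp_signal.resample_poly(filt, frac.numerator, frac.denominator, axis=-1)
    return InertialRecord(target_rate, out[0:3], out[3:6], out[6:9])


def _perturb_instrument(x: np.ndarray, fs: float, mis: np.ndarray,
                        bias: np.ndarray, temp_bias: float, scale: float,
                        density: float, rw: float, bi: float, tau: float,
                        rng: np.random.Generator) -> np.ndarray:
    out = mis @ x
    out = out * scale
    out = out + bias[:, None] + temp_bias
    n = out.shape[1]
    for ax in range(3):
        if density > 0:
            out[ax] += synth_noise("white", density, n, fs, rng)
        if rw > 0:
            out[ax] += synth_noise("random_walk", rw, n, fs, rng)
        if bi > 0:
            out[ax] += synth_noise("bias_instability", bi, n, fs, rng, tau=tau)
    return out


def apply_sensor_model(record: InertialRecord, spec: SensorSpec, seed) -> InertialRecord:
    """Perturb an ideal record with the full error model of ``spec``.

    The record's sample rate must be at least the spec's; the output runs
    at ``spec.sample_rate``.  Magnetometer channels pass through rate
    conversion and quantization only.  Fully deterministic under a fixed
    (record, spec, seed) triple.
    """
    spec.validate()
    record.validate()
    if record.sample_rate < spec.sample_rate:
        raise ValueError("record sample_rate must be >= spec sample_rate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = record.sample_rate
    scale = 1.0 + spec.temp_scale_coeff * spec.temp_offset
    accel = _perturb_instrument(
        record.accel.copy(), fs, spec.accel_misalignment, spec.accel_bias,
        spec.accel_temp_bias_coeff * spec.temp_offset, scale,
        spec.accel_noise_density, spec.accel_random_walk,
        spec.accel_bias_instability, spec.bias_instability_tau, rng)
    gyro = _perturb_instrument(
        record.gyro.copy(), fs, spec.gyro_misalignment, spec.gyro_bias,
        spec.gyro_temp_bias_coeff * spec.temp_offset, scale,
        spec.gyro_noise_density, spec.gyro_random_walk,
        spec.gyro_bias_instability, spec.bias_instability_tau, rng)
    noisy = InertialRecord(fs, accel, gyro, record.mag.copy())
    low = resample(noisy, spec.sample_rate)
    return InertialRecord(
        spec.sample_rate,
        quantize(low.accel, spec.adc_bits, spec.accel_range),
        quantize(low.gyro, spec.adc_bits, spec.gyro_range),
        quantize(low.mag, spec.adc_bits, spec.mag_range),
    )


def _mmr(**over) -> SensorSpec:
    base = dict(
        name="mmr", sample_rate=100.0, adc_bits=16,
        accel_range=16.0, gyro_range=2000.0,
        accel_noise_density=180e-6, gyro_noise_density=0.0070,
    )
    base.update(over)
    return SensorSpec(**base)


#: Shipped sensor presets.  "sbg" and "mmr" follow the datasheet parameters
#: of the SBG Ellipse-E (1000 Hz reference-grade) and the MetaMotionR
#: wearable; "mmr_8bit" degrades the ADC to 8 bit; "mmr_8bit_noisy"
#: additionally worsens every noise coefficient by 10%.
PRESETS: dict[str, SensorSpec] = {
    "sbg": SensorSpec(
        name="sbg", sample_rate=1000.0, adc_bits=16,
        accel_range=16.0, gyro_range=1000.0,
        accel_noise_density=57e-6, gyro_noise_density=0.0025,
    ),
    "mmr": _mmr(),
    "mmr_8bit": _mmr(name="mmr_8bit", adc_bits=8),
    "mmr_8bit_noisy": _mmr(
        name="mmr_8bit_noisy", adc_bits=8,
        accel_noise_density=180e-6 * 1.10, gyro_noise_density=0.0070 * 1.10,
    ),
}


def get_preset(name: str) -> SensorSpec:
    """Return a fresh copy of a named sensor preset."""
    try:
        return PRESETS[name].replace()
    except KeyError:
        raise KeyError(
            f"unknown sensor preset {name!r}; available: {sorted(PRESETS)}") from None
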