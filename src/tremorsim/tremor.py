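"""Parkinsonian tremor synthesis and injection.

Tremor bursts are modeled analytically as multisine signals: per axis a sum
of ``n_components`` sinusoids with random frequencies inside the class
band, random amplitudes, and independent random phases.  Class bands follow
the clinical consensus ranges: rest tremor (RT) 4-7 Hz, postural tremor
(PT) 5-8 Hz, kinetic tremor (KT) around 9 Hz (realized as 8.5-9.5 Hz so
frequency can still be randomized).

A trial is a fixed-duration record (default 60 s) carrying a fixed number
of pairwise-disjoint tremor segments (default five of 2 s).  Injection
adds the multisine only inside the segments, with a short raised-cosine
taper at the edges to avoid spectral splatter; outside the segments the
record is bit-identical to its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tremorsim.sensor_model import InertialRecord

__all__ = [
    "TREMOR_BANDS", "TremorSpec", "TremorEvent", "make_multisine",
    "sample_tremor_event", "inject_tremor",
]

#: Clinical frequency bands (Hz) per tremor class.
TREMOR_BANDS: dict[str, tuple[float, float]] = {
    "RT": (4.0, 7.0),
    "PT": (5.0, 8.0),
    "KT": (8.5, 9.5),
}

#: Default per-axis total amplitude ranges: accel in g, gyro in deg/s.
DEFAULT_ACCEL_AMP = (0.05, 0.30)
DEFAULT_GYRO_AMP = (10.0, 60.0)

TAPER_S = 0.010  # raised-cosine on/off ramp at segment edges


@dataclass
class TremorSpec:
    """Tremor class with band, amplitude ranges and trial protocol."""

    tremor_class: str = "RT"
    freq_band: tuple[float, float] | None = None
    accel_amp_range: tuple[float, float] = DEFAULT_ACCEL_AMP
    gyro_amp_range: tuple[float, float] = DEFAULT_GYRO_AMP
    n_components: int = 3
    segment_duration: float = 2.0
    segments_per_trial: int = 5
    trial_duration: float = 60.0
    share_components_across_axes: bool = False

    def __post_init__(self) -> None:
        if self.tremor_class not in TREMOR_BANDS:
            raise ValueError(
                f"unknown tremor class {self.tremor_class!r}; "
                f"valid: {sorted(TREMOR_BANDS)}")
        if self.freq_band is None:
            self.freq_band = TREMOR_BANDS[self.tremor_class]

    def validate(self, fs: float | None = None) -> None:
        lo, hi = self.freq_band
        if not (0 < lo <= hi):
            raise ValueError("freq_band must satisfy 0 < lo <= hi")
        if fs is not None and hi >= fs / 2:
            raise ValueError(f"freq_band upper edge {hi} Hz >= Nyquist {fs / 2} Hz")
        for rng_ in (self.accel_amp_range, self.gyro_amp_range):
            if rng_[0] < 0 or rng_[1] < rng_[0]:
                raise ValueError("amplitude ranges must satisfy 0 <= lo <= hi")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.segments_per_trial * self.segment_duration > self.trial_duration:
            raise ValueError("segments do not fit into the trial duration")


@dataclass
class TremorEvent:
    """One tremor burst: interval + per-axis multisine components.

    ``accel_components`` / ``gyro_components`` are arrays of shape
    (3 axes, n_components, 3) holding (frequency Hz, amplitude, phase rad).
    """

    start: float
    duration: float
    accel_components: np.ndarray
    gyro_components: np.ndarray

    @property
    def end(self) -> float:
        return self.start + self.duration

    def overlaps(self, other: "TremorEvent") -> bool:
        return self.start < other.end and other.start < self.end


def make_multisine(components, duration: float, fs: float) -> np.ndarray:
    """s(t) = sum_k a_k sin(2 pi f_k t + phi_k), length round(duration*fs)."""
    n = int(round(duration * fs))
    out = np.zeros(n)
    t = np.arange(n) / fs
    for k, (f, a, phi) in enumerate(components):
        if f >= fs / 2:
            raise ValueError(
                f"component {k} frequency {f} Hz aliases at fs={fs} Hz")
        out += a * np.sin(2 * np.pi * f * t + phi)
    return out


def _draw_components(rng: np.random.Generator, band, amp_range, n_comp: int,
                     shared: np.ndarray | None) -> np.ndarray:
    """(3, n_comp, 3) array of (freq, amp, phase) per axis.

    Component amplitudes are uniform in amp_range / n_comp so the per-axis
    total (sum of component amplitudes) always stays inside amp_range.
    """
    if shared is not None:
        return shared.copy()
    lo, hi = band
    alo, ahi = amp_range
    comps = np.empty((3, n_comp, 3))
    for ax in range(3):
        comps[ax, :, 0] = rng.uniform(lo, hi, size=n_comp)
        comps[ax, :, 1] = rng.uniform(alo / n_comp, ahi / n_comp, size=n_comp)
        comps[ax, :, 2] = rng.uniform(0, 2 * np.pi, size=n_comp)
    return comps


def sample_tremor_event(spec: TremorSpec, trial_duration: float,
                        existing: list[TremorEvent], seed) -> TremorEvent:
    """Draw one event with uniform placement among disjoint feasible starts.

    Frequencies are uniform in the class band, per-axis total amplitudes
    uniform in the configured ranges, phases independent per axis.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dur = spec.segment_duration
    max_tries = 2000
    for attempt in range(max_tries):
        start = rng.uniform(0.0, trial_duration - dur)
        cand_iv = (start, start + dur)
        if all(not (cand_iv[0] < ev.end and ev.start < cand_iv[1]) for ev in existing):
            break
    else:
        raise RuntimeError(
            f"no feasible disjoint placement found after {max_tries} attempts")
    acc = _draw_components(rng, spec.freq_band, spec.accel_amp_range,
                           spec.n_components, None)
    if spec.share_components_across_axes:
        acc = np.broadcast_to(acc[0], acc.shape).copy()
    gyr = _draw_components(rng, spec.freq_band, spec.gyro_amp_range,
                           spec.n_components, None)
    if spec.share_components_across_axes:
        gyr = np.broadcast_to(gyr[0], gyr.shape).copy()
    return TremorEvent(start=start, duration=dur,
                       accel_components=acc, gyro_components=gyr)


def _raised_cosine_window(n: int, fs: float, taper_s: float = TAPER_S) -> np.ndarray:
    w = np.ones(n)
    m = int(round(taper_s * fs))
    if m > 0 and 2 * m < n:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
        w[:m] = ramp
        w[-m:] = ramp[::-1]
    return w


def tremor_waveform(event: TremorEvent, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Tapered per-axis accel (g) and gyro (deg/s) burst waveforms (3 x n)."""
    n = int(round(event.duration * fs))
    win = _raised_cosine_window(n, fs)
    acc = np.vstack([make_multisine(event.accel_components[ax], event.duration, fs)
                     for ax in range(3)]) * win
    gyr = np.vstack([make_multisine(event.gyro_components[ax], event.duration, fs)
                     for ax in range(3)]) * win
    return acc, gyr


def inject_tremor(record: InertialRecord, spec: TremorSpec,
                  seed) -> tuple[InertialRecord, list[TremorEvent]]:
    """Superimpose ``segments_per_trial`` disjoint tremor bursts on a record.

    Tremor is added to accelerometer and gyroscope channels only; the
    magnetometer and all samples outside the event intervals are
    bit-identical to the input.
    """
    spec.validate(record.sample_rate)
    if record.duration < spec.trial_duration - 1e-9:
        raise ValueError(
            f"record duration {record.duration:.3f} s shorter than trial "
            f"duration {spec.trial_duration} s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = record.copy()
    events: list[TremorEvent] = []
    fs = record.sample_rate
    for _ in range(spec.segments_per_trial):
        ev = sample_tremor_event(spec, spec.trial_duration, events, rng)
        events.append(ev)
        i0 = int(round(ev.start * fs))
        acc, gyr = tremor_waveform(ev, fs)
        n = acc.shape[1]
        out.accel[:, i0:i0 + n] += acc
        out.gyro[:, i0:i0 + n] += gyr
    events.sort(key=lambda e: e.start)
    return out, events
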