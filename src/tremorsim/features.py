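"""The 11-feature sliding-window representation and Z-score scaling.

Per channel and per window the features are, in order:

time domain
    1. mean                 arithmetic mean
    2. abs_mean             mean of absolute values ("average rectified")
    3. sq_sum_below_p25     sum of x_i^2 over samples below the 25th percentile
    4. sq_sum_below_p75     sum of x_i^2 over samples below the 75th percentile
    5. lowpass_energy       energy below 2 Hz (voluntary movement)
    6. highpass_energy      energy above 2.5 Hz (involuntary movement)
    7. autocorr_peak_lag    lag (s) of the first autocorrelation peak
    8. autocorr_peak_height normalized height of that peak
frequency domain
    9. dominant_freq        frequency (Hz) of the maximum-magnitude bin
    10. amp_sum_below_5hz   sum of spectral amplitudes in (0, 5] Hz
    11. n_peaks_below_5hz   count of spectral peaks in (0, 5] Hz

Energies, autocorrelation and the spectrum are computed on the de-meaned
window, so adding a constant offset changes only the mean / abs_mean /
percentile features.  Percentiles use linear interpolation on the signed
sample values.  The spectrum is a Hann-tapered magnitude spectrum scaled so
a pure sinusoid of amplitude ``a`` peaks near ``a``.

Z-score scaling fits mean and population standard deviation on the
training split only and applies them to both splits (no leakage).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FEATURE_NAMES", "band_energy", "autocorr_first_peak", "spectral_features",
    "extract_features", "extract_features_batch", "zscore_normalize",
    "WindowFeatureExtractor", "feature_column_names",
]

FEATURE_NAMES = [
    "mean", "abs_mean", "sq_sum_below_p25", "sq_sum_below_p75",
    "lowpass_energy", "highpass_energy", "autocorr_peak_lag",
    "autocorr_peak_height", "dominant_freq", "amp_sum_below_5hz",
    "n_peaks_below_5hz",
]

LOW_CUTOFF_HZ = 2.0
HIGH_CUTOFF_HZ = 2.5
SPECTRAL_BAND_HZ = 5.0
PEAK_PROMINENCE_FRAC = 0.10  # spectral peak threshold, fraction of global max


def _band_filter(x: np.ndarray, fs: float, band: str) -> np.ndarray:
    if band == "low":
        cut = LOW_CUTOFF_HZ
        btype = "lowpass"
    elif band == "high":
        cut = HIGH_CUTOFF_HZ
        btype = "highpass"
    else:
        raise ValueError(f"band must be 'low' or 'high', got {band!r}")
    if cut >= fs / 2:
        raise ValueError(f"{band} cutoff {cut} Hz >= Nyquist {fs / 2} Hz")
    b, a = sp_signal.butter(4, cut / (fs / 2), btype=btype)
    xm = x - x.mean(axis=-1, keepdims=True)
    return sp_signal.filtfilt(b, a, xm, axis=-1)


def band_energy(x, fs: float, band: str) -> float | np.ndarray:
    """Energy (sum of squares) of the zero-phase band-filtered, de-meaned
    signal; ``band`` is 'low' (<2 Hz) or 'high' (>2.5 Hz)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < int(0.5 * fs):
        raise ValueError("window shorter than 0.5 s")
    y = _band_filter(x, fs, band)
    return np.sum(y ** 2, axis=-1)


def _batch_autocorr_peak(xm: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """First autocorrelation peak (lag s, height) for rows of ``xm``
    (already de-meaned).  Rows without a zero crossing followed by a local
    maximum — including zero-variance rows — return (window_s, 0)."""
    w, n = xm.shape
    win_s = n / fs
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(xm, n=nfft, axis=-1)
    r = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=-1)[:, :n]
    r0 = r[:, 0].copy()
    ok = r0 > 0
    rho = np.zeros_like(r)
    rho[ok] = r[ok] / r0[ok, None]

    lags = np.full(w, win_s)
    heights = np.zeros(w)
    if n < 3:
        return lags, heights
    nonpos = rho[:, 1:] <= 0  # candidate zero crossings at k >= 1
    has_zc = nonpos.any(axis=1)
    kzc = np.where(has_zc, np.argmax(nonpos, axis=1) + 1, n)
    interior = np.zeros((w, n), dtype=bool)
    interior[:, 1:-1] = (rho[:, 1:-1] >= rho[:, :-2]) & (rho[:, 1:-1] >= rho[:, 2:])
    k_idx = np.arange(n)[None, :]
    cand = interior & (k_idx > kzc[:, None]) & ok[:, None] & has_zc[:, None]
    has_peak = cand.any(axis=1)
    first = np.argmax(cand, axis=1)
    lags[has_peak] = first[has_peak] / fs
    heights[has_peak] = rho[has_peak, first[has_peak]]
    return lags, heights


def autocorr_first_peak(x, fs: float) -> tuple[float, float]:
    """(lag_s, height) of the first peak of the normalized autocorrelation
    after its first zero crossing; (window_s, 0) if none exists."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("window must have at least 2 samples")
    xm = (x - x.mean())[None, :]
    lag, h = _batch_autocorr_peak(xm, fs)
    return float(lag[0]), float(h[0])


def _batch_spectrum(xm: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered amplitude spectrum of de-meaned rows; returns
    (freqs, magnitudes) with magnitudes scaled to sinusoid amplitude."""
    n = xm.shape[-1]
    win = np.hanning(n)
    mags = np.abs(np.fft.rfft(xm * win, axis=-1)) * 2.0 / win.sum()
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, mags


def _batch_spectral_features(xm: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    freqs, mags = _batch_spectrum(xm, fs)
    w = xm.shape[0]
    pos = freqs > 0
    mags_pos = np.where(pos[None, :], mags, 0.0)
    gmax = mags_pos.max(axis=1)
    dom = np.where(gmax > 0, freqs[np.argmax(mags_pos, axis=1)], 0.0)

    in_band = pos & (freqs <= SPECTRAL_BAND_HZ)
    amp_sum = mags_pos[:, in_band].sum(axis=1)

    nb = mags.shape[1]
    interior = np.zeros((w, nb), dtype=bool)
    if nb >= 3:
        interior[:, 1:-1] = (mags[:, 1:-1] > mags[:, :-2]) & (mags[:, 1:-1] >= mags[:, 2:])
    thresh = PEAK_PROMINENCE_FRAC * gmax
    is_peak = interior & in_band[None, :] & (mags > thresh[:, None]) & (gmax[:, None] > 0)
    n_peaks = is_peak.sum(axis=1).astype(float)
    return dom, amp_sum, n_peaks


def spectral_features(x, fs: float) -> tuple[float, float, int]:
    """(dominant_freq, amp_sum_below_5hz, n_peaks_below_5hz) of a window."""
    x = np.asarray(x, dtype=float)
    if x.size < int(fs):
        raise ValueError("window shorter than 1 s")
    xm = (x - x.mean())[None, :]
    dom, amp, npk = _batch_spectral_features(xm, fs)
    return float(dom[0]), float(amp[0]), int(npk[0])


def extract_features_batch(windows: np.ndarray, fs: float) -> np.ndarray:
    """Features for a stack of windows.

    ``windows`` has shape (n_windows, n_channels, n_samples); the result is
    (n_windows, n_channels * 11), channels concatenated in order, features
    in ``FEATURE_NAMES`` order within each channel.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim == 2:
        windows = windows[:, None, :]
    w, c, n = windows.shape
    flat = windows.reshape(w * c, n)
    if not np.all(np.isfinite(flat)):
        raise ValueError("non-finite sample in feature extraction input")

    feats = np.empty((w * c, len(FEATURE_NAMES)))
    feats[:, 0] = flat.mean(axis=1)
    feats[:, 1] = np.abs(flat).mean(axis=1)
    p25 = np.percentile(flat, 25, axis=1, method="linear")
    p75 = np.percentile(flat, 75, axis=1, method="linear")
    feats[:, 2] = np.sum(np.where(flat < p25[:, None], flat ** 2, 0.0), axis=1)
    feats[:, 3] = np.sum(np.where(flat < p75[:, None], flat ** 2, 0.0), axis=1)
    feats[:, 4] = band_energy(flat, fs, "low")
    feats[:, 5] = band_energy(flat, fs, "high")
    xm = flat - flat.mean(axis=1, keepdims=True)
    feats[:, 6], feats[:, 7] = _batch_autocorr_peak(xm, fs)
    feats[:, 8], feats[:, 9], feats[:, 10] = _batch_spectral_features(xm, fs)
    return feats.reshape(w, c * len(FEATURE_NAMES))


def extract_features(window: np.ndarray, fs: float,
                     channel_names: list[str] | None = None) -> pd.Series:
    """11 features per channel of a single (n_channels, n_samples) window,
    returned as a named pandas Series (``<channel>__<feature>``)."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    vals = extract_features_batch(window[None, :, :], fs)[0]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(window.shape[0])]
    idx = feature_column_names(channel_names)
    return pd.Series(vals, index=idx)


def feature_column_names(channel_names) -> list[str]:
    return [f"{ch}__{f}" for ch in channel_names for f in FEATURE_NAMES]


def zscore_normalize(train_features: np.ndarray, test_features: np.ndarray | None = None):
    """Z-score columns with training-set mean and population sigma.

    Returns (train_z, test_z, mu, sigma); ``test_z`` is None when no test
    matrix is given.  Zero-variance features map to 0 with a warning.
    """
    train = np.asarray(train_features, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("train_features must be 2-D with at least 2 rows")
    mu = train.mean(axis=0)
    sigma = train.std(axis=0)  # population convention (ddof=0)
    dead = sigma == 0
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} zero-variance feature(s) mapped to 0",
                      stacklevel=2)
    safe = np.where(dead, 1.0, sigma)
    train_z = (train - mu) / safe
    train_z[:, dead] = 0.0
    test_z = None
    if test_features is not None:
        test = np.asarray(test_features, dtype=float)
        test_z = (test - mu) / safe
        test_z[:, dead] = 0.0
    return train_z, test_z, mu, sigma


class WindowFeatureExtractor(BaseEstimator, TransformerMixin):
    """sklearn transformer: (n_windows, n_channels, n_samples) -> features.

    Stateless apart from the sampling rate; provided so the feature stage
    composes with sklearn pipelines and model selection.
    """

    def __init__(self, fs: float = 100.0):
        self.fs = fs

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim not in (2, 3):
            raise ValueError("X must be (n_windows, n_samples) or "
                             "(n_windows, n_channels, n_samples)")
        self.n_features_in_ = X.shape[1] if X.ndim == 3 else 1
        return self

    def transform(self, X):
        return extract_features_batch(np.asarray(X), self.fs)

    def get_feature_names_out(self, input_features=None):
        names = input_features or [f"ch{i}" for i in range(getattr(self, "n_features_in_", 1))]
        return np.array(feature_column_names(list(names)))
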