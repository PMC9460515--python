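"""Naive single-window, single-channel feature reference.

Deliberately plain loops and direct formulas, written independently of the
vectorized implementation, to serve as the oracle in equivalence tests.
"""

import numpy as np
from scipy import signal as sp_signal


def reference_features(x: np.ndarray, fs: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = np.empty(11)
    out[0] = sum(x) / n
    out[1] = sum(abs(v) for v in x) / n

    p25 = np.percentile(x, 25, method="linear")
    p75 = np.percentile(x, 75, method="linear")
    out[2] = sum(v * v for v in x if v < p25)
    out[3] = sum(v * v for v in x if v < p75)

    xm = x - sum(x) / n
    b, a = sp_signal.butter(4, 2.0 / (fs / 2), btype="lowpass")
    low = sp_signal.filtfilt(b, a, xm)
    out[4] = sum(v * v for v in low)
    b, a = sp_signal.butter(4, 2.5 / (fs / 2), btype="highpass")
    high = sp_signal.filtfilt(b, a, xm)
    out[5] = sum(v * v for v in high)

    # autocorrelation by direct time-domain products (no FFT)
    r0 = float(np.dot(xm, xm))
    lag_s, height = n / fs, 0.0
    if r0 > 0:
        rho = np.array([np.dot(xm[:n - k], xm[k:]) / r0 for k in range(n)])
        kzc = None
        for k in range(1, n):
            if rho[k] <= 0:
                kzc = k
                break
        if kzc is not None:
            for m in range(kzc + 1, n - 1):
                if rho[m] >= rho[m - 1] and rho[m] >= rho[m + 1]:
                    lag_s, height = m / fs, rho[m]
                    break
    out[6], out[7] = lag_s, height

    win = np.hanning(n)
    spec = np.abs(np.fft.rfft(xm * win)) * 2.0 / win.sum()
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    pos = freqs > 0
    gmax = spec[pos].max() if pos.any() else 0.0
    if gmax > 0:
        out[8] = freqs[pos][np.argmax(spec[pos])]
    else:
        out[8] = 0.0
    band = pos & (freqs <= 5.0)
    out[9] = spec[band].sum()
    count = 0
    if gmax > 0:
        for i in range(1, len(spec) - 1):
            if band[i] and spec[i] > spec[i - 1] and spec[i] >= spec[i + 1] \
                    and spec[i] > 0.10 * gmax:
                count += 1
    out[10] = count
    return out
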