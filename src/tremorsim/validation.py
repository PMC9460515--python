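"""Simulator-validation figures of merit.

Two aligned signals are compared, after independent min-max normalization
to [0, 1], by Pearson's correlation coefficient and the root-mean-square
error, both expressed in percent:

    rho_%  = E[(X - mu_x)(Y - mu_y)] / (sigma_x sigma_y) * 100
    RMSE_% = sqrt(1/n sum_i (X_i - Y_i)^2) * 100

Population (n-denominator) moments are used.  The comparison can also be
run on the absolute values of the signals, and on whole records axis by
axis.  When the two signals come from devices at different rates, the
faster one is resampled down and an optional cross-correlation lag search
aligns them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tremorsim.sensor_model import InertialRecord, resample

__all__ = ["SignalComparison", "minmax_normalize", "compare_signals",
           "compare_records"]


@dataclass
class SignalComparison:
    pearson_pct: float
    rmse_pct: float
    n: int
    label: str = ""


def minmax_normalize(x) -> np.ndarray:
    """Rescale to [0, 1]; the minimum maps to 0 and the maximum to 1."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("constant signal: min-max scaling is undefined")
    return (x - lo) / (hi - lo)


def _align_by_xcorr(x: np.ndarray, y: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    xm = x - x.mean()
    ym = y - y.mean()
    lags = range(-max_lag, max_lag + 1)
    best_lag, best = 0, -np.inf
    for lag in lags:
        if lag >= 0:
            a, b = xm[lag:], ym[:len(ym) - lag]
        else:
            a, b = xm[:len(xm) + lag], ym[-lag:]
        if len(a) < 2:
            continue
        c = float(np.dot(a, b))
        if c > best:
            best, best_lag = c, lag
    if best_lag >= 0:
        return x[best_lag:], y[:len(y) - best_lag]
    return x[:len(x) + best_lag], y[-best_lag:]


def compare_signals(x, y, absolute: bool = False, normalize: bool = True,
                    align: bool = False, max_lag: int = 0,
                    label: str = "") -> SignalComparison:
    """Pearson% and RMSE% between two equal-length signals.

    With ``normalize`` (the default) each signal is min-max scaled
    independently first, bounding RMSE% by 100.  ``absolute`` compares
    |x| with |y| (the "abs" rows of validation tables); ``align`` searches
    a cross-correlation lag up to ``max_lag`` samples before comparing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if absolute:
        x, y = np.abs(x), np.abs(y)
    if align and max_lag > 0:
        x, y = _align_by_xcorr(x, y, max_lag)
    if normalize:
        x = minmax_normalize(x)
        y = minmax_normalize(y)
    mx, my = x.mean(), y.mean()
    sx, sy = x.std(), y.std()  # population
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance signal: Pearson undefined")
    rho = float(np.mean((x - mx) * (y - my)) / (sx * sy))
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    return SignalComparison(pearson_pct=100 * rho, rmse_pct=100 * rmse,
                            n=int(x.size), label=label)


def compare_records(a: InertialRecord, b: InertialRecord,
                    instrument: str = "accel", align: bool = False,
                    max_lag_s: float = 0.1) -> pd.DataFrame:
    """Per-axis + abs comparison table for one instrument of two records.

    The faster record is resampled down to the slower rate first.
    """
    if a.sample_rate > b.sample_rate:
        a = resample(a, b.sample_rate)
    elif b.sample_rate > a.sample_rate:
        b = resample(b, a.sample_rate)
    xa = getattr(a, instrument)
    xb = getattr(b, instrument)
    n = min(xa.shape[1], xb.shape[1])
    max_lag = int(max_lag_s * a.sample_rate)
    rows = []
    for i, axis in enumerate(("x", "y", "z")):
        c = compare_signals(xa[i, :n], xb[i, :n], align=align,
                            max_lag=max_lag, label=axis)
        rows.append({"axis": axis, "pearson_pct": c.pearson_pct,
                     "rmse_pct": c.rmse_pct, "n": c.n})
    mag_a = np.linalg.norm(xa[:, :n], axis=0)
    mag_b = np.linalg.norm(xb[:, :n], axis=0)
    c = compare_signals(mag_a, mag_b, align=align, max_lag=max_lag, label="abs")
    rows.append({"axis": "abs", "pearson_pct": c.pearson_pct,
                 "rmse_pct": c.rmse_pct, "n": c.n})
    return pd.DataFrame(rows).set_index("axis")
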