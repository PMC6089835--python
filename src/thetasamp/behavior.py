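"""Reaction-time time courses on the target-delay grid and their rhythm.

Targets appear at 20 delays spaced 37.5 ms over the 750 ms following
flanker onset, so the RT-versus-delay series is effectively sampled at
~26.7 Hz.  RTs are normalized per session (deviation from the session
mean), pooled, averaged per delay, detrended with a second-order
polynomial, and tested for rhythmicity with the shuffle-surrogate test.
Delays in the 0-250 ms masking period are excluded from analysis.
Smoothing is display-only; every statistic runs on non-smoothed data.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import spectral
from .containers import RTSeries, SurrogateResult

__all__ = [
    "build_rt_timecourse",
    "detrend_rt",
    "smooth_rt",
    "rt_spectrum",
    "rt_phase_difference",
    "rt_peak_trough_delays",
]

MASKED_RANGE = (0.0, 250.0)


def build_rt_timecourse(
    rt_table: pd.DataFrame,
    location: str,
    masked_range: tuple[float, float] = MASKED_RANGE,
) -> RTSeries:
    """Mean +/- SEM normalized RT per target delay for one location.

    Only correct detection trials of ``location`` (``"center"`` or
    ``"flanker"``) enter.  RTs are first normalized session-wise as the
    deviation from that session's mean RT (over all its correct
    detection trials), then pooled and averaged per delay.  Unmasked
    delays with no trials are kept as NaN (interpolation happens only at
    the cross-correlation resampling step, never before spectral
    testing).
    """
    required = {"condition", "target_delay_ms", "rt_ms", "correct"}
    if not required.issubset(rt_table.columns):
        raise ValueError(f"rt_table needs columns {sorted(required)}")
    df = rt_table.copy()
    if "session" not in df.columns:
        df["session"] = 0
    det = df[(df["condition"] != "catch") & df["correct"]
             & np.isfinite(df["rt_ms"])].copy()
    if det.empty:
        raise ValueError("no correct detection trials")
    det["rt_norm"] = det["rt_ms"] - det.groupby("session")["rt_ms"].transform("mean")
    loc = det[det["condition"] == location]
    if loc.empty:
        raise ValueError(f"no trials for location {location!r}")
    delays = np.sort(rt_table["target_delay_ms"].dropna().unique())
    mean = np.full(delays.size, np.nan)
    sem = np.full(delays.size, np.nan)
    n = np.zeros(delays.size, dtype=int)
    for i, d in enumerate(delays):
        vals = loc.loc[loc["target_delay_ms"] == d, "rt_norm"].to_numpy()
        n[i] = vals.size
        if vals.size:
            mean[i] = vals.mean()
            sem[i] = (vals.std(ddof=1) / np.sqrt(vals.size)
                      if vals.size > 1 else np.nan)
    lo, hi = masked_range
    unmasked = (delays < lo) | (delays >= hi)
    if not np.isfinite(mean[unmasked]).any():
        raise ValueError("no unmasked delay has any correct trial")
    return RTSeries(delays_ms=delays, mean_rt=mean, sem_rt=sem,
                    n_per_delay=n, masked_range=masked_range,
                    location=location)


def detrend_rt(series: RTSeries) -> RTSeries:
    """Remove a least-squares second-order polynomial over unmasked delays."""
    m = series.unmasked
    if m.sum() < 4:
        raise ValueError("need at least 4 unmasked delays to detrend")
    x = series.delays_ms[m]
    y = series.mean_rt[m]
    coef = np.polyfit(x, y, 2)
    out = np.full_like(series.mean_rt, np.nan)
    out[m] = y - np.polyval(coef, x)
    return RTSeries(delays_ms=series.delays_ms, mean_rt=out,
                    sem_rt=series.sem_rt, n_per_delay=series.n_per_delay,
                    masked_range=series.masked_range,
                    location=series.location, detrended=True)


def smooth_rt(series: RTSeries, lam: Optional[float] = None) -> RTSeries:
    """Display-only smoothing spline over unmasked delays."""
    from scipy.interpolate import make_smoothing_spline
    m = series.unmasked
    x = series.delays_ms[m]
    y = series.mean_rt[m]
    spl = make_smoothing_spline(x, y, lam=lam)
    out = np.full_like(series.mean_rt, np.nan)
    out[m] = spl(x)
    return RTSeries(delays_ms=series.delays_ms, mean_rt=out,
                    sem_rt=series.sem_rt, n_per_delay=series.n_per_delay,
                    masked_range=series.masked_range,
                    location=series.location,
                    detrended=series.detrended, smoothed=True)


def _unmasked_series(series: RTSeries) -> tuple[np.ndarray, np.ndarray, float]:
    if series.smoothed:
        raise ValueError("statistics must run on non-smoothed RT data")
    m = series.unmasked
    x = series.delays_ms[m]
    y = series.mean_rt[m]
    if np.diff(x).size and not np.allclose(np.diff(x), np.diff(x)[0]):
        raise ValueError("unmasked delays must form a contiguous uniform grid")
    return x, y, series.grid_fs


def rt_spectrum(
    series: RTSeries,
    n_surrogates: int = 5000,
    seed: Optional[int] = None,
    pad_to: float = 5.0,
) -> SurrogateResult:
    """Shuffle-surrogate rhythmicity test of the detrended RT course.

    The delay-indexed series is treated as a time series at the grid's
    effective sampling rate (~26.7 Hz) and passed to the randomization
    test; surrogates shuffle the non-interpolated RT values.
    """
    if not series.detrended:
        raise ValueError("detrend the RT course before spectral testing")
    _, y, fs = _unmasked_series(series)
    return spectral.randomization_test(
        y, fs, n_surrogates=n_surrogates, seed=seed, pad_to=pad_to)


def rt_phase_difference(
    center: RTSeries,
    flanker: RTSeries,
    at_freq: float,
    pad_to: float = 5.0,
) -> float:
    """Circular difference (deg) of the two locations' Fourier phases.

    Computed at ``at_freq`` from the detrended, non-smoothed series;
    positive values mean the flanker rhythm lags the center rhythm.
    """
    xc, yc, fs = _unmasked_series(center)
    xf, yf, fsf = _unmasked_series(flanker)
    if not np.array_equal(xc, xf):
        raise ValueError("series must share the same unmasked delay grid")
    if not 0 < at_freq < fs / 2:
        raise ValueError("at_freq outside the resolvable band")
    phases = []
    for y in (yc, yf):
        spec = spectral.powerspectrum(y - y.mean(), fs, window=None,
                                      pad_to=pad_to)
        fi = int(np.argmin(np.abs(spec.freqs - at_freq)))
        phases.append(np.radians(spec.phase[fi]))
    d = np.degrees(np.angle(np.exp(1j * (phases[1] - phases[0]))))
    return float(d % 360.0)


def rt_peak_trough_delays(
    series: RTSeries,
    use_smoothed: bool = True,
    lam: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Delays (ms) of fast-RT peaks and slow-RT troughs.

    The RT course is inverted so that fast RTs are peaks.  Extrema are
    located on the display smoother by default (robust to single-bin
    noise) and snapped to the nearest grid delay; ``use_smoothed=False``
    finds extrema on the raw detrended course.  Raises when the course
    is monotonic (no interior extremum).
    """
    from scipy.signal import argrelmax, argrelmin
    if not series.detrended:
        raise ValueError("peak/trough detection expects a detrended course")
    work = smooth_rt(series, lam=lam) if use_smoothed else series
    m = work.unmasked
    x = work.delays_ms[m]
    fast = -work.mean_rt[m]  # inverted: peak = fast RT
    pk = argrelmax(fast, order=1)[0]
    tr = argrelmin(fast, order=1)[0]
    if pk.size == 0 and tr.size == 0:
        raise ValueError("no local extrema in the RT course")
    return x[pk], x[tr]
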