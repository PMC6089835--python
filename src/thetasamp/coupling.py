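"""Coupling between behavioral and neural rhythms.

The RT time course (inverted, so that a positive correlation means fast
RTs coincide with high MUA) and the catch-trial MUA PSTH are resampled
to a common 150 Hz grid in absolute trial time (a target delay ``d``
after flanker onset maps to trial time ``0.5 s + d``), mean-subtracted,
and cross-correlated over lags of +/-450 ms with overlap-scaled
normalization such that a zero-lag autocorrelation equals 1.  The peak
coefficient is the signed maximum within +/-125 ms of zero lag.  The
same machinery serves MUA-MUA lag estimation between channel groups;
lags convert to phase assuming a 4 Hz oscillation.  d' quantifies the
target-evoked MUA response against a baseline preceding the response
peak by 60 ms.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import spectral
from .containers import (CrossCorrelogram, DPrimeResult, RTSeries,
                         SurrogateResult, TrialTensor)

__all__ = [
    "phase_time_convert",
    "rt_mua_crosscorrelation",
    "ccg_rhythmicity",
    "mua_mua_lag",
    "single_trial_phase_at_target",
    "dprime",
    "dprime_target_response",
]

FS_COMMON = 150.0
MAX_LAG_MS = 450.0
PEAK_WINDOW_MS = 125.0
#: trial time (s) of flanker onset; target delays are relative to it
FLANKER_ONSET_S = 0.5


def phase_time_convert(value: float, freq: float, direction: str) -> float:
    """Convert between oscillation phase (deg) and time (ms) at ``freq``.

    ``deg_to_ms``: ms = deg / 360 * 1000 / freq (134 deg at 4 Hz -> 93 ms
    after rounding at report level); ``ms_to_deg``: deg = ms * freq * 360
    / 1000 (100 ms at 4 Hz -> 144 deg).  No rounding is applied here.
    """
    if freq <= 0:
        raise ValueError("freq must be positive")
    if direction == "deg_to_ms":
        return value / 360.0 * 1000.0 / freq
    if direction == "ms_to_deg":
        return value * freq * 360.0 / 1000.0
    raise ValueError("direction must be 'deg_to_ms' or 'ms_to_deg'")


def _lagged_corr(
    x: np.ndarray,
    y: np.ndarray,
    offset: int,
    max_lag: int,
    min_overlap: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap-scaled normalized cross-correlation.

    ``cc[k] = mean_i(x[i] * y[i + offset + k]) / sqrt(mean(x^2) mean(y^2))``
    over valid indices; lags with fewer than ``min_overlap`` overlapping
    samples are NaN.  ``offset`` places ``x[0]`` at index ``offset`` of
    ``y``'s sample grid.
    """
    nx, ny = x.size, y.size
    full = np.correlate(y, x, mode="full")          # index j: sum x[i] y[j-nx+1+i]
    counts = np.correlate(np.ones(ny), np.ones(nx), mode="full")
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.full(lags.size, np.nan)
    denom = np.sqrt(np.mean(x**2) * np.mean(y**2))
    if denom == 0:
        raise ValueError("flat input; correlation undefined")
    for li, k in enumerate(lags):
        j = k + offset + nx - 1
        if 0 <= j < full.size and counts[j] >= min_overlap:
            cc[li] = full[j] / counts[j] / denom
    if not np.isfinite(cc).any():
        raise ValueError("no lag has sufficient overlap")
    return lags, cc


def _peak(lags_ms: np.ndarray, cc: np.ndarray,
          window_ms: float = PEAK_WINDOW_MS) -> tuple[float, float]:
    """Signed maximum of ``cc`` within ``+/-window_ms`` around zero lag."""
    m = (np.abs(lags_ms) <= window_ms) & np.isfinite(cc)
    if not m.any():
        raise ValueError("no valid lag inside the peak window")
    sub = np.where(m, cc, -np.inf)
    i = int(np.argmax(sub))
    return float(cc[i]), float(lags_ms[i])


def _resample_rt(series: RTSeries, grid_t0: float,
                 fs: float = FS_COMMON) -> tuple[np.ndarray, int]:
    """Invert and linearly interpolate the RT course onto the common grid.

    Returns the resampled values and the index of their first sample on
    the grid anchored at ``grid_t0``.
    """
    if series.smoothed:
        raise ValueError("use the non-smoothed RT course")
    if not series.detrended:
        raise ValueError("detrend the RT course first")
    m = series.unmasked
    t_abs = FLANKER_ONSET_S + series.delays_ms[m] / 1000.0
    vals = -series.mean_rt[m]            # inverted: fast RT = positive
    i0 = int(np.ceil((t_abs[0] - grid_t0) * fs - 1e-9))
    i1 = int(np.floor((t_abs[-1] - grid_t0) * fs + 1e-9))
    tt = grid_t0 + np.arange(i0, i1 + 1) / fs
    return np.interp(tt, t_abs, vals), i0


def rt_mua_crosscorrelation(
    rt: RTSeries,
    mua_psth: np.ndarray,
    psth_fs: float,
    psth_t0: float,
    max_lag_ms: float = MAX_LAG_MS,
    min_overlap_s: float = 0.25,
) -> CrossCorrelogram:
    """Cross-correlate the inverted RT course with a catch-trial PSTH.

    Both signals are resampled to 150 Hz on a grid in absolute trial
    time, mean-subtracted, and correlated over ``+/-max_lag_ms`` with
    overlap-scaled (unbiased) normalization; the peak coefficient is the
    signed maximum within +/-125 ms of zero lag.  A positive peak means
    high MUA coincides with fast RTs.  Positive lags mean the MUA
    pattern follows the RT pattern by that delay on the trial-time axis.
    """
    from fractions import Fraction
    from scipy.signal import resample_poly
    frac = Fraction(FS_COMMON / psth_fs).limit_denominator(1000)
    y = np.asarray(resample_poly(np.asarray(mua_psth, float),
                                 frac.numerator, frac.denominator))
    x, i0 = _resample_rt(rt, psth_t0)
    x = x - x.mean()
    y = y - y.mean()
    max_lag = int(round(max_lag_ms / 1000.0 * FS_COMMON))
    min_ov = max(int(round(min_overlap_s * FS_COMMON)), 2)
    lags, cc = _lagged_corr(x, y, i0, max_lag, min_ov)
    lags_ms = lags * 1000.0 / FS_COMMON
    peak_c, peak_lag = _peak(lags_ms, cc)
    return CrossCorrelogram(lags_ms=lags_ms, cc=cc, peak_coefficient=peak_c,
                            peak_lag_ms=peak_lag, fs_common=FS_COMMON,
                            inverted_rt=True)


def ccg_rhythmicity(
    rt: RTSeries,
    mua_psth: np.ndarray,
    psth_fs: float,
    psth_t0: float,
    n_surrogates: int = 1000,
    seed: Optional[int] = None,
    pad_to: float = 5.0,
) -> SurrogateResult:
    """Rhythmicity of the RT-MUA cross-correlogram.

    The observed statistic is the power spectrum of the correlogram's
    lag series; the null re-runs the *full* cross-correlation on RT
    courses whose values were randomly re-assigned to new delay
    positions, then takes the spectrum of each surrogate correlogram.
    """
    rng = np.random.default_rng(seed)

    def spectrum_of(series: RTSeries):
        ccg = rt_mua_crosscorrelation(series, mua_psth, psth_fs, psth_t0)
        valid = np.isfinite(ccg.cc)
        return spectral.powerspectrum(ccg.cc[valid] - ccg.cc[valid].mean(),
                                      FS_COMMON, window=None, pad_to=pad_to)

    obs = spectrum_of(rt)
    if not np.any(obs.power > 0):
        raise ValueError("degenerate cross-correlogram (all zeros)")
    m = rt.unmasked
    vals = rt.mean_rt[m]
    sur = np.empty((n_surrogates, obs.power.size))
    shuf_series = RTSeries(delays_ms=rt.delays_ms.copy(),
                           mean_rt=rt.mean_rt.copy(),
                           masked_range=rt.masked_range,
                           location=rt.location, detrended=True)
    for i in range(n_surrogates):
        shuf_series.mean_rt[m] = rng.permutation(vals)
        sur[i] = spectrum_of(shuf_series).power
    k = (sur >= obs.power[None, :]).sum(axis=0)
    p = (k + 1.0) / (n_surrogates + 1.0)
    band95 = np.percentile(sur, 95.0, axis=0)
    return SurrogateResult(obs.freqs, obs.power, band95, p,
                           n_surrogates, seed, surrogate_power=sur)


def mua_mua_lag(
    ch1: np.ndarray,
    ch2: np.ndarray,
    fs: float,
    at_freq: float = 4.0,
    max_lag_ms: float = MAX_LAG_MS,
    peak_window_ms: float = PEAK_WINDOW_MS,
) -> tuple[float, float]:
    """Lag between two aligned MUA series and its phase at ``at_freq``.

    Both series are resampled to 150 Hz, mean-subtracted and
    cross-correlated; the lag of the correlogram peak within
    +/-``peak_window_ms`` is converted to degrees assuming a 4 Hz
    oscillation.  Returns ``(lag_ms, lag_deg)``.
    """
    from scipy.signal import resample_poly
    from fractions import Fraction
    ch1 = np.asarray(ch1, float)
    ch2 = np.asarray(ch2, float)
    if ch1.std() == 0.0 or ch2.std() == 0.0:
        raise ValueError("flat series; lag undefined")
    frac = Fraction(FS_COMMON / fs).limit_denominator(1000)
    x = np.asarray(resample_poly(ch1, frac.numerator, frac.denominator))
    y = np.asarray(resample_poly(ch2, frac.numerator, frac.denominator))
    x = x - x.mean()
    y = y - y.mean()
    max_lag = int(round(max_lag_ms / 1000.0 * FS_COMMON))
    lags, cc = _lagged_corr(x, y, 0, max_lag,
                            max(int(0.25 * FS_COMMON), 2))
    lags_ms = lags * 1000.0 / FS_COMMON
    _, lag = _peak(lags_ms, cc, window_ms=peak_window_ms)
    return lag, phase_time_convert(lag, at_freq, "ms_to_deg")


def single_trial_phase_at_target(
    trial_mua: np.ndarray,
    fs: float,
    target_time: float,
    theta_freq: float,
    t0: float = 0.0,
    conduction_delay_ms: float = 0.0,
) -> float:
    """Theta phase (deg) of a single trial's MUA at target presentation.

    The time-resolved phase (0.5 s sliding window, 4 Hz multitaper
    smoothing) is evaluated at the time of target presentation on
    screen.  ``conduction_delay_ms`` optionally adds the phase advance
    accumulated while the target signal travels to cortex (~100 ms,
    i.e. 144 deg at 4 Hz).
    """
    ps = spectral.timeresolved_phase(trial_mua, fs, theta_freq, t0=t0)
    phase = ps.at(target_time)
    if conduction_delay_ms:
        phase += phase_time_convert(conduction_delay_ms, ps.freq, "ms_to_deg")
    return phase % 360.0


def dprime(mu_p: float, mu_b: float, sigma_p: float, sigma_b: float) -> float:
    """``d' = (mu_p - mu_b) / sqrt((sigma_p^2 + sigma_b^2) / 2)``."""
    pooled = 0.5 * (sigma_p**2 + sigma_b**2)
    if pooled == 0:
        raise ValueError("both SDs zero; d' undefined")
    return (mu_p - mu_b) / np.sqrt(pooled)


def dprime_target_response(
    signal: TrialTensor,
    channel: int,
    trials: np.ndarray,
    condition: str = "",
    search_window_s: tuple[float, float] = (0.0, 0.2),
    peak_halfwidth_s: float = 0.02,
    baseline_precede_s: float = 0.06,
) -> DPrimeResult:
    """d' of the target-evoked MUA response for a trial set.

    Trials are aligned on their per-trial target onsets
    (``event_times['target_on']``).  The response peak is the maximum of
    the trial-averaged target-aligned MUA within ``search_window_s``
    after target onset; the peak window is 40 ms centered there and the
    baseline is an equal-length window ending ``baseline_precede_s``
    before the peak window's center.  Means and SDs are taken across
    trials of the window-averaged MUA.
    """
    trials = np.asarray(trials, dtype=int)
    if trials.size < 2:
        raise ValueError("need at least 2 trials per condition")
    t_target = np.asarray(signal.event_times["target_on"], dtype=float)
    if t_target.ndim == 0:
        t_target = np.full(signal.n_trials, float(t_target))
    fs = signal.fs
    n_rel = int(round((search_window_s[1] - search_window_s[0]) * fs))
    rel = np.arange(n_rel) / fs + search_window_s[0]
    snips = np.empty((trials.size, n_rel))
    for k, tr in enumerate(trials):
        tt = t_target[tr]
        if not np.isfinite(tt):
            raise ValueError(f"trial {tr} has no target")
        i0 = int(round((tt + search_window_s[0] - signal.t0_offset) * fs))
        snips[k] = signal.data[channel, tr, i0: i0 + n_rel]
    peak_rel = rel[int(np.argmax(snips.mean(axis=0)))]
    half = int(round(peak_halfwidth_s * fs))
    base_center = peak_rel - baseline_precede_s - peak_halfwidth_s
    mu = {}
    sd = {}
    for name, center in (("p", peak_rel), ("b", base_center)):
        per_trial = np.empty(trials.size)
        for k, tr in enumerate(trials):
            ic = int(round((t_target[tr] + center - signal.t0_offset) * fs))
            per_trial[k] = signal.data[channel, tr, ic - half: ic + half].mean()
        mu[name] = float(per_trial.mean())
        sd[name] = float(per_trial.std(ddof=1))
    d = dprime(mu["p"], mu["b"], sd["p"], sd["b"])
    return DPrimeResult(mu_p=mu["p"], mu_b=mu["b"], sigma_p=sd["p"],
                        sigma_b=sd["b"], dprime=float(d),
                        condition=condition, n_trials=int(trials.size))
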