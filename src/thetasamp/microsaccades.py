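"""Microsaccade detection and its relation to trial-structured signals.

Detection follows the velocity-space outlier approach of Engbert &
Kliegl: eye velocities from a 5-sample moving-window derivative, a robust
(median-based) SD per axis, and an elliptical threshold at ``lambda_sd``
(default 5) robust SDs.  Supra-threshold runs of at least 6 ms become
events; events separated by less than 20 ms are merged.  The module also
provides the rate, kernel-density and triggered-average summaries used to
test whether a neural rhythm depends on microsaccades.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from . import spectral
from .containers import (EyeTrace, MicrosaccadeEvent, SpectralResult,
                         TrialTensor)

__all__ = [
    "detect_microsaccades",
    "ms_rate",
    "ms_density",
    "ms_triggered_average",
    "bonferroni_holm",
    "split_trials_by_ms",
    "compare_theta_by_ms",
]

#: minimum event duration (s): 3 samples at 500 Hz
MIN_DURATION = 0.006
#: events closer than this (s) are merged
MERGE_GAP = 0.020


def _ek_velocity(pos: np.ndarray, fs: float) -> np.ndarray:
    """5-sample moving-window velocity estimate (deg/s)."""
    v = np.zeros_like(pos)
    v[2:-2] = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) * fs / 6.0
    return v


def _robust_sd(v: np.ndarray) -> float:
    """Median-based velocity SD: sqrt(median(v^2) - median(v)^2)."""
    var = np.median(v**2) - np.median(v) ** 2
    return float(np.sqrt(max(var, 0.0)))


def detect_microsaccades(
    eye: EyeTrace,
    lambda_sd: float = 5.0,
) -> list[MicrosaccadeEvent]:
    """Detect microsaccades as outliers in velocity space.

    The elliptical criterion ``(vx/ex)^2 + (vy/ey)^2 > 1`` with
    ``e = lambda_sd x robust SD`` marks candidate samples; runs of at
    least ``MIN_DURATION`` become events, runs separated by less than
    ``MERGE_GAP`` are merged.  Amplitude is the displacement between
    onset and offset positions; peak velocity is the maximal velocity
    magnitude within the event.
    """
    if eye.x.size < 5:
        raise ValueError("trace shorter than the 5-sample velocity window")
    fs = eye.fs
    vx = _ek_velocity(eye.x, fs)
    vy = _ek_velocity(eye.y, fs)
    ex = lambda_sd * _robust_sd(vx)
    ey = lambda_sd * _robust_sd(vy)
    if ex == 0.0 or ey == 0.0:
        raise ValueError("zero velocity variance; threshold undefined")
    above = (vx / ex) ** 2 + (vy / ey) ** 2 > 1.0
    runs: list[list[int]] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge runs separated by < MERGE_GAP
    merged: list[list[int]] = []
    gap = int(round(MERGE_GAP * fs))
    for run in runs:
        if merged and run[0] - merged[-1][1] < gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    min_len = int(round(MIN_DURATION * fs))
    events: list[MicrosaccadeEvent] = []
    speed = np.hypot(vx, vy)
    for i0, i1 in merged:
        if i1 - i0 + 1 < min_len:
            continue
        amp = float(np.hypot(eye.x[i1] - eye.x[i0], eye.y[i1] - eye.y[i0]))
        events.append(MicrosaccadeEvent(
            trial=eye.trial,
            onset=eye.t0_offset + i0 / fs,
            offset=eye.t0_offset + i1 / fs,
            amplitude=amp,
            peak_velocity=float(speed[i0: i1 + 1].max()),
        ))
    return events


def ms_rate(
    events: Sequence[MicrosaccadeEvent],
    windows: dict[int, tuple[float, float]],
) -> float:
    """Average microsaccade rate (Hz) across trials.

    ``windows`` maps trial id to its analysis window ``[a, b)``.  The
    rate is the mean over trials of (event count in window) / (window
    length); e.g. counts {1, 0, 2} in 0.75 s windows give
    (1+0+2)/3/0.75 = 1.333 Hz.
    """
    if not windows:
        raise ValueError("no analysis windows")
    counts = dict.fromkeys(windows, 0)
    for ev in events:
        w = windows.get(ev.trial)
        if w is not None and w[0] <= ev.onset < w[1]:
            counts[ev.trial] += 1
    rates = []
    for tr, (a, b) in windows.items():
        if b <= a:
            raise ValueError("zero-length analysis window")
        rates.append(counts[tr] / (b - a))
    return float(np.mean(rates))


def ms_density(
    event_times: np.ndarray,
    window: tuple[float, float] = (0.3, 1.0),
    bandwidth: float = 0.18,
    fs_grid: float = 500.0,
    pad_to: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, Optional[SpectralResult]]:
    """Gaussian kernel density of pooled event times, plus its spectrum.

    Event times from all trials are pooled on the analysis window and
    smoothed with a normal kernel of SD ``bandwidth`` (seconds); the
    density is then fed to the same Hanning-tapered power spectrum as the
    MUA.  The evaluation grid extends 4 bandwidths beyond the window so
    the kernel mass is not truncated and the density integrates to 1.
    Returns ``(times, density, spectrum)``; with no events the density is
    empty and the spectrum ``None`` (trials without any microsaccade are
    common).
    """
    event_times = np.asarray(event_times, dtype=float)
    t = np.arange(window[0] - 4 * bandwidth, window[1] + 4 * bandwidth,
                  1.0 / fs_grid)
    if event_times.size == 0:
        return t, np.zeros(0), None
    diffs = t[None, :] - event_times[:, None]
    dens = np.exp(-0.5 * (diffs / bandwidth) ** 2).sum(axis=0)
    dens /= event_times.size * bandwidth * np.sqrt(2 * np.pi)
    spec = spectral.powerspectrum(dens - dens.mean(), fs_grid, window=None,
                                  pad_to=max(pad_to, t.size / fs_grid))
    return t, dens, spec


def bonferroni_holm(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejection set at family-wise level ``alpha``.

    Returns a boolean array aligned with the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


def ms_triggered_average(
    events: Sequence[MicrosaccadeEvent],
    signal: TrialTensor,
    window: tuple[float, float] = (-0.3, 0.5),
    n_shuffles: int = 200,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> dict:
    """Microsaccade-triggered average of a trial-aligned signal.

    Each event's timestamp aligns its own trial's signal; events whose
    window is truncated by the trial edges are excluded (and counted).
    The shuffle control pairs each event time with a randomly chosen
    *different* trial, destroying any event-locked structure while
    keeping the trial-time statistics.  Per-timepoint two-sided p-values
    (event-triggered vs shuffle distribution) are Bonferroni-Holm
    corrected.

    Returns a dict with keys ``times``, ``mean``, ``sem``, ``control``,
    ``significant`` (channels x time), ``n_used``, ``n_excluded``.
    """
    rng = np.random.default_rng(seed)
    fs = signal.fs
    i_rel0 = int(round(window[0] * fs))
    i_rel1 = int(round(window[1] * fs))
    nwin = i_rel1 - i_rel0
    times = (np.arange(nwin) + i_rel0) / fs
    used: list[tuple[int, int]] = []
    n_excluded = 0
    for ev in events:
        ic = int(round((ev.onset - signal.t0_offset) * fs))
        if ic + i_rel0 < 0 or ic + i_rel1 > signal.n_samples:
            n_excluded += 1
            continue
        used.append((ev.trial, ic))
    if not used:
        raise ValueError("no event has a full window inside its trial")
    nch = signal.n_channels
    snips = np.empty((len(used), nch, nwin))
    ctrl = np.empty_like(snips)
    n_trials = signal.n_trials
    for k, (tr, ic) in enumerate(used):
        snips[k] = signal.data[:, tr, ic + i_rel0: ic + i_rel1]
        if n_trials > 1:
            other = rng.integers(0, n_trials - 1)
            other += other >= tr
        else:
            other = tr
        ctrl[k] = signal.data[:, other, ic + i_rel0: ic + i_rel1]
    mean = snips.mean(axis=0)
    sem = (snips.std(axis=0, ddof=1) / np.sqrt(len(used))
           if len(used) > 1 else np.full_like(mean, np.nan))
    ctrl_mean = ctrl.mean(axis=0)
    # per-timepoint paired comparison (event vs control snippets)
    pvals = np.ones_like(mean)
    if len(used) > 5:
        diff = snips - ctrl
        for c in range(nch):
            for j in range(nwin):
                d = diff[:, c, j]
                if np.allclose(d, 0.0):
                    pvals[c, j] = 1.0
                else:
                    pvals[c, j] = wilcoxon(d)[1]
    significant = np.stack([
        bonferroni_holm(pvals[c], alpha=alpha) for c in range(nch)])
    return {
        "times": times, "mean": mean, "sem": sem, "control": ctrl_mean,
        "p_values": pvals, "significant": significant,
        "n_used": len(used), "n_excluded": n_excluded,
    }


def split_trials_by_ms(
    events: Sequence[MicrosaccadeEvent],
    analysis_window: tuple[float, float],
    trial_ids: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Partition trials by microsaccade presence inside the window."""
    a, b = analysis_window
    if b <= a:
        raise ValueError("invalid analysis window")
    with_ms = {ev.trial for ev in events if a <= ev.onset < b}
    trial_ids = np.asarray(trial_ids)
    mask = np.isin(trial_ids, sorted(with_ms))
    return trial_ids[mask], trial_ids[~mask]


def compare_theta_by_ms(
    mua: TrialTensor,
    events: Sequence[MicrosaccadeEvent],
    analysis_window: tuple[float, float] = (0.3, 1.0),
    band: tuple[float, float] = spectral.THETA_BAND,
    pad_to: float = 5.0,
) -> dict:
    """Theta power per channel on trials with vs without microsaccades.

    Computes the band-mean power of each channel's spectrum separately
    over the two trial partitions and compares them with a paired
    two-sided Wilcoxon signed-rank test across channels.  If either
    partition is empty the comparison is skipped and flagged.
    """
    trials = np.arange(mua.n_trials)
    with_ms, without_ms = split_trials_by_ms(events, analysis_window, trials)
    if with_ms.size == 0 or without_ms.size == 0:
        return {"skipped": True, "with_ms": with_ms, "without_ms": without_ms,
                "p_value": np.nan}
    power = {}
    for name, subset in (("with", with_ms), ("without", without_ms)):
        vals = np.empty(mua.n_channels)
        for c in range(mua.n_channels):
            spec = spectral.powerspectrum(
                mua.data[c, subset, :], mua.fs, window=analysis_window,
                pad_to=pad_to, t0=mua.t0_offset, detrend_mean=True)
            vals[c] = spec.power[spec.band(*band)].mean()
        power[name] = vals
    diff = power["with"] - power["without"]
    p = 1.0 if np.allclose(diff, 0.0) else float(wilcoxon(diff)[1])
    return {"skipped": False, "with_ms": with_ms, "without_ms": without_ms,
            "theta_with": power["with"], "theta_without": power["without"],
            "p_value": p}
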