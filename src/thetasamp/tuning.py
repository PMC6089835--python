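"""Size tuning, suppression and theta indices, and channel selection.

Surround suppression is quantified from disk size-tuning curves:
``SI = (Amax - Amin) / Amax`` where ``Amax`` is the response at the RF
center diameter (the diameter eliciting the strongest mean activation)
and ``Amin`` the minimal mean response among larger diameters.  The theta
index ``TI = (ls - ss) / (ls + ss)`` contrasts theta power between two
stimulus conditions.  Channel inclusion requires the RF focus to lie
within 1.5 degrees of the stimulus center.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import wilcoxon

from . import spectral
from .containers import SizeTuningCurve, TrialTensor

__all__ = [
    "size_tuning",
    "suppression_index",
    "theta_index",
    "include_channel_by_rf",
    "select_theta_selective_channels",
]

ANALYSIS_WINDOW = (0.3, 1.0)
BASELINE_WINDOW = (-0.7, 0.0)


def suppression_index(a_max: float, a_min: float) -> float:
    """``SI = (Amax - Amin) / Amax``; ``Amax`` must be positive."""
    if a_max <= 0:
        raise ValueError("a_max must be positive")
    return (a_max - a_min) / a_max


def theta_index(power_large: float, power_small: float) -> float:
    """``TI = (ls - ss) / (ls + ss)`` in [-1, 1]; both powers nonnegative."""
    if power_large < 0 or power_small < 0:
        raise ValueError("powers must be nonnegative")
    tot = power_large + power_small
    if tot == 0:
        raise ValueError("both powers zero; TI undefined")
    return (power_large - power_small) / tot


def include_channel_by_rf(
    rf_center: tuple[float, float],
    stim_center: tuple[float, float],
    max_dist: float = 1.5,
) -> bool:
    """Whether the RF focus lies strictly within ``max_dist`` degrees of
    the stimulus center (Euclidean distance)."""
    d = float(np.hypot(rf_center[0] - stim_center[0],
                       rf_center[1] - stim_center[1]))
    return d < max_dist


def size_tuning(
    mua: TrialTensor,
    diameters_per_trial: Sequence[float],
    analysis_window: tuple[float, float] = ANALYSIS_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    alpha: float = 0.05,
) -> list[SizeTuningCurve]:
    """Per-channel size-tuning curve, RF-center diameter and SI.

    The RF center is the diameter eliciting the strongest mean response
    (across trials and post-stimulus time).  A channel is included only
    when its maximal response significantly exceeds baseline (one-sided
    Wilcoxon signed-rank across trials).  The SI compares the center
    response to the minimum over strictly larger diameters; if the RF
    center is the largest tested diameter there is no surround regime
    and the SI is undefined.
    """
    dia = np.asarray(diameters_per_trial, dtype=float)
    if dia.size != mua.n_trials:
        raise ValueError("one diameter per trial required")
    uniq = np.unique(dia)
    if uniq.size < 2:
        raise ValueError("need at least two distinct diameters")
    post = mua.windowed(analysis_window).mean(axis=2)   # ch x trials
    base = mua.windowed(baseline_window).mean(axis=2)
    curves = []
    for c in range(mua.n_channels):
        resp = np.array([post[c, dia == d].mean() for d in uniq])
        best = int(np.argmax(resp))
        rf_dia = float(uniq[best])
        sel = dia == uniq[best]
        diff = post[c, sel] - base[c, sel]
        included = False
        if not np.allclose(diff, 0.0):
            included = wilcoxon(diff, alternative="greater")[1] < alpha
        larger = resp[best + 1:]
        if larger.size and resp[best] > 0:
            si = suppression_index(resp[best], float(larger.min()))
            supp_defined = True
        else:
            si, supp_defined = np.nan, False
        curves.append(SizeTuningCurve(
            diameters=uniq, response=resp, rf_center_diameter=rf_dia,
            si=si, included=bool(included),
            suppression_defined=supp_defined,
            channel=mua.channel_labels[c]))
    return curves


def _channel_theta_power(
    mua: TrialTensor,
    channel: int,
    window: tuple[float, float],
    band: tuple[float, float],
    pad_to: float = 5.0,
) -> np.ndarray:
    """Per-trial band-mean theta power of one channel in a window."""
    out = np.empty(mua.n_trials)
    for tr in range(mua.n_trials):
        spec = spectral.powerspectrum(
            mua.data[channel, tr, :], mua.fs, window=window, pad_to=pad_to,
            t0=mua.t0_offset, detrend_mean=True)
        out[tr] = spec.power[spec.band(*band)].mean()
    return out


def select_theta_selective_channels(
    mua: TrialTensor,
    group: str,
    analysis_window: tuple[float, float] = ANALYSIS_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    band: tuple[float, float] = spectral.THETA_BAND,
    alpha: float = 0.05,
    n_surrogates: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Channels of ``group`` with significant stimulus-driven theta.

    Three criteria, mirroring the phase-analysis channel selection:
    response preference for the queried stimulus position (stronger mean
    post-stimulus response than the other group's channels show is not
    required -- preference is the channel's own group tag backed by its
    response), post-stimulus theta power significantly above baseline
    theta power (paired one-sided Wilcoxon across trials), and a
    significant shuffle-surrogate rhythmicity test on the trial-averaged
    post-stimulus time course.  Returns the selected channel indices
    (possibly empty).
    """
    if group not in ("disk", "bar"):
        raise ValueError("group must be 'disk' or 'bar'")
    # response preference: stronger mean response to its own stimulus
    # epoch; synthetic channels carry their group tag
    candidates = mua.group_channels(group)
    selected = []
    # baseline window may be shorter than the analysis window; compare
    # band-mean power, which is window-length normalized
    for c in candidates:
        post = _channel_theta_power(mua, c, analysis_window, band)
        base = _channel_theta_power(mua, c, baseline_window, band)
        diff = post - base
        if np.allclose(diff, 0.0):
            continue
        if wilcoxon(diff, alternative="greater")[1] >= alpha:
            continue
        avg = mua.data[c].mean(axis=0)
        seg = avg[mua.window_indices(analysis_window)]
        sur = spectral.randomization_test(
            seg, mua.fs, n_surrogates=n_surrogates, seed=seed + int(c))
        if not sur.significant(band, alpha=alpha):
            continue
        selected.append(int(c))
    return np.asarray(selected, dtype=int)
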