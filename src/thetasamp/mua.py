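"""Multi-unit activity envelope extraction and normalization.

MUA is estimated from broadband extracellular voltage as its
high-frequency envelope: high-pass at 300 Hz, full-wave rectification,
low-pass at 120 Hz, then anti-aliased downsampling to 500 Hz.  Envelopes
are z-scored channel-wise against the 700 ms pre-stimulus fixation
baseline so that all downstream analyses operate in z-units.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import TrialTensor

__all__ = ["extract_mua", "zscore_mua", "trial_average"]

#: leading/trailing span (s) where zero-phase filtering is edge-affected
EDGE_UNRELIABLE_S = 0.05


def _sos(kind: str, cutoff: float, fs: float, order: int = 4):
    return butter(order, cutoff, btype=kind, fs=fs, output="sos")


def extract_mua(
    broadband: TrialTensor,
    hp_hz: float = 300.0,
    lp_hz: float = 120.0,
    fs_out: float = 500.0,
) -> TrialTensor:
    """Extract the MUA envelope from broadband traces.

    Per channel and trial: zero-phase 4th-order Butterworth high-pass at
    ``hp_hz``, full-wave rectification, zero-phase low-pass at ``lp_hz``,
    then decimation to ``fs_out`` behind an anti-aliasing low-pass at 0.8x
    the output Nyquist.  Filtering pads trials by reflection (handled by
    ``sosfiltfilt``); the first and last ~50 ms remain edge-affected.
    The output is nonnegative up to filter ringing.
    """
    fs = broadband.fs
    if fs <= 2 * hp_hz:
        raise ValueError(f"broadband fs {fs} must exceed twice hp_hz {hp_hz}")
    if fs_out > fs:
        raise ValueError("fs_out cannot exceed the broadband rate")
    if lp_hz >= fs_out / 2:
        raise ValueError("lp_hz must be below the output Nyquist")
    q = fs / fs_out
    if abs(q - round(q)) > 1e-9:
        raise ValueError("broadband fs must be an integer multiple of fs_out")
    q = int(round(q))
    x = broadband.data
    x = sosfiltfilt(_sos("high", hp_hz, fs), x, axis=2)
    x = np.abs(x)
    x = sosfiltfilt(_sos("low", lp_hz, fs), x, axis=2)
    if q > 1:
        # guard band below the output Nyquist before subsampling
        x = sosfiltfilt(_sos("low", 0.8 * fs_out / 2, fs), x, axis=2)
        x = x[:, :, ::q]
    return TrialTensor(
        x, fs=fs_out, t0_offset=broadband.t0_offset,
        channel_labels=list(broadband.channel_labels),
        channel_groups=list(broadband.channel_groups),
        event_times=dict(broadband.event_times),
    )


def zscore_mua(
    mua: TrialTensor,
    baseline_window: tuple[float, float] = (-0.7, 0.0),
) -> tuple[TrialTensor, np.ndarray]:
    """Z-score each channel against its pre-stimulus fixation baseline.

    The baseline mean and SD are pooled over all trials' samples inside
    ``baseline_window`` (default: the 700 ms before first-stimulus
    onset).  Channels with zero baseline SD cannot be scaled; they are
    flagged and returned as NaN rather than silently kept.

    Returns
    -------
    (TrialTensor, excluded)
        The z-scored tensor and a boolean array marking excluded
        (constant-baseline) channels.
    """
    base = mua.windowed(baseline_window)
    mean = base.mean(axis=(1, 2))
    sd = base.std(axis=(1, 2))
    excluded = sd == 0.0
    safe_sd = np.where(excluded, np.nan, sd)
    data = (mua.data - mean[:, None, None]) / safe_sd[:, None, None]
    out = TrialTensor(
        data, fs=mua.fs, t0_offset=mua.t0_offset,
        channel_labels=list(mua.channel_labels),
        channel_groups=list(mua.channel_groups),
        event_times=dict(mua.event_times),
    )
    return out, excluded


def trial_average(
    mua: TrialTensor,
    trial_subset: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and SEM time course (PSTH) over a trial subset.

    With a single trial the mean equals that trial and the SEM is
    returned as NaN (undefined).
    """
    if trial_subset is None:
        sel = mua.data
    else:
        idx = np.asarray(trial_subset, dtype=int)
        if idx.size == 0:
            raise ValueError("empty trial subset")
        sel = mua.data[:, idx, :]
    mean = sel.mean(axis=1)
    nt = sel.shape[1]
    if nt < 2:
        sem = np.full_like(mean, np.nan)
    else:
        sem = sel.std(axis=1, ddof=1) / np.sqrt(nt)
    return mean, sem
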