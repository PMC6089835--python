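"""In-memory containers shared by all analysis stages.

Conventions used throughout the package:

* Time is expressed in seconds relative to first-stimulus onset.  A trial
  tensor stores ``t0_offset``, the time of its first sample, so that
  ``t0_offset + i / fs`` recovers absolute trial time for sample ``i``.
* Analysis windows are half-open intervals ``[a, b)``.
* Angles are degrees, wrapped to ``[0, 360)`` unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TrialTensor",
    "EyeTrace",
    "MicrosaccadeEvent",
    "SpectralResult",
    "SurrogateResult",
    "PhaseSeries",
    "RTSeries",
    "SizeTuningCurve",
    "CrossCorrelogram",
    "DPrimeResult",
]


@dataclass
class TrialTensor:
    """Trial-aligned multichannel signal: ``channels x trials x samples``.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_trials, n_samples)``.
    fs
        Sampling rate in Hz.
    t0_offset
        Time (s) of the first sample relative to first-stimulus onset
        (negative when a pre-stimulus baseline is included).
    channel_labels
        One identifier per channel.
    channel_groups
        One group tag per channel, each in ``{"disk", "bar", "other"}``.
    event_times
        Named event times in seconds.  Scalars apply to every trial;
        per-trial arrays (length ``n_trials``) are allowed, with NaN
        marking trials where the event did not occur (e.g. no target on
        catch trials).
    """

    data: np.ndarray
    fs: float
    t0_offset: float = 0.0
    channel_labels: Sequence[str] = field(default_factory=list)
    channel_groups: Sequence[str] = field(default_factory=list)
    event_times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, trials, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if not self.channel_groups:
            self.channel_groups = ["other"] * self.n_channels
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length mismatch")
        if len(self.channel_groups) != self.n_channels:
            raise ValueError("channel_groups length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Absolute trial time (s) of each sample."""
        return self.t0_offset + np.arange(self.n_samples) / self.fs

    def window_indices(self, window: tuple[float, float]) -> slice:
        """Sample slice covering the half-open time window ``[a, b)``."""
        a, b = window
        if b <= a:
            raise ValueError("window must satisfy a < b")
        t = self.times
        if a < t[0] - 0.5 / self.fs or b > t[-1] + 1.5 / self.fs:
            raise ValueError(
                f"window [{a}, {b}) outside trial extent [{t[0]}, {t[-1] + 1 / self.fs})"
            )
        i0 = int(np.ceil((a - self.t0_offset) * self.fs - 1e-9))
        i1 = int(np.ceil((b - self.t0_offset) * self.fs - 1e-9))
        return slice(max(i0, 0), min(i1, self.n_samples))

    def windowed(self, window: tuple[float, float]) -> np.ndarray:
        """Data restricted to ``[a, b)``."""
        return self.data[:, :, self.window_indices(window)]

    def group_channels(self, group: str) -> np.ndarray:
        """Indices of channels tagged with ``group``."""
        return np.flatnonzero(np.asarray(self.channel_groups) == group)


@dataclass
class EyeTrace:
    """Single-trial gaze position (visual degrees) at a fixed sampling rate."""

    trial: int
    x: np.ndarray
    y: np.ndarray
    fs: float = 500.0
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.x.size) / self.fs


@dataclass(frozen=True)
class MicrosaccadeEvent:
    """A detected (or injected) microsaccade."""

    trial: int
    onset: float
    offset: float
    amplitude: float
    peak_velocity: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


@dataclass
class SpectralResult:
    """One-sided power spectrum of a windowed, tapered, zero-padded series."""

    freqs: np.ndarray
    power: np.ndarray
    phase: Optional[np.ndarray] = None
    pad_to: float = 5.0
    taper: str = "hann"
    window: Optional[tuple[float, float]] = None

    def band(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask for frequencies in ``[lo, hi]``."""
        return (self.freqs >= lo) & (self.freqs <= hi)


@dataclass
class SurrogateResult:
    """Observed spectrum against a shuffle-surrogate null distribution.

    ``p_values`` are per-frequency; band-level inference uses the
    max-statistic over the band (``band_p``), which keeps the family-wise
    error controlled despite peak picking.
    """

    freqs: np.ndarray
    observed_power: np.ndarray
    null_band_95: np.ndarray
    p_values: np.ndarray
    n_surrogates: int
    seed: Optional[int] = None
    surrogate_power: Optional[np.ndarray] = None

    def band_p(self, band: tuple[float, float]) -> float:
        """Max-statistic p for the band: fraction of surrogates whose
        band-maximum power meets or exceeds the observed band maximum."""
        m = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not m.any():
            raise ValueError("band outside spectrum")
        obs = self.observed_power[m].max()
        if self.surrogate_power is None:
            # fall back on the per-frequency p at the band peak
            peak = np.argmax(np.where(m, self.observed_power, -np.inf))
            return float(self.p_values[peak])
        k = int((self.surrogate_power[:, m].max(axis=1) >= obs).sum())
        return (k + 1.0) / (self.n_surrogates + 1.0)

    def significant(self, band: tuple[float, float], alpha: float = 0.05) -> bool:
        """Whether the band-limited rhythm beats the shuffle null at ``alpha``."""
        return bool(self.band_p(band) < alpha)


@dataclass
class PhaseSeries:
    """Time-resolved phase (degrees, wrapped to [0, 360)) at one frequency."""

    times: np.ndarray
    phase: np.ndarray
    freq: float
    window_len: float = 0.5
    smoothing_hz: float = 4.0

    def at(self, t: float) -> float:
        """Phase at time ``t`` (nearest window center)."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} outside phase coverage "
                             f"[{self.times[0]}, {self.times[-1]}]")
        return float(self.phase[np.argmin(np.abs(self.times - t))])


@dataclass
class RTSeries:
    """Mean reaction time per target-onset delay on the task's delay grid.

    ``mean_rt`` is NaN at masked delays (the post-flanker masking period)
    and at delays with no usable trials.  ``detrended``/``smoothed`` record
    the processing state; all statistics must run on non-smoothed data.
    """

    delays_ms: np.ndarray
    mean_rt: np.ndarray
    sem_rt: Optional[np.ndarray] = None
    n_per_delay: Optional[np.ndarray] = None
    masked_range: tuple[float, float] = (0.0, 250.0)
    location: str = ""
    detrended: bool = False
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        self.mean_rt = np.asarray(self.mean_rt, dtype=float)
        if self.delays_ms.shape != self.mean_rt.shape:
            raise ValueError("delays and mean_rt must align")

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean mask of analyzable delays (outside mask, with data)."""
        lo, hi = self.masked_range
        outside = (self.delays_ms < lo) | (self.delays_ms >= hi)
        return outside & np.isfinite(self.mean_rt)

    @property
    def grid_fs(self) -> float:
        """Effective sampling rate (Hz) of the delay grid."""
        dt = np.diff(self.delays_ms)
        if not np.allclose(dt, dt[0]):
            raise ValueError("delay grid is not uniform")
        return 1000.0 / dt[0]


@dataclass
class SizeTuningCurve:
    """Per-channel mean response as a function of disk diameter."""

    diameters: np.ndarray
    response: np.ndarray
    rf_center_diameter: float
    si: float = np.nan
    included: bool = True
    suppression_defined: bool = True
    channel: str = ""


@dataclass
class CrossCorrelogram:
    """Normalized cross-correlation over signed lags.

    ``cc`` is scaled so that the zero-lag autocorrelation of either input
    equals 1; the peak coefficient is the signed maximum within the
    ``peak_window_ms`` interval around zero lag.
    """

    lags_ms: np.ndarray
    cc: np.ndarray
    peak_coefficient: float
    peak_lag_ms: float
    fs_common: float = 150.0
    inverted_rt: bool = False
    peak_window_ms: float = 125.0


@dataclass
class DPrimeResult:
    """Target-response sensitivity: standardized peak-vs-baseline contrast."""

    mu_p: float
    mu_b: float
    sigma_p: float
    sigma_b: float
    dprime: float
    condition: str = ""
    n_trials: int = 0
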