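"""Synthetic neural, oculomotor and behavioral data generators.

The pipeline analyzes trial-structured recordings from a center-surround
competition paradigm: a disk stimulus appears in the receptive fields of
one neuronal pool at t = 0 s, flanking bars appear in the surround
(driving a neighboring pool) 0.5 s later, and the two mutually inhibiting
pools settle into an anti-phase theta (~3-6 Hz) oscillation of their
multi-unit activity (MUA).  During the attention task a luminance target
appears on one of the two stimuli at a randomized delay on a 20-point,
37.5 ms grid spanning 750 ms after flanker onset; reaction times (RTs)
inherit the neural rhythm, anti-phase between the two target locations.

Two MUA generators are provided:

* ``phenomenological`` (default): transients, sustained responses and the
  theta oscillation are written down directly, with exactly controlled
  frequency and phase -- the reference for parameter-recovery tests.
* ``mechanistic``: a two-pool Wilson-Cowan-style rate model with mutual
  inhibition and subtractive spike-rate adaptation; the rhythm emerges
  from the competition dynamics and disappears when the inhibitory
  coupling is removed.

Every generator draws all randomness from ``SimulationParams.seed`` so
identical parameters yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import EyeTrace, MicrosaccadeEvent, TrialTensor

__all__ = [
    "SimulationParams",
    "SyntheticSession",
    "simulate_competition_mua",
    "simulate_broadband",
    "simulate_eye_trace",
    "simulate_attention_session",
    "simulate_passive_session",
]

#: stimulus diameters (visual degrees) of the size-tuning protocol
SIZE_TUNING_DIAMETERS = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 7.0)


@dataclass
class SimulationParams:
    """All knobs of the synthetic generators, with task-calibrated defaults.

    Defaults mirror the recorded paradigm: 500 Hz MUA and eye sampling,
    1 s fixation baseline, 0.5 s between first (disk) and second (flanker)
    stimulus onset, a 4.1 Hz neural theta rhythm, ~1 Hz microsaccades,
    ~210 ms base RT with theta-rhythmic modulation at 4.3 Hz offset by
    95 degrees between the two target locations, one-third catch trials,
    and a 20 x 37.5 ms target-delay grid covering 750 ms.
    """

    seed: int = 0
    model: str = "phenomenological"  # or "mechanistic"
    n_channels_disk: int = 8
    n_channels_bar: int = 8
    n_trials: int = 1200
    fs_mua: float = 500.0
    fs_broadband: float = 10_000.0
    t_baseline: float = 1.0
    t_stim1: float = 0.5
    t_stim2: float = 1.0
    theta_freq: float = 4.1
    theta_amp: float = 0.5
    antiphase_deg: float = 180.0
    inhibition_weight: float = 1.0
    adaptation_tau: float = 0.08
    noise_sd: float = 0.3
    sustained_amp: float = 1.0
    transient_amp: float = 1.2
    ms_rate: float = 1.0
    ms_amp_range: tuple[float, float] = (0.1, 0.5)
    ms_duration: float = 0.025
    ms_suppression: float = 0.15
    eye_noise_sd: float = 0.0025
    rt_base: float = 210.0
    rt_mod_amp: float = 30.0
    rt_mod_freq: float = 4.3
    rt_phase_offset_deg: float = 95.0
    rt_noise_sd: float = 20.0
    rt_trend_ms: float = 15.0
    mask_penalty_ms: float = 40.0
    catch_fraction: float = 1.0 / 3.0
    n_delays: int = 20
    delay_spacing: float = 37.5
    target_amp: float = 2.0
    target_coupling: float = 0.6
    target_amp_noise: float = 0.25

    def __post_init__(self) -> None:
        for name in ("fs_mua", "fs_broadband", "t_baseline", "t_stim1",
                     "t_stim2", "theta_freq", "rt_mod_freq", "delay_spacing",
                     "adaptation_tau", "rt_base", "ms_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("n_channels_disk", "n_channels_bar", "n_trials",
                     "n_delays"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 < self.catch_fraction < 1.0:
            raise ValueError("catch_fraction must lie in (0, 1)")
        if self.ms_rate < 0:
            raise ValueError("ms_rate must be nonnegative")
        if self.inhibition_weight < 0:
            raise ValueError("inhibition_weight must be nonnegative")
        if self.model not in ("phenomenological", "mechanistic"):
            raise ValueError("model must be phenomenological or mechanistic")

    @property
    def delays_ms(self) -> np.ndarray:
        """Target-delay grid in ms after flanker onset (20 x 37.5 = 750)."""
        return self.delay_spacing * np.arange(1, self.n_delays + 1)

    @property
    def trial_duration(self) -> float:
        return self.t_stim1 + self.t_stim2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ms_amp_range"] = list(self.ms_amp_range)
        return d


@dataclass
class SyntheticSession:
    """A complete simulated attention-task session with its ground truth."""

    mua: Optional[TrialTensor]
    eye: list
    rt_table: pd.DataFrame
    ground_truth: dict
    params: SimulationParams
    broadband: Optional[TrialTensor] = None


def _transient(t: np.ndarray, onset: float, amp: float,
               rise: float = 0.015, decay: float = 0.05) -> np.ndarray:
    """Stereotyped stimulus-onset transient (difference of exponentials)."""
    tt = np.clip(t - onset, 0.0, None)
    h = np.exp(-tt / decay) - np.exp(-tt / rise)
    h[t < onset] = 0.0
    peak = h.max()
    return amp * h / peak if peak > 0 else h


def _osc_gain(w: float) -> float:
    """Oscillation amplitude gain as a function of the inhibitory coupling.

    Zero coupling removes the rhythm entirely; the default coupling of 1
    yields unit gain, saturating for stronger inhibition.
    """
    return float((1.0 - np.exp(-w)) / (1.0 - np.exp(-1.0)))


def _phenomenological_rates(
    params: SimulationParams,
    t: np.ndarray,
    stim_order: str,
    freq: Optional[float] = None,
    group_phase_deg: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free disk-pool and bar-pool rate time courses for one trial.

    The pool driven by the first stimulus responds from t = 0; the pool
    driven by the second responds from t = 0.5 s.  From second-stimulus
    onset both pools oscillate at ``freq``; the first-driven pool starts
    in suppression (incoming inhibition from the newly excited pool), the
    second-driven pool in excitation, separated by ``antiphase_deg``.
    """
    f = params.theta_freq if freq is None else freq
    gain = _osc_gain(params.inhibition_weight)
    t2 = params.t_stim1
    osc_t = np.clip(t - t2, 0.0, None)
    on2 = (t >= t2).astype(float)
    if group_phase_deg is None:
        group_phase_deg = (0.0, params.antiphase_deg)
    ph1, ph2 = np.radians(group_phase_deg)

    def pool(onset: float, osc_phase: float) -> np.ndarray:
        on = (t >= onset).astype(float)
        base = params.sustained_amp * on + _transient(t, onset,
                                                     params.transient_amp)
        osc = -params.theta_amp * gain * np.cos(
            2 * np.pi * f * osc_t + osc_phase) * on2
        return base + osc

    # first-driven pool enters the oscillation at -cos(ph1) = -1
    # (suppression); the second-driven pool is offset by antiphase_deg,
    # so at the 180-degree default it starts at +1 (excitation)
    first, second = pool(0.0, ph1), pool(t2, ph2)
    if stim_order == "disk_first":
        return first, second
    if stim_order == "bar_first":
        return second, first
    raise ValueError("stim_order must be 'disk_first' or 'bar_first'")


def _mechanistic_rates(params: SimulationParams, t: np.ndarray,
                       stim_order: str) -> tuple[np.ndarray, np.ndarray]:
    """Two-pool rate model: mutual inhibition plus spike-rate adaptation.

    tau_r dr_i/dt = -r_i + [I_i(t) - w r_j - a_i]_+
    tau_a da_i/dt = -a_i + b r_i

    With both drives on, inhibition hands dominance back and forth at a
    period set mainly by the adaptation time constant; w = 0 leaves two
    uncoupled adapting pools with no sustained rhythm.
    """
    dt = 1.0 / params.fs_mua
    tau_r = 0.010
    w = 2.5 * params.inhibition_weight
    b = 2.0
    drive1 = (t >= 0.0).astype(float)
    drive2 = (t >= params.t_stim1).astype(float)
    if stim_order == "bar_first":
        drive1, drive2 = drive2, drive1
    r1 = r2 = a1 = a2 = 0.0
    out1 = np.empty_like(t)
    out2 = np.empty_like(t)
    for i in range(t.size):
        inp1 = max(drive1[i] - w * r2 - a1, 0.0)
        inp2 = max(drive2[i] - w * r1 - a2, 0.0)
        r1 += dt / tau_r * (-r1 + inp1)
        r2 += dt / tau_r * (-r2 + inp2)
        a1 += dt / params.adaptation_tau * (-a1 + b * r1)
        a2 += dt / params.adaptation_tau * (-a2 + b * r2)
        out1[i], out2[i] = r1, r2
    scale = params.sustained_amp / max(out1.max(), 1e-12)
    return out1 * scale, out2 * scale


def simulate_competition_mua(
    params: SimulationParams,
    n_trials: Optional[int] = None,
    stim_order: str = "disk_first",
    rng: Optional[np.random.Generator] = None,
) -> TrialTensor:
    """Simulate MUA rate traces for two competing channel groups.

    Returns a ``TrialTensor`` spanning ``[-t_baseline, t_stim1 + t_stim2)``
    at ``fs_mua`` with disk-group channels followed by bar-group channels.
    From second-stimulus onset both groups oscillate at ``theta_freq``
    with a ``antiphase_deg`` phase difference; the group driven by the
    first stimulus enters the oscillation through a suppression, the other
    through an excitation, and reversing ``stim_order`` swaps the roles.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if n_trials is None:
        n_trials = min(params.n_trials, 100)
    n = int(round((params.t_baseline + params.trial_duration) * params.fs_mua))
    t = -params.t_baseline + np.arange(n) / params.fs_mua
    if params.model == "mechanistic":
        disk, bar = _mechanistic_rates(params, t, stim_order)
    else:
        disk, bar = _phenomenological_rates(params, t, stim_order)
    nch = params.n_channels_disk + params.n_channels_bar
    clean = np.empty((nch, n))
    ch_gain = 1.0 + 0.1 * rng.standard_normal(nch)
    clean[: params.n_channels_disk] = ch_gain[: params.n_channels_disk, None] * disk
    clean[params.n_channels_disk:] = ch_gain[params.n_channels_disk:, None] * bar
    data = clean[:, None, :] + params.noise_sd * rng.standard_normal(
        (nch, n_trials, n))
    groups = ["disk"] * params.n_channels_disk + ["bar"] * params.n_channels_bar
    labels = [f"{g}{i}" for i, g in enumerate(groups)]
    return TrialTensor(
        data, fs=params.fs_mua, t0_offset=-params.t_baseline,
        channel_labels=labels, channel_groups=groups,
        event_times={"stim1_on": 0.0, "stim2_on": params.t_stim1},
    )


def simulate_broadband(
    mua_rate: TrialTensor,
    params: SimulationParams,
    rate_hz_per_unit: float = 60.0,
    noise_sd: float = 0.0,
    pink_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> TrialTensor:
    """Render rate traces as broadband extracellular voltage.

    Spikes are drawn from an inhomogeneous Poisson process whose rate is
    the (floored-at-zero) input scaled by ``rate_hz_per_unit``, convolved
    with a biphasic ~0.6 ms spike waveform, with optional white and 1/f
    background noise, all at ``params.fs_broadband``.
    """
    fs = params.fs_broadband
    if fs < 2000:
        raise ValueError("fs_broadband below 2 kHz: envelope extraction "
                         "(300 Hz high-pass) undefined")
    if rng is None:
        rng = np.random.default_rng(params.seed + 7)
    up = int(round(fs / mua_rate.fs))
    rate = np.clip(mua_rate.data, 0.0, None) * rate_hz_per_unit
    rate_hi = np.repeat(rate, up, axis=2)
    spikes = (rng.random(rate_hi.shape) < rate_hi / fs).astype(float)
    # biphasic spike waveform: one sine cycle over ~0.6 ms
    nwav = max(int(round(0.0006 * fs)), 2)
    wav = np.sin(2 * np.pi * np.arange(nwav) / nwav)
    from scipy.signal import fftconvolve
    bb = fftconvolve(spikes, wav[None, None, :], mode="same", axes=2)
    if noise_sd > 0:
        bb += noise_sd * rng.standard_normal(bb.shape)
    if pink_sd > 0:
        nsamp = bb.shape[2]
        white = rng.standard_normal(bb.shape)
        f = np.fft.rfftfreq(nsamp, 1 / fs)
        shaping = np.where(f > 0, 1.0 / np.sqrt(f), 0.0)
        pink = np.fft.irfft(np.fft.rfft(white, axis=2) * shaping, n=nsamp,
                            axis=2)
        std = pink.std()
        if std > 0:
            bb += pink_sd * pink / std
    return TrialTensor(bb, fs=fs, t0_offset=mua_rate.t0_offset,
                       channel_labels=list(mua_rate.channel_labels),
                       channel_groups=list(mua_rate.channel_groups),
                       event_times=dict(mua_rate.event_times))


def _minimum_jerk(n: int) -> np.ndarray:
    """Normalized minimum-jerk displacement profile, 0 -> 1 over n samples."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_eye_trace(
    params: SimulationParams,
    trial_duration: float,
    trial: int = 0,
    t0_offset: float = 0.0,
    suppression_onsets: Sequence[float] = (),
    rng: Optional[np.random.Generator] = None,
) -> tuple[EyeTrace, list[MicrosaccadeEvent]]:
    """Simulate a 500 Hz fixation eye trace with injected microsaccades.

    The trace is slow bounded drift (an Ornstein-Uhlenbeck walk) plus
    tremor noise plus microsaccades: a Poisson process at ``ms_rate``
    gated off for ``ms_suppression`` seconds after each entry of
    ``suppression_onsets`` (stimulus onsets transiently suppress
    microsaccades), each event a ~25 ms minimum-jerk displacement whose
    amplitude is drawn from ``ms_amp_range`` and whose peak velocity
    follows the main-sequence relation of the minimum-jerk profile
    (1.875 x amplitude / duration).  Gaze never leaves the 1 degree
    fixation radius.  Returns the trace and the injected ground truth.
    """
    if trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    fs = 500.0
    if rng is None:
        rng = np.random.default_rng(params.seed + 1000 + trial)
    n = int(round(trial_duration * fs))
    dt = 1.0 / fs
    # OU drift, bounded well inside the fixation window
    tau_d, sigma_d, bound = 0.5, 0.03, 0.3
    drift = np.zeros((2, n))
    steps = sigma_d * np.sqrt(dt) * rng.standard_normal((2, n))
    for i in range(1, n):
        d = drift[:, i - 1] * (1 - dt / tau_d) + steps[:, i]
        drift[:, i] = np.clip(d, -bound, bound)
    pos = drift + params.eye_noise_sd * rng.standard_normal((2, n))

    events: list[MicrosaccadeEvent] = []
    nms = int(round(params.ms_duration * fs))
    if params.ms_rate > 0:
        t_abs = t0_offset + np.arange(n) / fs
        gate = np.ones(n, dtype=bool)
        for on in suppression_onsets:
            gate &= ~((t_abs >= on) & (t_abs < on + params.ms_suppression))
        # candidate Poisson onsets, thinned to a 100 ms minimum separation
        expect = params.ms_rate * trial_duration
        n_cand = rng.poisson(expect)
        onsets = np.sort(rng.random(n_cand) * (trial_duration - params.ms_duration))
        kept: list[float] = []
        for on in onsets:
            i0 = int(round(on * fs))
            if i0 >= n or not gate[i0]:
                continue
            if kept and on - kept[-1] < 0.1:
                continue
            kept.append(on)
        for on in kept:
            i0 = int(round(on * fs))
            i1 = min(i0 + nms, n)
            amp = rng.uniform(*params.ms_amp_range)
            ang = rng.uniform(0.0, 2 * np.pi)
            step_vec = amp * np.array([np.cos(ang), np.sin(ang)])
            # corrective bias: flip direction if the jump would leave fixation
            if np.linalg.norm(pos[:, i0] + step_vec) > 0.8:
                step_vec = -step_vec
            prof = _minimum_jerk(i1 - i0)
            pos[:, i0:i1] += step_vec[:, None] * prof[None, :]
            pos[:, i1:] += step_vec[:, None]
            events.append(MicrosaccadeEvent(
                trial=trial,
                onset=t0_offset + on,
                offset=t0_offset + on + (i1 - i0 - 1) * dt,
                amplitude=float(amp),
                peak_velocity=float(1.875 * amp / params.ms_duration),
            ))
    # hard fixation bound (1 degree radius)
    r = np.hypot(pos[0], pos[1])
    over = r > 1.0
    if over.any():
        pos[:, over] *= (1.0 / r[over])[None, :]
    trace = EyeTrace(trial=trial, x=pos[0], y=pos[1], fs=fs,
                     t0_offset=t0_offset)
    return trace, events


def _trial_schedule(params: SimulationParams,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Balanced trial list: catch trials plus detection trials covering the
    delay grid for both target locations."""
    n_catch = int(round(params.n_trials * params.catch_fraction))
    n_detect = params.n_trials - n_catch
    per_cell = n_detect // (2 * params.n_delays)
    if per_cell < 1:
        raise ValueError(
            f"n_trials={params.n_trials} cannot place >=1 detection trial "
            f"per delay per location")
    conds, delays = [], []
    for loc in ("center", "flanker"):
        for d in params.delays_ms:
            conds += [loc] * per_cell
            delays += [d] * per_cell
    rest = n_detect - len(conds)
    extra = rng.choice(len(conds), size=rest, replace=False) if rest else []
    for i in extra:
        conds.append(conds[i])
        delays.append(delays[i])
    conds += ["catch"] * n_catch
    delays += [np.nan] * n_catch
    order = rng.permutation(len(conds))
    return pd.DataFrame({
        "trial": np.arange(len(conds)),
        "condition": np.asarray(conds, dtype=object)[order],
        "target_delay_ms": np.asarray(delays, dtype=float)[order],
    })


def simulate_attention_session(
    params: SimulationParams,
    with_mua: bool = True,
    with_eye: bool = True,
) -> SyntheticSession:
    """Simulate a full distributed-attention session.

    One underlying rhythm at ``rt_mod_freq`` drives everything after
    flanker onset: the anti-phase MUA oscillation of disk- and bar-group
    channels, the trial-by-trial amplitude of the target-evoked MUA
    response (large when the target falls on a rhythm peak of its
    location), and the RTs, which are negatively coupled to that
    amplitude.  The center and flanker locations are offset by
    ``rt_phase_offset_deg``.  Delays inside the 0-250 ms masking period
    incur ``mask_penalty_ms`` and degraded accuracy.  Catch trials
    (``catch_fraction`` of all trials) carry full-length MUA and no RT.
    """
    rng = np.random.default_rng(params.seed)
    table = _trial_schedule(params, rng)
    f = params.rt_mod_freq
    phase_loc = {"center": 0.0, "flanker": np.radians(params.rt_phase_offset_deg)}
    d_s = table["target_delay_ms"].to_numpy() / 1000.0
    loc_phase = np.array([phase_loc.get(c, np.nan) for c in table["condition"]])

    # rhythm value at each trial's target time; +1 = location's MUA peak
    osc_val = -np.cos(2 * np.pi * f * d_s + loc_phase)
    is_detect = table["condition"] != "catch"
    masked = is_detect & (table["target_delay_ms"] < 250.0)

    rt = (params.rt_base
          + params.rt_trend_ms * ((d_s - 0.375) / 0.375) ** 2
          - params.rt_mod_amp * osc_val
          + params.rt_noise_sd * rng.standard_normal(len(table)))
    rt[masked] += params.mask_penalty_ms
    rt[~is_detect] = np.nan

    p_correct = np.where(masked, 0.75, 0.95)
    correct = rng.random(len(table)) < p_correct
    correct[~is_detect] = rng.random((~is_detect).sum()) < 0.97
    rt[is_detect & ~correct] = np.nan
    table["rt_ms"] = rt
    table["correct"] = correct
    table["session"] = 0

    amp_target = params.target_amp * np.clip(
        1.0 + params.target_coupling * osc_val
        + params.target_amp_noise * rng.standard_normal(len(table)),
        0.0, None)
    amp_target[~is_detect] = np.nan

    ground_truth: dict = {
        "rhythm_freq_hz": f,
        "phase_center_deg": 0.0,
        "phase_flanker_deg": params.rt_phase_offset_deg,
        "target_amplitude": amp_target,
        "osc_value_at_target": osc_val,
        "ms_events": [],
    }

    mua = None
    if with_mua:
        n = int(round((params.t_baseline + params.trial_duration) * params.fs_mua))
        t = -params.t_baseline + np.arange(n) / params.fs_mua
        on1 = (t >= 0.0).astype(float)
        on2 = (t >= params.t_stim1).astype(float)
        osc_t = np.clip(t - params.t_stim1, 0.0, None)
        gain = _osc_gain(params.inhibition_weight)
        base = {
            "disk": (params.sustained_amp * on1
                     + _transient(t, 0.0, params.transient_amp)
                     - params.theta_amp * gain * on2
                     * np.cos(2 * np.pi * f * osc_t + phase_loc["center"])),
            "bar": (params.sustained_amp * on2
                    + _transient(t, params.t_stim1, params.transient_amp)
                    - params.theta_amp * gain * on2
                    * np.cos(2 * np.pi * f * osc_t + phase_loc["flanker"])),
        }
        nch = params.n_channels_disk + params.n_channels_bar
        groups = (["disk"] * params.n_channels_disk
                  + ["bar"] * params.n_channels_bar)
        data = np.empty((nch, len(table), n))
        ch_gain = 1.0 + 0.1 * rng.standard_normal(nch)
        for ci, g in enumerate(groups):
            data[ci] = ch_gain[ci] * base[g][None, :]
        # target-evoked transient on the target location's channels
        t_target = params.t_stim1 + d_s
        evoked_latency, evoked_sd = 0.06, 0.02
        for ti in range(len(table)):
            cond = table["condition"].iloc[ti]
            if cond == "catch":
                continue
            g = "disk" if cond == "center" else "bar"
            bump = amp_target[ti] * np.exp(
                -0.5 * ((t - t_target[ti] - evoked_latency) / evoked_sd) ** 2)
            for ci in np.flatnonzero(np.asarray(groups) == g):
                data[ci, ti] += ch_gain[ci] * bump
        data += params.noise_sd * rng.standard_normal(data.shape)
        mua = TrialTensor(
            data, fs=params.fs_mua, t0_offset=-params.t_baseline,
            channel_labels=[f"{g}{i}" for i, g in enumerate(groups)],
            channel_groups=groups,
            event_times={"stim1_on": 0.0, "stim2_on": params.t_stim1,
                         "target_on": np.where(is_detect,
                                               params.t_stim1 + d_s, np.nan)},
        )

    eye: list[EyeTrace] = []
    if with_eye:
        dur = params.t_baseline + params.trial_duration
        ms_all: list[MicrosaccadeEvent] = []
        for ti in range(len(table)):
            trace, evs = simulate_eye_trace(
                params, dur, trial=ti, t0_offset=-params.t_baseline,
                suppression_onsets=(0.0, params.t_stim1),
                rng=np.random.default_rng(
                    np.random.SeedSequence([params.seed, 77, ti])),
            )
            eye.append(trace)
            ms_all.extend(evs)
        ground_truth["ms_events"] = ms_all

    return SyntheticSession(mua=mua, eye=eye, rt_table=table,
                            ground_truth=ground_truth, params=params)


def _size_tuning_response(diameter: float, rf_center: float = 2.0,
                          suppression: float = 0.90) -> float:
    """Ratio-of-Gaussians size-tuning curve peaking at ``rf_center``."""
    sc = rf_center / 2.0
    ss = 2.5 * sc
    exc = 1.0 - np.exp(-(diameter / (np.sqrt(2) * sc)) ** 2)
    inh = 1.0 - np.exp(-(diameter / (np.sqrt(2) * ss)) ** 2)
    return float(exc / (1.0 + (suppression / (1 - suppression)) * inh)
                 * (1.0 + suppression / (1 - suppression)))


def simulate_passive_session(
    params: SimulationParams,
    n_trials_per_condition: int = 30,
    diameters: Sequence[float] = SIZE_TUNING_DIAMETERS,
) -> dict:
    """Simulate the passive-viewing experiments.

    Returns a dict with three parts:

    * ``size_tuning``: TrialTensor + stimulus table for the disk-diameter
      protocol (responses peak at the 2 degree RF center, then are
      surround-suppressed).
    * conditions ``disk_small``, ``disk_large``, ``disk_annulus``:
      TrialTensors for a 2 degree disk, a 6 degree disk and a 2 degree
      disk with a 4-6 degree annulus; only the disk-annulus condition
      carries the theta oscillation (center and surround driven by
      separate stimuli), the large disk responds weakly (surround
      suppression) and arrhythmically.
    * ``eye``: per (condition, trial) eye traces with ground-truth
      microsaccades, statistically independent of the MUA rhythm.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.fs_mua
    dur = params.t_baseline + params.trial_duration
    n = int(round(dur * fs))
    t = -params.t_baseline + np.arange(n) / fs
    on1 = (t >= 0.0).astype(float)
    nch = params.n_channels_disk
    ch_gain = 1.0 + 0.1 * rng.standard_normal(nch)

    # size-tuning block: single stimulus, amplitude set by the tuning curve
    dia_per_trial = np.tile(np.asarray(diameters, float), n_trials_per_condition)
    st_data = np.empty((nch, dia_per_trial.size, n))
    for ti, dia in enumerate(dia_per_trial):
        amp = params.sustained_amp * _size_tuning_response(dia)
        clean = amp * on1 + _transient(t, 0.0, params.transient_amp * amp)
        st_data[:, ti, :] = ch_gain[:, None] * clean[None, :]
    st_data += params.noise_sd * rng.standard_normal(st_data.shape)
    size_tuning = {
        "mua": TrialTensor(st_data, fs=fs, t0_offset=-params.t_baseline,
                           channel_groups=["disk"] * nch,
                           event_times={"stim1_on": 0.0}),
        "stim_table": pd.DataFrame({"trial": np.arange(dia_per_trial.size),
                                    "diameter_deg": dia_per_trial}),
    }

    # condition block: both stimuli on for the full 1.5 s (simultaneous)
    gain = _osc_gain(params.inhibition_weight)
    osc = -params.theta_amp * gain * np.cos(
        2 * np.pi * params.theta_freq * np.clip(t, 0, None)) * on1
    cond_clean = {
        "disk_small": params.sustained_amp * on1,
        "disk_large": 0.4 * params.sustained_amp * on1,
        "disk_annulus": 0.7 * params.sustained_amp * on1 + osc,
    }
    out: dict = {"size_tuning": size_tuning, "eye": {}}
    for cond, clean in cond_clean.items():
        full = clean + _transient(t, 0.0, params.transient_amp
                                  * (0.4 if cond == "disk_large" else 1.0))
        data = (ch_gain[:, None, None] * full[None, None, :]
                + params.noise_sd * rng.standard_normal(
                    (nch, n_trials_per_condition, n)))
        out[cond] = TrialTensor(data, fs=fs, t0_offset=-params.t_baseline,
                                channel_groups=["disk"] * nch,
                                event_times={"stim1_on": 0.0})
        cond_id = list(cond_clean).index(cond)
        traces, events = [], []
        for ti in range(n_trials_per_condition):
            tr, evs = simulate_eye_trace(
                params, dur, trial=ti, t0_offset=-params.t_baseline,
                suppression_onsets=(0.0,),
                rng=np.random.default_rng(
                    np.random.SeedSequence([params.seed, 200 + cond_id, ti])))
            traces.append(tr)
            events.extend(evs)
        out["eye"][cond] = {"traces": traces, "ms_events": events}
    return out
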