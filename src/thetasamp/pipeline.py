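"""End-to-end orchestration of the passive-viewing and attention scenarios.

Both runners consume a synthetic session (or user-supplied tables in the
same layout), execute every analysis stage with the paradigm's default
parameters, and return a report dict of tidy DataFrames plus the
resolved configuration; ``write_report`` serializes everything as CSV
and JSON so a run is reproducible from its emitted config and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, coupling, microsaccades, spectral, tuning
from .containers import TrialTensor
from .mua import trial_average, zscore_mua
from .simulate import (SimulationParams, simulate_attention_session,
                       simulate_passive_session)

__all__ = ["PipelineConfig", "run_passive_viewing", "run_attention",
           "write_report"]


@dataclass
class PipelineConfig:
    """Resolved parameters of a pipeline run.

    Defaults equal the paradigm's stated analysis constants: the
    0.3-1.0 s sustained window, 5 s spectral padding, the 3-9 Hz theta
    band, a 5 SD microsaccade threshold with 0.18 s kernel bandwidth,
    5000 surrogates, 150 Hz common resampling with +/-450 / +/-125 ms
    lag windows, the 0-250 ms delay mask, and the 60 ms d' baseline
    precedence.
    """

    scenario: str = "attention"
    seed: int = 0
    analysis_window: tuple[float, float] = (0.3, 1.0)
    baseline_window: tuple[float, float] = (-0.7, 0.0)
    pad_to: float = 5.0
    theta_band: tuple[float, float] = (3.0, 9.0)
    ms_lambda_sd: float = 5.0
    ms_kernel_bw: float = 0.18
    n_surrogates: int = 5000
    n_surrogates_ccg: int = 500
    mask_ms: float = 250.0
    sim: SimulationParams = field(default_factory=SimulationParams)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in d and isinstance(d["sim"], dict):
            sim_known = {f.name for f in fields(SimulationParams)}
            bad = set(d["sim"]) - sim_known
            if bad:
                raise ValueError(f"unknown sim keys: {sorted(bad)}")
            if "ms_amp_range" in d["sim"]:
                d["sim"]["ms_amp_range"] = tuple(d["sim"]["ms_amp_range"])
            d["sim"] = SimulationParams(**d["sim"])
        for key in ("analysis_window", "baseline_window", "theta_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d


def _condition_spectra(cfg: PipelineConfig, session: dict) -> pd.DataFrame:
    rows = []
    for cond in ("disk_small", "disk_large", "disk_annulus"):
        tens: TrialTensor = session[cond]
        z, _ = zscore_mua(tens, cfg.baseline_window)
        for c in range(z.n_channels):
            spec = spectral.powerspectrum(
                z.data[c], z.fs, window=cfg.analysis_window,
                pad_to=cfg.pad_to, t0=z.t0_offset, detrend_mean=True)
            pk_f, pk_p = spectral.find_theta_peak(spec, cfg.theta_band)
            rows.append({
                "condition": cond, "channel": z.channel_labels[c],
                "theta_power": spec.power[spec.band(*cfg.theta_band)].mean(),
                "peak_freq_hz": pk_f, "peak_power": pk_p,
            })
    return pd.DataFrame(rows)


def run_passive_viewing(cfg: PipelineConfig,
                        session: Optional[dict] = None) -> dict:
    """Passive-fixation analyses: size tuning, condition spectra, theta
    index, microsaccade battery, and channel-group phase differences."""
    params = cfg.sim
    if session is None:
        session = simulate_passive_session(params)

    report: dict = {"config": cfg.to_dict(), "scenario": "passive_viewing"}

    # --- size tuning and suppression index
    st = session["size_tuning"]
    z, _ = zscore_mua(st["mua"], cfg.baseline_window)
    curves = tuning.size_tuning(z, st["stim_table"]["diameter_deg"],
                                cfg.analysis_window, cfg.baseline_window)
    report["size_tuning"] = pd.DataFrame([{
        "channel": cv.channel, "rf_center_deg": cv.rf_center_diameter,
        "si": cv.si, "included": cv.included,
        "suppression_defined": cv.suppression_defined} for cv in curves])

    # --- condition powerspectra and theta index
    spectra = _condition_spectra(cfg, session)
    report["condition_spectra"] = spectra
    piv = spectra.pivot(index="channel", columns="condition",
                        values="theta_power")
    report["theta_index"] = pd.DataFrame({
        "channel": piv.index,
        "ti_annulus_vs_large": [
            tuning.theta_index(a, l) for a, l in zip(
                piv["disk_annulus"], piv["disk_large"])],
    })

    # --- microsaccade battery on the rhythmic condition
    eye_info = session["eye"]["disk_annulus"]
    detected = []
    windows = {}
    for tr in eye_info["traces"]:
        detected.extend(microsaccades.detect_microsaccades(
            tr, lambda_sd=cfg.ms_lambda_sd))
        windows[tr.trial] = cfg.analysis_window
    rate = microsaccades.ms_rate(detected, windows)
    onsets = np.array([e.onset for e in detected
                       if cfg.analysis_window[0] <= e.onset < cfg.analysis_window[1]])
    _, dens, dens_spec = microsaccades.ms_density(
        onsets, cfg.analysis_window, bandwidth=cfg.ms_kernel_bw)
    za, _ = zscore_mua(session["disk_annulus"], cfg.baseline_window)
    trig = (microsaccades.ms_triggered_average(detected, za, seed=cfg.seed)
            if detected else None)
    cmp_ms = microsaccades.compare_theta_by_ms(
        za, detected, cfg.analysis_window, cfg.theta_band, cfg.pad_to)
    report["microsaccades"] = {
        "n_detected": len(detected), "rate_hz": rate,
        "n_ground_truth": len(eye_info["ms_events"]),
        "density_peak_freq": (spectral.find_theta_peak(
            dens_spec, (0.5, 9.0))[0] if dens_spec is not None else np.nan),
        "triggered_n_used": trig["n_used"] if trig else 0,
        "theta_with_vs_without_p": cmp_ms["p_value"],
        "theta_comparison_skipped": cmp_ms["skipped"],
    }

    # --- channel-group phase relationship (on the condition with rhythm)
    disk_idx = za.group_channels("disk")
    psth, _ = trial_average(za)
    seg = slice(*[za.window_indices(cfg.analysis_window).start,
                  za.window_indices(cfg.analysis_window).stop])
    if disk_idx.size >= 2:
        lag_ms, lag_deg = coupling.mua_mua_lag(
            psth[disk_idx[0], seg], psth[disk_idx[1], seg], za.fs)
        report["within_group_lag"] = {"lag_ms": lag_ms, "lag_deg": lag_deg}
    return report


def run_attention(cfg: PipelineConfig, session=None) -> dict:
    """Attention-task analyses: RT courses and spectra, phase difference,
    catch-trial MUA spectra, RT-MUA cross-correlation and its
    rhythmicity, and d' for fast- vs slow-RT target delays."""
    params = cfg.sim
    if session is None:
        session = simulate_attention_session(params)
    report: dict = {"config": cfg.to_dict(), "scenario": "attention"}

    table = session.rt_table
    series = {}
    for loc in ("center", "flanker"):
        raw = behavior.build_rt_timecourse(table, loc,
                                           masked_range=(0.0, cfg.mask_ms))
        det = behavior.detrend_rt(raw)
        sur = behavior.rt_spectrum(det, n_surrogates=cfg.n_surrogates,
                                   seed=cfg.seed, pad_to=cfg.pad_to)
        band = sur.freqs[np.argmax(np.where(
            (sur.freqs >= cfg.theta_band[0]) & (sur.freqs <= cfg.theta_band[1]),
            sur.observed_power, -np.inf))]
        series[loc] = {"raw": raw, "detrended": det, "surrogate": sur,
                       "peak_freq": float(band),
                       "significant": sur.significant(cfg.theta_band)}
    report["rt"] = {
        loc: {"peak_freq_hz": series[loc]["peak_freq"],
              "significant": series[loc]["significant"]}
        for loc in series}
    f_ref = series["center"]["peak_freq"]
    report["rt"]["phase_difference_deg"] = behavior.rt_phase_difference(
        series["center"]["detrended"], series["flanker"]["detrended"], f_ref)
    report["rt"]["phase_difference_ms_at_4hz"] = coupling.phase_time_convert(
        report["rt"]["phase_difference_deg"], 4.0, "deg_to_ms")

    if session.mua is None:
        return report

    z, _ = zscore_mua(session.mua, cfg.baseline_window)
    catch = np.flatnonzero((table["condition"] == "catch").to_numpy())
    psth, _ = trial_average(z, catch)

    # catch-trial MUA spectra
    rows = []
    for c in range(z.n_channels):
        spec = spectral.powerspectrum(
            z.data[c][catch], z.fs, window=cfg.analysis_window,
            pad_to=cfg.pad_to, t0=z.t0_offset, detrend_mean=True)
        pk_f, _ = spectral.find_theta_peak(spec, cfg.theta_band)
        rows.append({"channel": z.channel_labels[c],
                     "group": z.channel_groups[c],
                     "theta_peak_hz": pk_f})
    report["catch_mua"] = pd.DataFrame(rows)

    # RT-MUA cross-correlation per channel (disk channels vs center RT)
    det_center = series["center"]["detrended"]
    cc_rows = []
    for c in z.group_channels("disk"):
        ccg = coupling.rt_mua_crosscorrelation(
            det_center, psth[c], z.fs, z.t0_offset)
        sur = coupling.ccg_rhythmicity(
            det_center, psth[c], z.fs, z.t0_offset,
            n_surrogates=cfg.n_surrogates_ccg, seed=cfg.seed + int(c))
        pk = sur.freqs[np.argmax(np.where(
            (sur.freqs >= cfg.theta_band[0]) & (sur.freqs <= cfg.theta_band[1]),
            sur.observed_power, -np.inf))]
        cc_rows.append({
            "channel": z.channel_labels[c],
            "peak_coefficient": ccg.peak_coefficient,
            "peak_lag_ms": ccg.peak_lag_ms,
            "ccg_theta_peak_hz": float(pk),
            "ccg_theta_significant": sur.significant(cfg.theta_band),
        })
    report["rt_mua_ccg"] = pd.DataFrame(cc_rows)

    # d' for fast- vs slow-RT delay conditions (center target, disk group)
    peaks, troughs = behavior.rt_peak_trough_delays(det_center)
    cond_trials = {
        "rt_peak": peaks, "rt_trough": troughs}
    d_rows = []
    for cond, delays in cond_trials.items():
        sel = np.flatnonzero(
            (table["condition"] == "center").to_numpy()
            & table["correct"].to_numpy()
            & np.isin(table["target_delay_ms"].to_numpy(), delays))
        for c in z.group_channels("disk"):
            res = coupling.dprime_target_response(z, int(c), sel, cond)
            d_rows.append({"channel": z.channel_labels[c], "condition": cond,
                           "mu_p": res.mu_p, "mu_b": res.mu_b,
                           "sigma_p": res.sigma_p, "sigma_b": res.sigma_b,
                           "dprime": res.dprime, "n_trials": res.n_trials})
    report["dprime"] = pd.DataFrame(d_rows)
    return report


def write_report(report: dict, out_dir) -> None:
    """Serialize a report: DataFrames as CSV, everything else as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for key, val in report.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{key}.csv", index=False)
        else:
            summary[key] = val
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not serializable: {type(o)}")
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, default=_default))
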