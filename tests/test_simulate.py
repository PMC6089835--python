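"""Synthetic-data generators: determinism, injected-structure recovery."""

import numpy as np
import pytest

from thetasamp import coupling, mua, spectral
from thetasamp.simulate import (SimulationParams, simulate_attention_session,
                                simulate_broadband, simulate_competition_mua,
                                simulate_eye_trace)

#: analysis window 0.3-1.0 s after second-stimulus onset (the epoch with
#: the oscillation), in absolute trial time
OSC_WINDOW = (0.8, 1.5)


def group_power_spectrum(tens, group, window=OSC_WINDOW, band=(3, 9)):
    """Average per-channel spectra of the trial-averaged MUA for a group.

    Power is averaged across channels (anti-phase groups cancel in the
    raw signal mean, not in power).
    """
    idx = tens.group_channels(group)
    specs = []
    for c in idx:
        avg = tens.data[c].mean(axis=0)
        specs.append(spectral.powerspectrum(
            avg, tens.fs, window=window, pad_to=5.0, t0=tens.t0_offset,
            detrend_mean=True))
    power = np.mean([s.power for s in specs], axis=0)
    from thetasamp.containers import SpectralResult
    return SpectralResult(specs[0].freqs, power, pad_to=5.0)


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"fs_mua": 0.0}, {"n_trials": 0}, {"catch_fraction": 1.0},
        {"ms_rate": -1.0}, {"t_baseline": -0.5}, {"model": "biophysical"},
    ])
    def test_invalid_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**kwargs)

    def test_delay_grid_spans_750ms(self):
        p = SimulationParams()
        assert p.delays_ms.size == 20
        assert p.delays_ms[-1] == pytest.approx(750.0)
        assert np.allclose(np.diff(p.delays_ms), 37.5)


class TestCompetitionMua:
    def test_deterministic_given_seed(self):
        p = SimulationParams(seed=9, n_trials=5)
        a = simulate_competition_mua(p, n_trials=5)
        b = simulate_competition_mua(p, n_trials=5)
        assert np.array_equal(a.data, b.data)

    def test_injected_frequency_recovered(self):
        p = SimulationParams(seed=10, theta_freq=4.1)
        tens = simulate_competition_mua(p, n_trials=60)
        spec = group_power_spectrum(tens, "disk")
        f, _ = spectral.find_theta_peak(spec)
        assert f == pytest.approx(4.1, abs=0.25)

    def test_no_inhibition_no_rhythm(self):
        p0 = SimulationParams(seed=12, inhibition_weight=0.0)
        p1 = SimulationParams(seed=12)
        t0 = simulate_competition_mua(p0, n_trials=40)
        t1 = simulate_competition_mua(p1, n_trials=40)
        band = lambda tens: group_power_spectrum(tens, "disk")  # noqa: E731
        s0, s1 = band(t0), band(t1)
        m = s0.band(3, 9)
        assert s0.power[m].mean() < 0.5 * s1.power[m].mean()

    def test_antiphase_between_groups(self):
        p = SimulationParams(seed=13)
        tens = simulate_competition_mua(p, n_trials=60)
        d = tens.data[tens.group_channels("disk")].mean(axis=(0, 1))
        b = tens.data[tens.group_channels("bar")].mean(axis=(0, 1))
        seg = tens.window_indices((0.6, 1.5))
        _, lag_deg = coupling.mua_mua_lag(d[seg], b[seg], tens.fs)
        assert 90.0 <= abs(lag_deg) <= 180.0

    def test_reversed_order_reverses_initial_polarity(self):
        p = SimulationParams(seed=14, noise_sd=0.0)
        fwd = simulate_competition_mua(p, n_trials=1, stim_order="disk_first")
        rev = simulate_competition_mua(p, n_trials=1, stim_order="bar_first")
        # disk-group deflection just after second-stimulus onset:
        # suppression when the disk came first, excitation when second
        seg = slice(*[fwd.window_indices((0.5, 0.56)).start,
                      fwd.window_indices((0.5, 0.56)).stop])
        disk = fwd.group_channels("disk")[0]
        sustained = p.sustained_amp
        assert fwd.data[disk, 0, seg].mean() < sustained
        assert rev.data[disk, 0, seg].mean() > 0.5 * sustained

    def test_mechanistic_model_oscillates_only_with_inhibition(self):
        pm = SimulationParams(seed=15, model="mechanistic", n_trials=10)
        pm0 = SimulationParams(seed=15, model="mechanistic", n_trials=10,
                               inhibition_weight=0.0)
        t1 = simulate_competition_mua(pm, n_trials=10)
        t0 = simulate_competition_mua(pm0, n_trials=10)
        s1 = group_power_spectrum(t1, "disk")
        s0 = group_power_spectrum(t0, "disk")
        m = s1.band(3, 9)
        assert s1.power[m].mean() > 10 * s0.power[m].mean()
        f, _ = spectral.find_theta_peak(s1)
        assert 3.0 <= f <= 6.0


class TestBroadband:
    def test_zero_rate_zero_noise_all_zero(self):
        p = SimulationParams(seed=16, n_channels_disk=1, n_channels_bar=1)
        rate = simulate_competition_mua(p, n_trials=1)
        rate.data[:] = 0.0
        bb = simulate_broadband(rate, p)
        assert np.allclose(bb.data, 0.0)

    def test_envelope_scales_with_rate(self):
        p = SimulationParams(seed=17)
        base = simulate_competition_mua(
            SimulationParams(seed=17, n_channels_disk=1, n_channels_bar=1,
                             noise_sd=0.0), n_trials=2)
        base.data[:] = 1.0
        double = simulate_competition_mua(
            SimulationParams(seed=17, n_channels_disk=1, n_channels_bar=1,
                             noise_sd=0.0), n_trials=2)
        double.data[:] = 2.0
        rng_a = np.random.default_rng(5)
        rng_b = np.random.default_rng(6)
        e1 = mua.extract_mua(simulate_broadband(base, p, rng=rng_a)).data
        e2 = mua.extract_mua(simulate_broadband(double, p, rng=rng_b)).data
        ratio = e2.mean() / e1.mean()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_modulated_rate_recovered_through_envelope(self):
        p = SimulationParams(seed=18, n_channels_disk=1, n_channels_bar=1,
                             noise_sd=0.0)
        rate = simulate_competition_mua(p, n_trials=30)
        t = rate.times
        rate.data[:] = 1.0 + 0.8 * np.sin(2 * np.pi * 4.0 * t)[None, None, :]
        env = mua.extract_mua(simulate_broadband(rate, p,
                                                 rate_hz_per_unit=120.0))
        avg = env.data[0].mean(axis=0)
        spec = spectral.powerspectrum(avg, env.fs, window=(-0.5, 1.4),
                                      pad_to=5.0, t0=env.t0_offset,
                                      detrend_mean=True)
        f, _ = spectral.find_theta_peak(spec, (2, 8))
        assert f == pytest.approx(4.0, abs=0.3)

    def test_low_sampling_rate_rejected(self):
        p = SimulationParams(seed=19, fs_broadband=1000.0)
        rate = simulate_competition_mua(p, n_trials=1)
        with pytest.raises(ValueError):
            simulate_broadband(rate, p)


class TestEyeTrace:
    def test_zero_rate_no_events(self):
        p = SimulationParams(seed=20, ms_rate=0.0)
        trace, events = simulate_eye_trace(p, 1.5)
        assert events == []

    def test_trace_bounded_by_fixation_radius(self):
        p = SimulationParams(seed=21)
        for tr in range(10):
            trace, _ = simulate_eye_trace(p, 3.0, trial=tr)
            assert np.all(np.hypot(trace.x, trace.y) <= 1.0 + 1e-9)

    def test_negative_duration_raises(self):
        with pytest.raises(ValueError):
            simulate_eye_trace(SimulationParams(), -1.0)

    def test_ground_truth_events_within_trial(self):
        p = SimulationParams(seed=22)
        trace, events = simulate_eye_trace(p, 2.0, t0_offset=-1.0)
        for ev in events:
            assert -1.0 <= ev.onset < ev.offset <= 1.0 + 1e-9

    def test_suppression_window_blocks_events(self):
        p = SimulationParams(seed=23, ms_rate=3.0)
        onsets = []
        for tr in range(40):
            _, evs = simulate_eye_trace(p, 2.0, trial=tr, t0_offset=-1.0,
                                        suppression_onsets=(0.0,))
            onsets += [e.onset for e in evs]
        onsets = np.asarray(onsets)
        assert not np.any((onsets >= 0.0) & (onsets < 0.15))


class TestAttentionSession:
    def test_deterministic(self):
        p = SimulationParams(seed=24, n_trials=120, n_channels_disk=2,
                             n_channels_bar=2)
        a = simulate_attention_session(p, with_eye=False)
        b = simulate_attention_session(p, with_eye=False)
        assert a.rt_table.equals(b.rt_table)
        assert np.array_equal(a.mua.data, b.mua.data)

    def test_catch_trials_have_no_target_or_rt(self):
        p = SimulationParams(seed=25, n_trials=120)
        sess = simulate_attention_session(p, with_mua=False, with_eye=False)
        catch = sess.rt_table[sess.rt_table["condition"] == "catch"]
        assert len(catch) == pytest.approx(40, abs=1)
        assert catch["target_delay_ms"].isna().all()
        assert catch["rt_ms"].isna().all()

    def test_delay_grid_fully_covered(self):
        p = SimulationParams(seed=26, n_trials=120)
        sess = simulate_attention_session(p, with_mua=False, with_eye=False)
        det = sess.rt_table.dropna(subset=["target_delay_ms"])
        for loc in ("center", "flanker"):
            covered = det[det["condition"] == loc]["target_delay_ms"].unique()
            assert len(covered) == 20

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            simulate_attention_session(
                SimulationParams(seed=27, n_trials=30), with_mua=False,
                with_eye=False)

    def test_masked_delays_carry_penalty(self):
        p = SimulationParams(seed=28, rt_noise_sd=1e-6, rt_mod_amp=0.0,
                             rt_trend_ms=0.0, n_trials=240)
        sess = simulate_attention_session(p, with_mua=False, with_eye=False)
        det = sess.rt_table.dropna(subset=["rt_ms"])
        masked = det[det["target_delay_ms"] < 250]["rt_ms"].mean()
        clear = det[det["target_delay_ms"] >= 250]["rt_ms"].mean()
        assert masked - clear == pytest.approx(p.mask_penalty_ms, abs=1.0)

    def test_masked_delays_have_lower_accuracy(self):
        p = SimulationParams(seed=29, n_trials=1200)
        sess = simulate_attention_session(p, with_mua=False, with_eye=False)
        det = sess.rt_table[sess.rt_table["condition"] != "catch"]
        acc_masked = det[det["target_delay_ms"] < 250]["correct"].mean()
        acc_clear = det[det["target_delay_ms"] >= 250]["correct"].mean()
        assert acc_masked < acc_clear
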