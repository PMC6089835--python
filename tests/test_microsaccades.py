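"""Velocity-space microsaccade detection and downstream summaries."""

import numpy as np
import pytest

from thetasamp import microsaccades as ms
from thetasamp.containers import EyeTrace, MicrosaccadeEvent, TrialTensor
from thetasamp.simulate import SimulationParams, simulate_eye_trace

FS = 500.0


def make_trace(x, y, trial=0, t0=0.0):
    return EyeTrace(trial=trial, x=x, y=y, fs=FS, t0_offset=t0)


def trace_with_ms(onset_s=0.5, amp=0.5, dur_s=0.025, total_s=1.5,
                  noise=0.002, seed=0, angle=0.0):
    rng = np.random.default_rng(seed)
    n = int(total_s * FS)
    x = noise * rng.standard_normal(n)
    y = noise * rng.standard_normal(n)
    i0 = int(onset_s * FS)
    nms = int(dur_s * FS)
    tau = np.linspace(0, 1, nms)
    prof = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    x[i0:i0 + nms] += amp * np.cos(angle) * prof
    x[i0 + nms:] += amp * np.cos(angle)
    y[i0:i0 + nms] += amp * np.sin(angle) * prof
    y[i0 + nms:] += amp * np.sin(angle)
    return make_trace(x, y)


class TestDetector:
    def test_quiet_trace_yields_no_events(self):
        rng = np.random.default_rng(1)
        trace = make_trace(0.002 * rng.standard_normal(750),
                           0.002 * rng.standard_normal(750))
        assert ms.detect_microsaccades(trace) == []

    def test_single_injected_event_recovered(self):
        trace = trace_with_ms(onset_s=0.5, amp=0.5)
        events = ms.detect_microsaccades(trace)
        assert len(events) == 1
        assert events[0].onset == pytest.approx(0.5, abs=0.004)
        assert events[0].amplitude == pytest.approx(0.5, rel=0.2)

    def test_translation_invariance_in_time(self):
        e1 = ms.detect_microsaccades(trace_with_ms(onset_s=0.4))[0]
        e2 = ms.detect_microsaccades(trace_with_ms(onset_s=0.9))[0]
        assert (e2.onset - e1.onset) == pytest.approx(0.5, abs=0.004)

    def test_axis_swap_equivariance(self):
        trace = trace_with_ms(angle=0.7)
        swapped = make_trace(trace.y.copy(), trace.x.copy())
        e1 = ms.detect_microsaccades(trace)
        e2 = ms.detect_microsaccades(swapped)
        assert len(e1) == len(e2) == 1
        assert e1[0].onset == e2[0].onset
        assert e1[0].amplitude == pytest.approx(e2[0].amplitude, rel=1e-6)

    @pytest.mark.parametrize("lams", [(4.0, 6.0), (5.0, 8.0)])
    def test_raising_threshold_never_adds_events(self, lams):
        rng = np.random.default_rng(5)
        trace = trace_with_ms(noise=0.004, seed=3)
        lo, hi = lams
        n_lo = len(ms.detect_microsaccades(trace, lambda_sd=lo))
        n_hi = len(ms.detect_microsaccades(trace, lambda_sd=hi))
        assert n_hi <= n_lo

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            ms.detect_microsaccades(make_trace(np.zeros(3), np.zeros(3)))

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            ms.detect_microsaccades(make_trace(np.zeros(100), np.zeros(100)))

    def test_sensitivity_and_false_rate_on_synthetic_traces(self):
        params = SimulationParams(seed=21)
        hits = total = 0
        false_events = 0.0
        dur = 2.0
        n_trials = 60
        for tr in range(n_trials):
            trace, gt = simulate_eye_trace(params, dur, trial=tr)
            det = ms.detect_microsaccades(trace)
            onsets = np.array([e.onset for e in det])
            total += len(gt)
            for g in gt:
                if onsets.size and np.min(np.abs(onsets - g.onset)) < 0.02:
                    hits += 1
            matched = sum(
                1 for e in det
                if gt and min(abs(e.onset - g.onset) for g in gt) < 0.02)
            false_events += len(det) - matched
        assert hits / total >= 0.9
        assert false_events / (n_trials * dur) <= 0.1


class TestRate:
    def test_worked_example(self):
        # counts {1, 0, 2} in 0.75 s windows -> (1+0+2)/3/0.75 = 1.333 Hz
        events = [
            MicrosaccadeEvent(0, 0.1, 0.12, 0.2, 20.0),
            MicrosaccadeEvent(2, 0.2, 0.22, 0.2, 20.0),
            MicrosaccadeEvent(2, 0.5, 0.52, 0.2, 20.0),
        ]
        windows = {0: (0.0, 0.75), 1: (0.0, 0.75), 2: (0.0, 0.75)}
        assert ms.ms_rate(events, windows) == pytest.approx(4.0 / 3.0 / 1.0 * 0.75 / 0.75)
        assert ms.ms_rate(events, windows) == pytest.approx(3 / 3 / 0.75)

    def test_no_events_zero_rate(self):
        assert ms.ms_rate([], {0: (0.0, 1.0)}) == 0.0

    def test_one_event_per_second_window(self):
        events = [MicrosaccadeEvent(t, 0.5, 0.52, 0.2, 20.0) for t in range(5)]
        windows = {t: (0.0, 1.0) for t in range(5)}
        assert ms.ms_rate(events, windows) == pytest.approx(1.0)

    def test_zero_length_window_raises(self):
        with pytest.raises(ValueError):
            ms.ms_rate([], {0: (0.5, 0.5)})

    def test_poisson_rate_recovery(self):
        params = SimulationParams(seed=31)
        events = []
        windows = {}
        for tr in range(100):
            trace, _ = simulate_eye_trace(params, 1.0, trial=tr)
            events.extend(ms.detect_microsaccades(trace))
            windows[tr] = (0.05, 0.8)
        assert ms.ms_rate(events, windows) == pytest.approx(1.0, abs=0.15)


class TestDensity:
    def test_single_event_gaussian_bump(self):
        t, dens, spec = ms.ms_density(np.array([0.65]), window=(0.3, 1.0))
        assert t[np.argmax(dens)] == pytest.approx(0.65, abs=0.01)
        peak = dens.max()
        assert peak == pytest.approx(1 / (0.18 * np.sqrt(2 * np.pi)), rel=0.01)

    def test_density_integrates_to_one(self):
        t, dens, _ = ms.ms_density(np.array([0.5, 0.6, 0.9]),
                                   window=(0.3, 1.0))
        integral = np.trapezoid(dens, t)
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_periodic_train_spectrum_peak(self):
        events = np.arange(0.5, 9.5, 1.0)  # exact 1 Hz train
        _, _, spec = ms.ms_density(events, window=(0.0, 10.0))
        band = (spec.freqs >= 0.5) & (spec.freqs <= 2.0)
        peak_f = spec.freqs[band][np.argmax(spec.power[band])]
        assert peak_f == pytest.approx(1.0, abs=0.1)

    def test_no_events_empty_result(self):
        t, dens, spec = ms.ms_density(np.array([]), window=(0.3, 1.0))
        assert dens.size == 0 and spec is None


class TestHolm:
    def test_hand_checked_three_element_set(self):
        # sorted: 0.01 <= 0.05/3 rejects; 0.03 > 0.05/2 stops the chain,
        # so 0.03 and 0.04 survive
        rej = ms.bonferroni_holm([0.01, 0.04, 0.03], alpha=0.05)
        assert rej.tolist() == [True, False, False]

    def test_hand_checked_full_rejection(self):
        # sorted: 0.01 <= 0.05/3, 0.02 <= 0.05/2, 0.04 <= 0.05/1 -> all
        rej = ms.bonferroni_holm([0.01, 0.04, 0.02], alpha=0.05)
        assert rej.all()

    def test_step_down_stops(self):
        # sorted: 0.001 <= 0.05/3 rejects; 0.03 > 0.05/2 stops the chain
        rej = ms.bonferroni_holm([0.03, 0.001, 0.04], alpha=0.05)
        assert rej.tolist() == [False, True, False]

    def test_all_ones_none_rejected(self):
        assert not ms.bonferroni_holm([1.0, 1.0, 1.0]).any()

    def test_single_p(self):
        assert ms.bonferroni_holm([0.04], alpha=0.05)[0]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ms.bonferroni_holm([])


def make_signal(n_trials=20, n_samples=600, fs=FS, t0=-0.2, fill=0.0):
    data = np.full((1, n_trials, n_samples), fill)
    return TrialTensor(data, fs=fs, t0_offset=t0)


class TestTriggeredAverage:
    def test_constant_signal_flat_and_nonsignificant(self):
        sig = make_signal(fill=1.0)
        events = [MicrosaccadeEvent(tr, 0.4, 0.42, 0.2, 20.0)
                  for tr in range(20)]
        res = ms.ms_triggered_average(events, sig, seed=0)
        assert np.allclose(res["mean"], 1.0)
        assert np.allclose(res["control"], 1.0)
        assert not res["significant"].any()

    def test_impulse_after_each_event_peaks_at_lag(self):
        rng = np.random.default_rng(7)
        sig = make_signal(n_trials=30, n_samples=800)
        sig.data += 0.01 * rng.standard_normal(sig.data.shape)
        events = []
        for tr in range(30):
            onset = 0.3 + 0.2 * rng.random()
            events.append(MicrosaccadeEvent(tr, onset, onset + 0.02, 0.2, 20.0))
            i = int(round((onset + 0.1 - sig.t0_offset) * FS))
            sig.data[0, tr, i] += 5.0
        res = ms.ms_triggered_average(events, sig, seed=1)
        assert res["times"][np.argmax(res["mean"][0])] == pytest.approx(
            0.1, abs=0.004)
        assert np.max(res["control"][0]) < 1.0

    def test_edge_events_excluded_and_counted(self):
        sig = make_signal(fill=0.5)
        # second event too close to trial start for the 0.3 s pre-window
        events = [MicrosaccadeEvent(0, 0.5, 0.52, 0.2, 20.0),
                  MicrosaccadeEvent(1, -0.15, -0.13, 0.2, 20.0)]
        res = ms.ms_triggered_average(events, sig, seed=2)
        assert res["n_used"] == 1 and res["n_excluded"] == 1

    def test_no_usable_event_raises(self):
        sig = make_signal()
        with pytest.raises(ValueError):
            ms.ms_triggered_average(
                [MicrosaccadeEvent(0, -0.19, -0.17, 0.2, 20.0)], sig)


class TestSplitByMs:
    def test_partition_matches_ground_truth(self):
        events = [MicrosaccadeEvent(1, 0.5, 0.52, 0.2, 20.0),
                  MicrosaccadeEvent(3, 0.7, 0.72, 0.2, 20.0),
                  MicrosaccadeEvent(2, 1.4, 1.42, 0.2, 20.0)]  # outside
        w, wo = ms.split_trials_by_ms(events, (0.3, 1.0), range(5))
        assert set(w) == {1, 3} and set(wo) == {0, 2, 4}

    def test_all_trials_with_events_flags_empty_partition(self):
        events = [MicrosaccadeEvent(tr, 0.5, 0.52, 0.2, 20.0)
                  for tr in range(4)]
        sig = make_signal(n_trials=4, n_samples=700, t0=-0.2)
        res = ms.compare_theta_by_ms(sig, events, (0.3, 1.0))
        assert res["skipped"] and np.isnan(res["p_value"])

    def test_ms_independent_theta_not_significant(self):
        # theta identical on every trial, microsaccades random: the
        # with/without comparison should usually be non-significant
        n_sig = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t = np.arange(-0.2, 1.2, 1 / FS)
            osc = 0.5 * np.sin(2 * np.pi * 4 * t) * (t > 0)
            data = osc[None, None, :] + 0.3 * rng.standard_normal(
                (6, 30, t.size))
            sig = TrialTensor(data, fs=FS, t0_offset=-0.2)
            events = [MicrosaccadeEvent(tr, 0.35 + 0.6 * rng.random(),
                                        0.99, 0.2, 20.0)
                      for tr in rng.choice(30, size=15, replace=False)]
            res = ms.compare_theta_by_ms(sig, events, (0.3, 1.0))
            if res["p_value"] < 0.05:
                n_sig += 1
        assert n_sig <= 2
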