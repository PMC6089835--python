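# thetasamp

Analysis pipeline for **theta-rhythmic neural activity and behavior in
center–surround competition paradigms**, with a synthetic-data module that
generates neural, oculomotor and behavioral sessions so the whole pipeline
runs — and is tested — without any recordings.

## The scientific problem

When two visual objects fall on the excitatory receptive-field (RF) center
and the suppressive surround of neighboring neuronal populations in visual
cortex (area V4), the mutual inhibition between the stimulus-representing
pools can turn sustained responses into an **anti-phase theta (3–9 Hz)
oscillation** of multi-unit activity (MUA). In a distributed-attention task
where a monkey monitors both objects for a brief luminance target, reaction
times (RTs) sampled on a fine target-delay grid fluctuate at the same theta
rate: the subject is fast to one object and slow to the other, alternating
every theta cycle. This package implements the full analysis chain that
quantifies this phenomenon, and a generator that emulates its assumed
structure:

- **MUA envelope extraction** — 300 Hz high-pass, rectification, 120 Hz
  low-pass, downsampling to 500 Hz, baseline z-scoring
  (`thetasamp.mua`).
- **Spectral statistics** — Hanning-tapered, zero-padded (5 s) power
  spectra; 3–9 Hz peak identification; autocorrelograms; time-resolved
  phase (0.5 s sliding window, 4 Hz multitaper smoothing); circular means;
  and a 5,000-shuffle **randomization test** whose null destroys temporal
  order while keeping the value distribution (`thetasamp.spectral`).
- **Microsaccade analysis** — velocity-space detection at 5 robust SDs
  (5-sample velocity window, median-based SD, elliptical threshold), rate,
  kernel-density spectra (bandwidth 0.18 s), microsaccade-triggered
  averages with a trial-shuffle control and Bonferroni–Holm correction
  (`thetasamp.microsaccades`).
- **Surround-suppression tuning** — size-tuning curves, suppression index
  `SI = (Amax − Amin)/Amax`, theta index `TI = (ls − ss)/(ls + ss)`,
  RF-distance channel inclusion (< 1.5°), theta-selective channel
  selection (`thetasamp.tuning`).
- **RT time-course analysis** — per-delay mean RTs on the 20 × 37.5 ms
  grid (effective sampling ≈ 26.7 Hz), session-wise normalization,
  quadratic detrending, masking of the first 250 ms, rhythmicity testing
  and location-specific Fourier phases (`thetasamp.behavior`).
- **Neural–behavioral coupling** — RT–MUA cross-correlation (inverted RT
  and catch-trial PSTH resampled to 150 Hz, lags ±450 ms, peak coefficient
  within ±125 ms), cross-correlogram rhythmicity, MUA–MUA lags converted
  to degrees at 4 Hz, single-trial phase at target time, and the target
  response sensitivity `d′ = (μp − μb)/√(½(σp² + σb²))` for fast- versus
  slow-RT target delays (`thetasamp.coupling`).

## Worked example

```python
import numpy as np
from thetasamp import behavior, coupling, mua
from thetasamp.simulate import SimulationParams, simulate_attention_session

params = SimulationParams(seed=7)          # 1200 trials, 1/3 catch trials
session = simulate_attention_session(params, with_eye=False)

center = behavior.detrend_rt(
    behavior.build_rt_timecourse(session.rt_table, "center"))
flanker = behavior.detrend_rt(
    behavior.build_rt_timecourse(session.rt_table, "flanker"))

sur = behavior.rt_spectrum(center, n_surrogates=5000, seed=7)
band = (sur.freqs >= 3) & (sur.freqs <= 9)
peak = sur.freqs[band][np.argmax(sur.observed_power[band])]
print(f"RT rhythm: {peak:.2f} Hz, p = {sur.band_p((3, 9)):.2e}")

offset = behavior.rt_phase_difference(center, flanker, peak)
shift = coupling.phase_time_convert(offset, 4.0, "deg_to_ms")
print(f"center-flanker offset: {offset:.0f} deg ({shift:.0f} ms at 4 Hz)")

z, _ = mua.zscore_mua(session.mua)
catch = np.flatnonzero((session.rt_table["condition"] == "catch").to_numpy())
psth, _ = mua.trial_average(z, catch)
ch = z.group_channels("disk")[0]
ccg = coupling.rt_mua_crosscorrelation(center, psth[ch], z.fs, z.t0_offset)
print(f"RT-MUA cross-correlation: peak {ccg.peak_coefficient:.2f} "
      f"at {ccg.peak_lag_ms:.0f} ms lag")
```

Output:

```
RT rhythm: 4.21 Hz, p = 2.00e-03
center-flanker offset: 94 deg (65 ms at 4 Hz)
RT-MUA cross-correlation: peak 0.56 at 7 ms lag
```

The session was generated with a 4.3 Hz RT modulation offset by 95°
between the two target locations; the analysis recovers the rhythm (4.21
Hz is the nearest bin of the 5 s-padded spectrum), rejects the shuffle
null, recovers the injected location offset, and finds the positive
near-zero-lag RT–MUA correlation that a shared rhythm predicts (high MUA
where RTs are fast).

A command-line interface mirrors the library:

```bash
thetasamp simulate --out session/ --seed 7
thetasamp detect-ms --eye session/eye.csv --out ms_events.csv
thetasamp rt-course --rt session/rt_table.csv --surrogates 5000 --seed 7 \
    --out-series rt_series.csv --out-spectrum rt_spectrum.csv
thetasamp run --scenario attention --seed 7 --out report/
```

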