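# Methods

This note documents the models, statistics, numerical choices and
limitations of the package. It complements the API docstrings; nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The paradigm being modeled

All analyses assume a trial structure of 1 s fixation baseline, a first
stimulus (a disk in the receptive-field center of one channel group) at
t = 0, and a second stimulus (flanking bars in the surround, driving a
neighboring group) at t = 0.5 s, with recording to t = 1.5 s. Times are
in seconds relative to first-stimulus onset; analysis windows are
half-open `[a, b)`. The sustained analysis window is 0.3–1.0 s after the
onset of the epoch of interest (for the two-stimulus oscillation epoch
this is 0.8–1.5 s in trial time). In the attention task a luminance
target appears on one of the two stimuli at one of 20 delays spaced
37.5 ms over the 750 ms following flanker onset, giving an effective
behavioral sampling rate of ~26.7 Hz; one third of trials are catch
trials with no target.

## Synthetic data generators

### Competition MUA

Two generators produce the anti-phase theta rhythm.

**Phenomenological (default).** Each pool's rate is a stereotyped onset
transient (difference of exponentials, 15/50 ms rise/decay) plus a
sustained step, plus — from second-stimulus onset — a sinusoid at
`theta_freq` (default 4.1 Hz) of amplitude `theta_amp` (default 0.5
relative to a sustained response of 1.0). The first-driven pool enters
the oscillation at its trough (the newly excited pool inhibits it), the
second-driven pool `antiphase_deg` (default 180°) away, i.e. at its
peak; reversing stimulus order swaps the roles. The oscillation
amplitude is scaled by `(1 − e^{−w})/(1 − e^{−1})` where `w` is the
inhibitory coupling, so `w = 0` removes the rhythm entirely and the
default `w = 1` leaves it unchanged. Injected frequency and phases are
exact, which is what parameter-recovery tests need.

**Mechanistic.** A two-pool rate model with mutual inhibition and
subtractive spike-rate adaptation,

    tau_r dr_i/dt = −r_i + [I_i(t) − w r_j − a_i]_+
    tau_a da_i/dt = −a_i + b r_i,

integrated by forward Euler at the MUA sampling step (2 ms), with
`tau_r = 10 ms`, `b = 2`, `w = 2.5 ×` the coupling parameter, and
`tau_a = adaptation_tau` (default 80 ms). With both drives on, dominance
alternates at a period set mainly by the adaptation time constant
(~3–4 Hz at the defaults); without inhibition the pools adapt to a
plateau with no sustained rhythm. The mechanistic model demonstrates
that the rhythm *emerges* from competition; its frequency is not
directly controllable, so recovery tests use the phenomenological
generator.

Channel heterogeneity is a ±10% multiplicative gain per channel; noise
is white Gaussian (`noise_sd`, default 0.3) per sample.

### Broadband rendering

To make the envelope-extraction stage testable end to end, rate traces
can be rendered as broadband voltage: an inhomogeneous Poisson spike
train (rate = floored rate trace × 60 Hz per unit by default), convolved
with a biphasic 0.6 ms spike waveform, plus optional white and 1/f
noise, at 10 kHz by default (30 kHz supported; filters scale with the
sampling rate, runtime and memory do too, which is why 10 kHz is the
desk-scale default).

### Eye traces

500 Hz gaze traces are slow drift (an Ornstein–Uhlenbeck walk with
500 ms time constant, clipped at 0.3°) plus white tremor noise (SD
0.0025°) plus microsaccades: Poisson onsets at `ms_rate` (default
1.0 Hz), thinned to a 100 ms minimum separation, gated off for 150 ms
after each stimulus onset (stimulus onsets transiently suppress
microsaccade production). Each microsaccade is a 25 ms minimum-jerk
displacement with amplitude drawn uniformly from 0.1–0.5° and peak
velocity 1.875 × amplitude / duration (the minimum-jerk main-sequence
relation); its direction is flipped toward the fixation point whenever
the jump would leave a 0.8° radius, and gaze is finally clipped to the
1° fixation window. Only the onset times and counts of the injected
events are used by recovery tests; the waveform shape and main-sequence
slope are modeling choices.

### Attention sessions

A single rhythm at `rt_mod_freq` (default 4.3 Hz) underlies everything
after flanker onset: the disk-group MUA oscillation, the flanker-group
oscillation offset by `rt_phase_offset_deg` (default 95°), the
trial-by-trial amplitude of the target-evoked response, and the RTs. For
a trial with target delay `d` at location ℓ the rhythm value is
`m = −cos(2π f d + φ_ℓ)`; the target-evoked MUA transient (a Gaussian
bump, 60 ms latency, 20 ms SD) has amplitude
`target_amp × (1 + 0.6 m + 0.25 ε)` and the RT is
`rt_base + trend − rt_mod_amp·m + noise`, so fast RTs coincide with high
MUA and large target responses. Delays inside the 0–250 ms masking
period add `mask_penalty_ms` (40 ms) and drop accuracy from 0.95 to
0.75. Defaults: 1200 trials (20 per delay per location after the 1/3
catch fraction), `rt_base = 210 ms`, `rt_mod_amp = 30 ms` with a 15 ms
quadratic trend (fluctuations of roughly ±45 ms around the session
mean), `rt_noise_sd = 20 ms` per trial (per-delay SEM ≈ 4.5 ms, making
the rhythm robustly detectable by the randomization test).

Using one frequency for both the neural and behavioral rhythm is a
deliberate modeling choice: the analyses this generator feeds
(cross-correlation, d′ at fast/slow delays) quantify a *shared* rhythm,
and a generator with dissociated frequencies would make their expected
outcomes ill-defined. `theta_freq` remains the independent knob for
passive-viewing and standalone MUA simulations.

### Passive-viewing sessions

Size tuning follows a ratio-of-Gaussians curve peaking at the 2° RF
center with ~60% surround suppression at the largest diameters. Three
stimulus conditions are generated: a small (2°) disk (sustained response,
no rhythm), a large (6°) disk (suppressed response, no rhythm), and a
disk-plus-annulus configuration (intermediate response with the theta
oscillation) — only separate center and surround stimulation yields the
rhythm. Eye traces are generated independently of the MUA, so the
with/without-microsaccade theta comparison is a true null.

## Statistics

**Power spectra** are one-sided amplitude-squared spectra of
Hanning-tapered segments zero-padded to 5 s (0.2 Hz bin spacing at
500 Hz input; ~0.2 Hz likewise for the 26.7 Hz RT grid). Only relative
comparisons are used downstream, so the absolute power normalization
(window-length scaling) is a convention. Peak identification returns the
largest *local* maximum inside the 3–9 Hz band, with ties broken toward
the lower frequency; a band with no local maximum (e.g. 1/f) returns a
NaN flag rather than the band edge.

**Time-resolved phase** uses a 0.5 s sliding window with "4 Hz spectral
smoothing" realized as DPSS tapers of time–half-bandwidth product 1
(half-bandwidth 2 Hz); the complex coefficient is averaged across
tapers, and the phase is referred to the window center so that a cosine
peaking at the center has phase 0°.

**Randomization test.** Surrogates randomly re-assign each value of the
(detrended, non-smoothed) series to a new position; the same spectral
analysis runs on each surrogate. Per-frequency
`p = (k + 1)/(n + 1)`, so 5,000 surrogates give a smallest attainable p
of 1/5001 ≈ 2 × 10⁻⁴. Because picking the band peak before testing
inflates the per-frequency false-positive rate, band-level decisions
(`SurrogateResult.significant`) use the max-statistic over the band:
the observed band maximum is compared against the null distribution of
surrogate band maxima. Per-frequency p-values remain available and are
what the type-I calibration checks at a fixed frequency. The surrogate
seed is an explicit argument and is stored in the result.

**Microsaccade detection** follows the velocity-space outlier approach:
5-sample moving-window velocity, per-axis robust SD
(`sqrt(median(v²) − median(v)²)`), elliptical threshold at 5 robust SDs,
minimum event duration 6 ms, events closer than 20 ms merged, monocular.
Amplitude is the onset-to-offset displacement. The density estimate
evaluates its Gaussian kernel (bandwidth interpreted as 0.18 **s**, the
trial-time axis) on a grid extended 4 bandwidths beyond the analysis
window so the pooled density integrates to 1.

**Cross-correlation.** The RT course is inverted (fast RT = positive),
mapped to absolute trial time (delay `d` → 0.5 s + `d`), linearly
interpolated to 150 Hz; the catch-trial PSTH is polyphase-resampled to
150 Hz; both are mean-subtracted and correlated over ±450 ms with the
unbiased (overlap-scaled) estimator, normalized so a zero-lag
autocorrelation equals 1. Lags with less than 0.25 s overlap (one theta
cycle) are reported as NaN. The peak coefficient is the **signed**
maximum within ±125 ms of zero. Cross-correlogram rhythmicity re-runs
the full cross-correlation on shuffled RT courses to build its null.
MUA–MUA lags use the same machinery and convert to degrees at 4 Hz
(`deg = ms × 4 × 360 / 1000`); at the 150 Hz common rate lags are
quantized to ~6.7 ms.

**d′.** For a trial set, trials are aligned on their target onsets; the
response peak is the maximum of the trial-averaged target-aligned MUA
within 0–200 ms; the peak window is 40 ms centered there; the baseline
is an equal-length window ending 60 ms before the peak window's center.
`d′ = (μp − μb)/√(½(σp² + σb²))` across trials. Fast-RT ("peak") and
slow-RT ("trough") delay sets come from the extrema of the inverted,
detrended RT course, located on the display smoother by default (robust
to single-bin noise) and snapped to the grid; locating them on the raw
series is supported by a flag.

**Channel selection** for phase analyses requires group membership,
post-stimulus theta power above baseline theta power (one-sided paired
Wilcoxon across trials, α = 0.05 — the package's choice of
"significantly larger" test, matching its prevailing nonparametric
tests), and a significant randomization rhythmicity test on the
trial-averaged course. Z-scoring uses the 700 ms pre-stimulus baseline
with mean and SD pooled across trials; constant-baseline channels are
flagged and excluded rather than silently kept.

## Problem sizes

Defaults are desk-scale: 8 + 8 channels, 100 trials for passive MUA
recovery, 1200-trial attention sessions (20 per delay per location), 200
fixation trials for microsaccade recovery, 5,000 surrogates for headline
tests and a few hundred for per-channel loops. The acceptance script
runs in seconds; the full test suite in well under a minute.

## Known limitations

- The generators are phenomenological at heart: no conductance-based
  dynamics, no latency gradients across the array, no
  eccentricity-dependent RF scatter. Real recordings show inter-group
  phase offsets below the idealized 180° (RF coverage heterogeneity);
  the generator exposes `antiphase_deg` but offers no mechanism for the
  deviation.
- Passing recovery tests shows the analysis chain is correct and
  calibrated under the assumed data structure; it cannot validate the
  biological model itself, nor the behavior of the detector and spectral
  stages under artifacts real data carry (blinks, drift nonstationarity,
  line noise).
- The surrogate test's per-frequency p-values are reported uncorrected;
  band-level decisions use the max-statistic. Which convention an
  individual published p corresponds to is not always decidable, so
  small quantitative differences in borderline significance are
  expected.
- LFP-like signals can be passed through the same operations but no
  LFP-specific method (coherence, Granger causality) is implemented.
- The broadband renderer is a plumbing model (Poisson spikes plus
  noise); it is not a biophysical extracellular-field simulation.
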