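# Methods

`bferp` analyses the coupling between basal-forebrain (BF) population
bursting and a frontal event-related potential (ERP) in an auditory oddball
task, and ships a generative forward model that produces complete synthetic
sessions for testing every stage.

## The task and the data model

A session is a sequence of tones 2 s apart: frequent unrewarded standards
with rare reward-predicting oddballs interleaved, the number of standards
between consecutive oddballs drawn uniformly from {2, 3, 4, 5, 6}
(oddball-to-oddball intervals of 6–14 s). An oddball answered in time is a
*hit*, otherwise a *miss*; a response to a standard is a *false alarm*.
Alongside the event table a session carries per-unit spike timestamps, a
frontal EEG channel, a no-task-signal control EEG channel, and a 32-channel
laminar LFP probe ordered by cortical depth (rank 1 superficial … 32 deep).
All analysis windows are half-open `[a, b)`; a sample at `t` belongs to the
bin whose left edge is ≤ `t`. Timestamps are stored as microsecond-precision
decimal text and samples as little-endian float32 with a JSON sidecar, so
bundles round-trip bit-exactly and are language-neutral.

## The analyses

**Bursting classification.** A unit's bursting index is its mean firing
rate in the `[50, 200)` ms post-tone window of hit trials divided by its
mean rate over the whole session span (including inter-trial epochs).
Units with index ≥ 2.5 are *bursting neurons*. The per-trial *population
bursting amplitude* is the mean window rate across bursting units; whether
this is a mean or a sum is immaterial downstream because the only consumer
(trial selection) thresholds at a fraction of the hit-trial mean.

**Choice probability.** For each lag on a grid of −0.2…0.4 s in 10 ms
steps, the per-trial EEG amplitude is the mean over a 100 ms window
*left-aligned* on the lag (alignment is a package convention; centred
windows would shift the series by 50 ms). The choice probability is the
ROC area between the amplitude distributions of two trial groups, with
midrank tie handling (the Mann–Whitney convention; an independent check
against `scipy.stats.mannwhitneyu` is part of the test suite). Group A is
fixed as the hit (or oddball) group, so values below 0.5 read "more
negative in hits". Significance comes from permuting group labels 1000
times, two-sided at α = 0.01, with the add-one estimate
`p = (1 + #extremes)/(n_perm + 1)` to avoid p = 0.

**Amplitude coupling.** Per unit and trial (all oddballs and standards):
spike count and mean EEG/LFP amplitude in `[50, 200)` ms. The amplitude is
multiplied by the sign of the session-average evoked deflection of that
channel, so a deeper negative ERP maps to a larger positive amplitude and
genuine coupling appears as a *positive* Pearson correlation (significant
at p < 0.001). The quintile view ranks trials by population bursting
amplitude (stable sort; bin sizes differ by ≤ 1), and expresses each
quintile's mean spike count and mean amplitude as a percentage of the
respective hit-trial averages (hits ≡ 100 %).

**Fine-timescale cross-correlation.** Trials with population amplitude
above 30 % of the mean hit amplitude are kept. Spike counts (1 ms bins)
and the EEG (downsampled 2 kHz → 1 kHz by two-sample mean where needed) in
`[0, 170)` ms of each kept trial are concatenated with a single shared
100 ms constant flank between neighbours (layout: flank, trial, flank,
trial, …, flank; length `270·n + 100`), the flank values being the unit's
session-mean rate per bin and the channel-mean EEG. Pearson coefficients
are computed with the EEG shifted over lags −50…50 ms; a *positive* best
lag means spiking leads the ERP. The EEG sequence is polarity-rectified
(same sign rule as amplitude coupling) so the maximum coefficient is
positive for a driving neuron. The null permutes the trial order of the
EEG segments before concatenation (1000 times); the envelope is per-lag
α/2 quantiles by default, with a max-statistic (family-wise) variant
available — per-lag matches a per-bin reading of the procedure, the max
variant is stricter.

**Layer profiles.** The 60 ms profile window is centred (±30 ms) on the
population bursting peak (argmax of the smoothed population PSTH in
`[0, 300)` ms; earliest bin on ties). Profile similarity is the cosine of
the angle between two 32-dimension vectors; its null permutes the 32
dimensions of one vector. Overall profiles are normalised to their peak
positive value (deep-positive peak ≡ 1). For stimulation sessions the
momentary pulse-averaged 32-channel vector is projected onto the unit-norm
reference at every millisecond; the series and its per-time-point 95 %
permutation band are normalised by the series' peak magnitude outside a
±5 ms artifact window. The onset of significant similarity is the first
post-pulse time above the upper band for ≥ 5 consecutive ms (an explicit,
configurable rule; "onset" needs a definition and a sustained run guards
against single-sample excursions).

## The generative forward model

Ten BF bursting neurons fire as inhomogeneous Poisson processes: a tonic
baseline plus, after each tone, a Gaussian burst (σ = 25 ms) peaking 50 ms
after the neuron's onset. Peak burst rates grade linearly from 100 down to
20 spikes/s and onsets stagger by 5 ms, strongest neuron earliest (first
onset 50 ms post-tone, so the strongest neuron peaks at 100 ms, matching
an ERP that begins ~50 ms and peaks ~100 ms after the tone). Every trial
carries a multiplicative amplitude: 1.0 on hits, 0.5 on misses and
standards (the model's attenuated example trial). The frontal EEG is
`polarity × gain × Σ_neurons (delayed drive) + noise` with polarity −1
(negative ERP) and a fixed 5 ms spike-to-ERP delay; each laminar channel
is the same summed drive times a fixed unit-norm deep-positive depth
profile. In `noise_free_intensity` mode the drive is the exact evoked
intensity — no Poisson sampling, no additive noise — which makes linearity
in the trial amplitude exact and, by the convolution shift theorem with
the symmetric kernel, makes the cross-correlation peak recover the 5 ms
delay in expectation. In `spike_driven` mode the drive is the
Gaussian-smoothed binned spike train minus the baseline rate, so signal
noise inherits realistic Poisson structure on top of additive Gaussian
noise. Stimulation sessions deliver one pulse every 2 s with no tones;
each pulse evokes the depth profile times a 40 ms raised-cosine bump
*starting* 8 ms after the pulse (strictly positive from its first sample,
so the nominal latency is exactly recoverable), plus a ±2 ms biphasic
artifact common to all channels.

Parameters that matter (defaults in `ForwardModelParams`):

| parameter | default | units | why |
|---|---|---|---|
| `peak_rates_hz` | 100 → 20, linear | spikes/s | stated range of the model ensemble |
| `onset_stagger_ms` | 5 | ms | stated stagger; stronger = earlier |
| `kernel_sigma_ms` | 25 | ms | gives ~100 ms bursts with peak at +100 ms; shape is a package choice (only PSTH shapes are known) |
| `baseline_rate_hz` | 4 | Hz | bursting-neuron baselines average ≈ 3.8 Hz; 4 is a round default |
| `erp_delay_ms` | 5 | ms | the model's fixed spike-to-ERP delay |
| `erp_polarity` | −1 | — | the frontal ERP is negative-going |
| `attenuated_scale` | 0.5 | — | the model's 50 % example trial |
| `erp_gain_uv_per_hz` | 0.5 | µV per Hz | sets evoked amplitude ~100–200 µV; arbitrary linear gain |
| `noise_sd_uv` | 2 | µV | keeps single-trial r in a realistic 0.3–0.6 range |
| `stim_latency_ms` | 8 | ms | stimulation-evoked onsets cluster near 8 ms |

## What the generator does and does not emulate

It reproduces the oddball trial grammar, graded Poisson bursting,
linear amplitude scaling across trial types, the fixed spike→ERP delay,
the deep-positive laminar profile, and stimulation-evoked responses with
artifact. It does **not** emulate hardware filtering (signals are
generated directly at 1 kHz), baseline-rate heterogeneity across units,
behavioural learning or satiety dynamics, volume conduction, or
current-source geometry. Passing tests therefore demonstrate that the
analysis code recovers the parameters of a linear, stationary,
Poisson-noise world; they do not certify performance against drifting
baselines, non-linear gain, or correlated noise in real recordings.

## Numerical choices

- Spike realisation discretises the intensity on a 1 ms grid
  (Poisson counts per bin, uniform placement within the bin, timestamps
  rounded to 1 µs). At peak rates ≤ 104 Hz the per-bin mass is ≤ 0.11, so
  discretisation bias is negligible at the 10 ms PSTH scale.
- PSTH smoothing uses a truncated (4σ), renormalised Gaussian with
  zero-padding, preserving total mass on interior bins to 1e-9.
- Argmax tie-breaks (burst peak, best lag) take the earliest candidate.
- Degenerate inputs raise rather than return sentinels: zero session rate
  (bursting index), zero variance (Pearson), constant sequences
  (cross-correlation), zero vectors (cosine), no positive entry
  (peak normalisation).
- Permutation p-values use the add-one estimator everywhere; permutation
  bands are quantiles of the null at the stated α.
- The pipeline derives per-stage seeds from one top-level seed via
  `SeedSequence.spawn`, making reports byte-identical under a fixed seed.

## Problem sizes

Test and example sessions use 12–40 oddballs (≈ 60–200 trials) with
permutation counts of 50–500; the delay-recovery benchmark uses a single
neuron over ≈ 1500 trials, where the best lag is 5 ms within ±1 ms (the
correlation function is nearly flat within ±2 ms of its peak — the
Gaussian kernel's autocorrelation — so ±1 ms argmax jitter is inherent).
Calibration suites run 2000 null replicates at reduced permutation counts
(199), which leaves the uniformity of the p-distribution intact.

## Known limitations

- Real-data summary counts reported in the literature (fractions of
  bursting or significantly coupled neurons, mean onset latencies) are
  *outputs* of the pipeline on synthetic data, not reproduction targets:
  the original recordings are not publicly deposited.
- The concatenated-flank layout uses one shared flank between adjacent
  trials; a doubled-flank layout changes the constant segments only and
  does not materially change the coefficients, but exact sequence lengths
  differ (`270·n + 100` vs `370·n + 100`).
- The bursting-index cutoff classification is inherently borderline for
  the weakest model neuron (expected index ≈ 2.8, sampling SE ≈ 0.4 in
  small sessions), so `n_bursting` can be 9 rather than 10 in short
  simulated sessions.
- Stimulation artifact handling is an exclusion window, not artifact
  removal; onsets earlier than the artifact window are undetectable by
  construction.
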