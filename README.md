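# bferp

Analysis pipeline linking **basal-forebrain (BF) population bursting** to a
**frontal event-related potential (ERP)** in an auditory oddball task —
with a generative forward model that produces complete synthetic sessions,
so every stage is testable end to end without any recordings.

Intended for electrophysiologists and computational neuroscientists who
work with simultaneous spike + EEG/LFP recordings and want reusable,
tested implementations of:

- **Bursting-neuron classification** — bursting index
  `= rate in [50, 200) ms of hit trials / whole-session rate`, cutoff 2.5;
- **ROC choice probability** — windowed AUC between trial groups over lags
  −0.2…0.4 s (10 ms steps, 100 ms windows), permutation significance;
  0.5 = indiscriminable, values < 0.5 = signal more negative in hits;
- **Single-trial amplitude coupling** — Pearson `r` between per-trial
  spike counts and EEG/LFP window amplitude (p < 0.001), plus the quintile
  linear-scaling curve normalised to hit trials = 100 %;
- **Millisecond spike–EEG cross-correlation** — per-trial `[0, 170)` ms
  windows concatenated with 100 ms constant flanks, Pearson coefficient at
  lags −50…50 ms, trial-order permutation null; positive best lag = the
  neuron *leads* the ERP;
- **Laminar layer profiles** — 32-channel, 60 ms window around the
  bursting peak; cosine similarity with a dimension-permutation null;
  stimulation-evoked scalar-projection similarity and onset latency.

The forward model: each of 10 BF neurons fires Poisson bursts after every
tone (peak rates 100 → 20 spikes/s, onsets staggered 5 ms, Gaussian kernel
σ = 25 ms), every trial scales multiplicatively (hits 1.0, misses and
standards 0.5), and the frontal EEG is the *negative, linear sum of all
neurons' smoothed drives delayed by 5 ms*; the 32-channel LFP is the same
drive times a fixed deep-positive depth profile. See `docs/methods.md`.

## Worked example

`examples/04_spike_erp_lag.py` simulates a 30-oddball session and runs the
concatenated cross-correlation for every unit:

```
153/153 trials selected
u01: index  6.9  best lag +16 ms (leads)  max r 0.155  significant=True
u02: index  8.2  best lag +16 ms (leads)  max r 0.164  significant=True
u03: index  8.3  best lag  +6 ms (leads)  max r 0.155  significant=True
u04: index  7.2  best lag  +1 ms (leads)  max r 0.147  significant=True
u05: index  5.5  best lag  +0 ms (trails)  max r 0.124  significant=True
u06: index  6.3  best lag  -1 ms (trails)  max r 0.124  significant=True
u07: index  5.1  best lag  -3 ms (trails)  max r 0.101  significant=True
u08: index  4.3  best lag -11 ms (trails)  max r 0.098  significant=True
u09: index  4.3  best lag -16 ms (trails)  max r 0.083  significant=True
u10: index  2.7  best lag -17 ms (trails)  max r 0.049  significant=True
```

Although *every* neuron drives the ERP with the same 5 ms delay, only the
strong, early-onset neurons appear to lead the (population-average) ERP,
and they correlate more strongly — the lead/lag asymmetry falls out of the
amplitude/latency grading, not from different circuit roles. The other
examples cover session simulation and bundle I/O (`01`), choice
probability against the control channel (`02`), amplitude coupling and
quintile scaling (`03`), layer-profile similarity (`05`), and
stimulation-evoked similarity onset (`06`); each prints the numbers it
computes and a line on what they mean.

```python
from bferp import ForwardModelParams, simulate_session
from bferp.burst import bursting_index

session = simulate_session(ForwardModelParams(), n_oddballs=25,
                           hit_rate=0.75, seed=42)
metrics = [bursting_index(u, session.events) for u in session.spikes]
print(sum(m.is_bursting for m in metrics), "bursting neurons")
```

## Layout

```
src/bferp/      io, synth, burst, choiceprob, coupling, xcorr, layers,
                pipeline, cli
examples/       one narrative script per capability
tests/          unit, property (hypothesis), and acceptance suites
docs/methods.md model, parameters, numerical choices, limitations
```
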