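"""Generative forward model: synthetic oddball sessions end to end.

The model emulates a population of basal-forebrain (BF) bursting neurons and
the frontal event-related potential (ERP) they drive:

* each tone evokes, in neuron *i*, a Gaussian burst of extra firing on top of
  a tonic baseline; stronger neurons burst earlier (peak rates graded
  linearly from 100 down to 20 spikes/s, onsets staggered by 5 ms);
* every trial carries a multiplicative amplitude ``trial_scale`` (1.0 on
  hits, an attenuated value — default 0.5 — on misses and standards);
* the frontal EEG is the *linear sum* of every neuron's smoothed drive,
  delayed by a fixed spike-to-ERP lag (5 ms) and sign-flipped (the frontal
  ERP is negative-going), plus Gaussian noise;
* the 32-channel laminar LFP is the same summed drive multiplied by a fixed
  deep-layer-positive depth profile;
* electrical-stimulation sessions evoke the same depth profile at a
  configurable post-pulse latency, with a brief stimulus artifact.

Spike trains are realised as inhomogeneous Poisson processes.  In
``noise_free_intensity`` mode the signal renderers use the exact evoked
intensity (no Poisson sampling, no additive noise), which makes linearity
and delay-recovery properties hold in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_seed_sequence
from .io import (
    ContinuousRecording,
    Session,
    SpikeTrain,
    StimEvents,
    TrialEvents,
)

__all__ = [
    "ForwardModelParams",
    "default_layer_profile",
    "generate_trial_sequence",
    "neuron_intensity",
    "simulate_bf_ensemble",
    "render_erp",
    "render_laminar_lfp",
    "simulate_stim_session",
    "simulate_session",
]

_FS = 1000.0  # signals are generated directly at 1 kHz
_DT = 1.0 / _FS


def default_layer_profile(n: int = 32) -> np.ndarray:
    """Unit-norm laminar depth profile: prominent positive response in the
    deep channels (rank ~26), weak negativity superficially."""
    rank = np.arange(1, n + 1, dtype=float)
    prof = np.exp(-0.5 * ((rank - 26.0) / 4.0) ** 2) - 0.3 * np.exp(
        -0.5 * ((rank - 8.0) / 5.0) ** 2
    )
    return prof / np.linalg.norm(prof)


@dataclass(frozen=True)
class ForwardModelParams:
    """Parameters of the generative spike -> ERP/LFP forward model.

    Defaults follow the model's stated configuration: 10 neurons with peak
    burst rates graded linearly 100 -> 20 spikes/s, burst onsets staggered
    by 5 ms (strongest neuron earliest), a fixed 5 ms spike-to-ERP delay,
    and a 50 %-amplitude attenuated trial type.  The burst kernel is a
    symmetric Gaussian (sigma 25 ms) peaking 50 ms after each neuron's
    onset; symmetry makes the cross-correlation peak recover ``erp_delay_ms``
    exactly in expectation.
    """

    n_neurons: int = 10
    peak_rates_hz: tuple = ()
    onset_stagger_ms: float = 5.0
    burst_onset_ms: float = 50.0
    kernel_sigma_ms: float = 25.0
    kernel_peak_after_onset_ms: float = 50.0
    baseline_rate_hz: float = 4.0
    erp_delay_ms: float = 5.0
    erp_polarity: float = -1.0
    erp_gain_uv_per_hz: float = 0.5
    attenuated_scale: float = 0.5
    noise_sd_uv: float = 2.0
    layer_profile_true: tuple = ()
    stim_latency_ms: float = 8.0
    stim_kernel_ms: float = 40.0
    stim_gain_uv: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if not self.peak_rates_hz:
            object.__setattr__(
                self,
                "peak_rates_hz",
                tuple(np.linspace(100.0, 20.0, self.n_neurons)),
            )
        if not len(self.layer_profile_true):
            object.__setattr__(
                self, "layer_profile_true", tuple(default_layer_profile())
            )
        if len(self.peak_rates_hz) != self.n_neurons:
            raise ValueError("peak_rates_hz length must equal n_neurons")
        if min(self.peak_rates_hz) <= 0:
            raise ValueError("peak burst rates must be positive")
        if self.kernel_sigma_ms <= 0:
            raise ValueError("burst kernel width must be positive")
        if max(self.layer_profile_true) <= 0:
            raise ValueError("layer profile must have a positive entry")

    def neuron_onset_ms(self, i: int) -> float:
        """Burst onset of neuron ``i`` (0-based; strongest neuron first)."""
        return self.burst_onset_ms + i * self.onset_stagger_ms

    def neuron_peak_time_ms(self, i: int) -> float:
        """Peri-stimulus time at which neuron ``i``'s burst rate peaks."""
        return self.neuron_onset_ms(i) + self.kernel_peak_after_onset_ms

    @property
    def profile(self) -> np.ndarray:
        return np.asarray(self.layer_profile_true, dtype=float)


# ---------------------------------------------------------------------------
# trial grammar
# ---------------------------------------------------------------------------


def generate_trial_sequence(
    n_oddballs: int,
    hit_rate: float,
    seed=None,
    *,
    fa_rate: float = 0.02,
    lead_standards: int | None = None,
    tail_standards: int = 2,
    t_first_s: float = 5.0,
) -> TrialEvents:
    """Oddball-task trial sequence: a tone every 2 s, 2-6 standards drawn
    uniformly between consecutive oddballs (oddball-to-oddball gaps of
    6-14 s), each oddball a hit with probability ``hit_rate`` else a miss.
    Standards are false-alarm-marked (via response_time_s) at ``fa_rate``.
    """
    if n_oddballs < 0:
        raise ValueError("n_oddballs must be >= 0")
    if not 0.0 <= hit_rate <= 1.0:
        raise ValueError("hit_rate must be a probability")
    rng = np.random.default_rng(seed)

    tones: list[str] = []
    lead = int(rng.integers(2, 7)) if lead_standards is None else lead_standards
    tones.extend(["standard"] * lead)
    for k in range(n_oddballs):
        tones.append("oddball")
        if k < n_oddballs - 1:
            tones.extend(["standard"] * int(rng.integers(2, 7)))
    tones.extend(["standard"] * tail_standards)

    n = len(tones)
    onset = t_first_s + 2.0 * np.arange(n)
    tone = np.array(tones, dtype=object)
    outcome = np.where(tone == "oddball", "miss", "none").astype(object)
    rt = np.full(n, np.nan)
    is_odd = tone == "oddball"
    hits = rng.random(n) < hit_rate
    outcome[is_odd & hits] = "hit"
    responded = is_odd & hits
    fas = (~is_odd) & (rng.random(n) < fa_rate)
    responded |= fas
    rt[responded] = np.round(rng.uniform(0.3, 1.2, responded.sum()), 6)
    return TrialEvents(
        trial_id=np.arange(n), onset_s=onset, tone=tone, outcome=outcome,
        response_time_s=rt,
    )


def trial_scales(params: ForwardModelParams, trials: TrialEvents) -> np.ndarray:
    """Per-trial amplitude: 1.0 on hit trials, ``attenuated_scale`` on
    miss and standard trials."""
    return np.where(trials.is_hit, 1.0, params.attenuated_scale)


# ---------------------------------------------------------------------------
# intensities and spikes
# ---------------------------------------------------------------------------


def neuron_intensity(params: ForwardModelParams, neuron_index: int,
                     trial_scale: float):
    """Peri-stimulus firing-rate function (Hz) for one neuron on one trial.

    ``intensity(t) = baseline + trial_scale * peak_rate_i * g(t - t_peak_i)``
    with ``g`` a unit-peak Gaussian of width ``kernel_sigma_ms``.  Returns a
    vectorised callable of peri-stimulus time in seconds.
    """
    if not 0 <= neuron_index < params.n_neurons:
        raise ValueError(f"neuron_index {neuron_index} out of range")
    if trial_scale < 0:
        raise ValueError("trial_scale must be non-negative")
    peak = params.peak_rates_hz[neuron_index]
    t_peak = params.neuron_peak_time_ms(neuron_index) / 1000.0
    sigma = params.kernel_sigma_ms / 1000.0

    def intensity(t_s):
        t_s = np.asarray(t_s, dtype=float)
        return params.baseline_rate_hz + trial_scale * peak * np.exp(
            -0.5 * ((t_s - t_peak) / sigma) ** 2
        )

    return intensity


def _session_grid(trials: TrialEvents, pad_s: float = 2.0):
    """1 kHz time grid covering the session: [0, last onset + pad).
    A session without trials has zero duration (and hence empty trains)."""
    t_end = (trials.onset_s[-1] + pad_s) if len(trials) else 0.0
    n = int(round(t_end * _FS))
    return n, t_end


def _add_kernels(drive: np.ndarray, centers_s: np.ndarray,
                 amps: np.ndarray, sigma_s: float) -> None:
    """Accumulate unit-peak Gaussians (amplitude-scaled) into ``drive``."""
    half = int(round(4 * sigma_s * _FS))
    tk = (np.arange(-half, half + 1)) * _DT
    kern = np.exp(-0.5 * (tk / sigma_s) ** 2)
    n = drive.size
    for c, a in zip(centers_s, amps):
        i0 = int(round(c * _FS)) - half
        j0, j1 = max(i0, 0), min(i0 + kern.size, n)
        if j1 > j0:
            drive[j0:j1] += a * kern[j0 - i0 : j1 - i0]


def _evoked_rate(params: ForwardModelParams, trials: TrialEvents,
                 neuron_index: int, delay_ms: float = 0.0) -> np.ndarray:
    """Session-long evoked rate (Hz, baseline excluded) of one neuron,
    optionally delayed, on the 1 kHz grid."""
    n, _ = _session_grid(trials)
    drive = np.zeros(n)
    scales = trial_scales(params, trials)
    centers = trials.onset_s + (params.neuron_peak_time_ms(neuron_index)
                                + delay_ms) / 1000.0
    amps = scales * params.peak_rates_hz[neuron_index]
    _add_kernels(drive, centers, amps, params.kernel_sigma_ms / 1000.0)
    return drive


def simulate_bf_ensemble(params: ForwardModelParams, trials: TrialEvents,
                         seed=None) -> list:
    """Draw each neuron's session spike train as an inhomogeneous Poisson
    process (baseline + trial-scaled bursts), discretised on a 1 ms grid
    with uniform within-bin placement.  Deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    n, t_end = _session_grid(trials)
    if n == 0:  # zero-duration session: nothing to draw
        return []
    span = (0.0, t_end)
    trains = []
    for i in range(params.n_neurons):
        lam = params.baseline_rate_hz + _evoked_rate(params, trials, i)
        counts = rng.poisson(lam * _DT)
        idx = np.repeat(np.nonzero(counts)[0], counts[counts > 0])
        t = (idx + rng.random(idx.size)) * _DT
        t = np.round(np.sort(t), 6)
        trains.append(SpikeTrain(f"u{i + 1:02d}", t, span))
    return trains


# ---------------------------------------------------------------------------
# signal renderers
# ---------------------------------------------------------------------------


def _summed_drive(params: ForwardModelParams, trials: TrialEvents,
                  mode: str, spikes=None) -> np.ndarray:
    """Summed, delayed drive (Hz) of all neurons on the 1 kHz grid.

    ``noise_free_intensity``: exact evoked intensities, delayed by
    ``erp_delay_ms``.  ``spike_driven``: Gaussian-smoothed binned spike
    rates minus each neuron's tonic baseline, delayed by ``erp_delay_ms``.
    """
    n, _ = _session_grid(trials)
    total = np.zeros(n)
    if mode == "noise_free_intensity":
        for i in range(params.n_neurons):
            total += _evoked_rate(params, trials, i,
                                  delay_ms=params.erp_delay_ms)
        return total
    if mode != "spike_driven":
        raise ValueError(f"unknown render mode {mode!r}")
    if spikes is None:
        raise ValueError("spike_driven mode requires spike trains")
    sigma_bins = params.kernel_sigma_ms / 1000.0 * _FS
    half = int(round(4 * sigma_bins))
    tk = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (tk / sigma_bins) ** 2)
    kern /= kern.sum()  # unit-mass smoother keeps rate units (Hz)
    shift = int(round(params.erp_delay_ms / 1000.0 * _FS))
    for st in spikes:
        counts = np.bincount(
            np.clip((st.spikes_s * _FS).astype(int), 0, n - 1), minlength=n
        ).astype(float)
        rate = np.convolve(counts, kern, mode="same") * _FS
        rate -= params.baseline_rate_hz
        delayed = np.zeros(n)
        delayed[shift:] = rate[: n - shift] if shift else rate
        total += delayed
    return total


def render_erp(params: ForwardModelParams, trials: TrialEvents,
               mode: str = "noise_free_intensity", spikes=None, seed=None,
               include_control: bool = True) -> ContinuousRecording:
    """Frontal EEG from the forward model: ``polarity * gain * summed
    delayed drive + noise``.  A control EEG channel (no task-locked
    component, noise only) is appended when ``include_control``."""
    rng = np.random.default_rng(seed)
    drive = _summed_drive(params, trials, mode, spikes)
    noise_sd = 0.0 if mode == "noise_free_intensity" else params.noise_sd_uv
    n = drive.size
    frontal = params.erp_polarity * params.erp_gain_uv_per_hz * drive
    if noise_sd:
        frontal = frontal + rng.normal(0, noise_sd, n)
    chans = [frontal]
    labels, roles, ranks = ["FrEEG"], ["frontal_eeg"], [None]
    if include_control:
        chans.append(rng.normal(0, noise_sd, n) if noise_sd else np.zeros(n))
        labels.append("CtrlEEG")
        roles.append("control_eeg")
        ranks.append(None)
    return ContinuousRecording(
        fs_hz=_FS, labels=labels, roles=roles, depth_rank=ranks,
        samples=np.vstack(chans), t0_s=0.0,
    )


def render_laminar_lfp(params: ForwardModelParams, trials: TrialEvents,
                       mode: str = "noise_free_intensity", spikes=None,
                       seed=None) -> ContinuousRecording:
    """32-channel laminar LFP: channel ``c`` = ``layer_profile_true[c] *
    gain * summed delayed drive + noise`` (deep channels positive)."""
    rng = np.random.default_rng(seed)
    drive = _summed_drive(params, trials, mode, spikes)
    noise_sd = 0.0 if mode == "noise_free_intensity" else params.noise_sd_uv
    prof = params.profile
    sig = prof[:, None] * (params.erp_gain_uv_per_hz * drive)[None, :]
    if noise_sd:
        sig = sig + rng.normal(0, noise_sd, sig.shape)
    return ContinuousRecording(
        fs_hz=_FS,
        labels=[f"LFP{r:02d}" for r in range(1, 33)],
        roles=["laminar_lfp"] * 32,
        depth_rank=list(range(1, 33)),
        samples=sig, t0_s=0.0,
    )


def simulate_stim_session(
    params: ForwardModelParams,
    n_pulses: int,
    seed=None,
    *,
    noise_sd_uv: float | None = None,
    early_transient_uv: float = 0.0,
    artifact_uv: float = 500.0,
    current_per_electrode_ua: float = 70.0,
) -> tuple[StimEvents, ContinuousRecording]:
    """Electrical-stimulation session: one pulse every 2 s, no tones.

    Each pulse evokes ``layer_profile_true`` times a raised-cosine bump of
    duration ``stim_kernel_ms`` *starting* ``stim_latency_ms`` after the
    pulse, plus a +/-2 ms biphasic artifact on all channels and optionally
    an early non-specific transient with a flat (profile-free) footprint.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    rng = np.random.default_rng(seed)
    noise_sd = params.noise_sd_uv if noise_sd_uv is None else noise_sd_uv
    pulses = 5.0 + 2.0 * np.arange(n_pulses)
    t_end = pulses[-1] + 2.0
    n = int(round(t_end * _FS))
    prof = params.profile

    dur = int(round(params.stim_kernel_ms))
    # strictly positive on every sample so the response truly starts at
    # `latency` (a half-open raised cosine would start one sample late)
    u = (np.arange(dur) + 1.0) / (dur + 1.0)
    bump = np.sin(np.pi * u) ** 2
    evoked = np.zeros(n)
    art = np.zeros(n)
    early = np.zeros(n)
    lat = int(round(params.stim_latency_ms))
    for p in pulses:
        i = int(round(p * _FS))
        evoked[i + lat : i + lat + dur] += bump[: max(0, min(dur, n - i - lat))]
        a0, a1 = max(i - 2, 0), min(i + 3, n)
        art[a0:a1] += artifact_uv * np.array([1, -1, 1, -1, 1])[: a1 - a0]
        if early_transient_uv:
            early[i + 2 : i + 6] += early_transient_uv
    sig = prof[:, None] * (params.stim_gain_uv * evoked)[None, :]
    sig += art[None, :]  # artifact is common to all channels
    sig += early[None, :]
    if noise_sd:
        sig = sig + rng.normal(0, noise_sd, sig.shape)
    rec = ContinuousRecording(
        fs_hz=_FS,
        labels=[f"LFP{r:02d}" for r in range(1, 33)],
        roles=["laminar_lfp"] * 32,
        depth_rank=list(range(1, 33)),
        samples=sig, t0_s=0.0,
    )
    stim = StimEvents(pulse_times_s=pulses,
                      current_per_electrode_ua=current_per_electrode_ua)
    return stim, rec


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------


def simulate_session(
    params: ForwardModelParams,
    n_oddballs: int = 40,
    hit_rate: float = 0.75,
    seed=None,
    mode: str = "spike_driven",
    fa_rate: float = 0.02,
) -> Session:
    """Complete synthetic session: trials, BF ensemble spikes, and a
    34-channel recording (frontal EEG, control EEG, 32 laminar LFP)."""
    ss = as_seed_sequence(params.seed if seed is None else seed)
    s_tr, s_sp, s_eeg, s_lfp = ss.spawn(4)
    trials = generate_trial_sequence(n_oddballs, hit_rate, seed=s_tr,
                                     fa_rate=fa_rate)
    spikes = simulate_bf_ensemble(params, trials, seed=s_sp)
    eeg = render_erp(params, trials, mode=mode, spikes=spikes, seed=s_eeg)
    lfp = render_laminar_lfp(params, trials, mode=mode, spikes=spikes,
                             seed=s_lfp)
    rec = ContinuousRecording(
        fs_hz=_FS,
        labels=list(eeg.labels) + list(lfp.labels),
        roles=list(eeg.roles) + list(lfp.roles),
        depth_rank=list(eeg.depth_rank) + list(lfp.depth_rank),
        samples=np.vstack([eeg.samples, lfp.samples]),
        t0_s=0.0,
    )
    return Session(events=trials, spikes=spikes, continuous=rec, stim=None)
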