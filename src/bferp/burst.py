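"""Peri-stimulus rate estimation and bursting-neuron classification.

A BF neuron's *bursting index* is the ratio of its mean firing rate in the
[50, 200) ms window after tone onset on hit trials to its mean firing rate
over the entire session; units with index >= 2.5 are classified as bursting
neurons.  The per-trial *population bursting amplitude* (mean window rate
across bursting units) drives trial sorting and selection downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import SpikeTrain, TrialEvents, ms_to_s

__all__ = [
    "PSTH",
    "BurstMetrics",
    "compute_psth",
    "population_psth",
    "bursting_index",
    "population_bursting_amplitude",
    "BURST_WINDOW_MS",
    "BURSTING_INDEX_CUTOFF",
]

#: Post-onset spike-counting window (ms), half-open.
BURST_WINDOW_MS = (50.0, 200.0)
#: Bursting-index cutoff classifying BF bursting neurons.
BURSTING_INDEX_CUTOFF = 2.5


@dataclass(frozen=True)
class PSTH:
    bin_edges_ms: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    smoothing_sigma_ms: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "bin_edges_ms",
                           np.asarray(self.bin_edges_ms, dtype=float))
        object.__setattr__(self, "rate_hz",
                           np.asarray(self.rate_hz, dtype=float))
        if len(self.rate_hz) != len(self.bin_edges_ms) - 1:
            raise ValueError("rate must have one entry per bin")
        if np.any(self.rate_hz < -1e-12):
            raise ValueError("PSTH rate must be non-negative")

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


@dataclass(frozen=True)
class BurstMetrics:
    """Per-unit bursting classification summary."""

    unit_id: str
    window_rate_hz: float
    session_mean_hz: float
    bursting_index: float
    is_bursting: bool


def _window_counts(spikes: SpikeTrain, onsets: np.ndarray,
                   window_ms=BURST_WINDOW_MS) -> np.ndarray:
    """Spike counts per trial in the half-open peri-onset window."""
    a, b = ms_to_s(window_ms[0]), ms_to_s(window_ms[1])
    lo = np.searchsorted(spikes.spikes_s, onsets + a, side="left")
    hi = np.searchsorted(spikes.spikes_s, onsets + b, side="left")
    return hi - lo


def compute_psth(
    spikes: SpikeTrain,
    onsets_s: np.ndarray,
    window_ms: tuple[float, float] = (-100.0, 400.0),
    bin_ms: float = 10.0,
    smoothing_sigma_ms: float | None = None,
) -> PSTH:
    """Trial-averaged peri-stimulus time histogram.

    Rate per bin is pooled spike count / (n_trials x bin width); optional
    Gaussian smoothing (zero-padded, mass-preserving on interior bins).
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    if onsets_s.size == 0:
        raise ValueError("compute_psth requires at least one event")
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    edges = np.arange(window_ms[0], window_ms[1] + bin_ms / 2, bin_ms)
    rel = (spikes.spikes_s[None, :] - onsets_s[:, None]) * 1000.0
    rel = rel[(rel >= edges[0]) & (rel < edges[-1])]
    # np.histogram's last bin is closed; nudge the final edge to keep all
    # bins half-open
    counts, _ = np.histogram(rel, bins=np.append(edges[:-1], edges[-1] - 1e-9))
    rate = counts / (onsets_s.size * ms_to_s(bin_ms))
    if smoothing_sigma_ms is not None:
        rate = gaussian_filter1d(rate, smoothing_sigma_ms / bin_ms,
                                 mode="constant", cval=0.0)
    return PSTH(edges, rate, onsets_s.size, smoothing_sigma_ms)


def population_psth(units: list, onsets_s: np.ndarray, **kwargs) -> PSTH:
    """Mean PSTH across units (equal unit weighting)."""
    if not units:
        raise ValueError("population_psth requires at least one unit")
    psths = [compute_psth(u, onsets_s, **kwargs) for u in units]
    rate = np.mean([p.rate_hz for p in psths], axis=0)
    return PSTH(psths[0].bin_edges_ms, rate, psths[0].n_trials,
                psths[0].smoothing_sigma_ms)


def bursting_index(
    spikes: SpikeTrain,
    trials: TrialEvents,
    window_ms: tuple[float, float] = BURST_WINDOW_MS,
    cutoff: float = BURSTING_INDEX_CUTOFF,
) -> BurstMetrics:
    """Bursting index: mean [50, 200) ms hit-trial rate over whole-session
    mean rate.  Raises on zero session rate rather than returning 0 or inf.
    """
    hit_onsets = trials.onset_s[trials.is_hit]
    if hit_onsets.size == 0:
        raise ValueError("bursting_index requires at least one hit trial")
    session_mean = spikes.mean_rate_hz
    if session_mean == 0:
        raise ZeroDivisionError(
            f"unit {spikes.unit_id}: session mean rate is 0; "
            "bursting index undefined"
        )
    width_s = ms_to_s(window_ms[1] - window_ms[0])
    window_rate = _window_counts(spikes, hit_onsets, window_ms).mean() / width_s
    idx = window_rate / session_mean
    return BurstMetrics(
        unit_id=spikes.unit_id,
        window_rate_hz=float(window_rate),
        session_mean_hz=float(session_mean),
        bursting_index=float(idx),
        is_bursting=bool(idx >= cutoff),
    )


def population_bursting_amplitude(
    units: list,
    trials: TrialEvents,
    window_ms: tuple[float, float] = BURST_WINDOW_MS,
) -> np.ndarray:
    """Per-trial population bursting amplitude (Hz): mean across the given
    (bursting) units of each unit's firing rate in the post-onset window."""
    if not units:
        raise ValueError("population amplitude requires at least one unit")
    width_s = ms_to_s(window_ms[1] - window_ms[0])
    rates = np.stack(
        [_window_counts(u, trials.onset_s, window_ms) / width_s for u in units]
    )
    return rates.mean(axis=0)
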