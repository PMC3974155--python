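"""Single-trial amplitude coupling between BF spiking and EEG/LFP.

For every oddball and standard tone, each unit contributes its spike count
in the [50, 200) ms post-onset window, paired with the mean EEG/LFP
amplitude in the same window.  Coupling is Pearson correlation across
trials (significant at p < 0.001).  The linear-scaling view bins trials
into quintiles of the population bursting amplitude and expresses both
measures as a percentage of their hit-trial average (hits = 100 %).

Sign convention: the EEG window mean is multiplied by the sign of the
session-average evoked deflection on that channel, so a deeper
(more negative) frontal ERP maps to a larger positive amplitude and
"strong bursting <-> strong ERP" is a positive correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .io import ContinuousRecording, SpikeTrain, TrialEvents, ms_to_s
from .burst import BURST_WINDOW_MS, _window_counts

__all__ = [
    "AmplitudeCouplingResult",
    "trial_pairs",
    "amplitude_correlation",
    "quintile_scaling",
    "evoked_sign",
]

SIGNIFICANCE_P = 1e-3


@dataclass(frozen=True)
class AmplitudeCouplingResult:
    unit_id: str
    r: float
    p: float
    significant: bool
    quintiles: np.ndarray | None = None  # (5, 2): (bf_pct, signal_pct)

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r out of [-1, 1]")


def evoked_sign(rec: ContinuousRecording, channel: str,
                onsets_s: np.ndarray,
                window_ms=BURST_WINDOW_MS) -> float:
    """Sign (+/-1) of the session-average evoked deflection of a channel in
    the post-onset window; +1 when the mean deflection is exactly zero."""
    x = rec.channel(channel)
    a, b = ms_to_s(window_ms[0]), ms_to_s(window_ms[1])
    w = int(round((b - a) * rec.fs_hz))
    i0 = np.floor((np.asarray(onsets_s) + a - rec.t0_s) * rec.fs_hz
                  + 1e-9).astype(int)
    idx = i0[:, None] + np.arange(w)[None, :]
    m = x[idx].mean()
    return -1.0 if m < 0 else 1.0


def trial_pairs(
    spikes: SpikeTrain,
    rec: ContinuousRecording,
    channel: str,
    events: TrialEvents,
    window_ms=BURST_WINDOW_MS,
    rectify: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (spike count, signal amplitude) pairs over all oddball and
    standard tones.  Amplitude is the [50, 200) ms window mean, polarity-
    rectified by the session-average evoked sign when ``rectify``."""
    onsets = events.onset_s
    if onsets.size < 3:
        raise ValueError("amplitude coupling requires at least 3 trials")
    counts = _window_counts(spikes, onsets, window_ms).astype(float)
    x = rec.channel(channel)
    a = ms_to_s(window_ms[0])
    w = int(round(ms_to_s(window_ms[1] - window_ms[0]) * rec.fs_hz))
    i0 = np.floor((onsets + a - rec.t0_s) * rec.fs_hz + 1e-9).astype(int)
    if i0.min() < 0 or i0.max() + w > rec.n_samples:
        raise ValueError("trial window outside recorded span")
    amps = x[i0[:, None] + np.arange(w)[None, :]].mean(axis=1)
    if rectify:
        amps = amps * evoked_sign(rec, channel, onsets, window_ms)
    return counts, amps


def amplitude_correlation(
    counts: np.ndarray,
    amps: np.ndarray,
    unit_id: str = "",
    significance_p: float = SIGNIFICANCE_P,
) -> AmplitudeCouplingResult:
    """Pearson correlation (two-sided p) between spike counts and signal
    amplitudes across trials."""
    counts = np.asarray(counts, dtype=float)
    amps = np.asarray(amps, dtype=float)
    if np.std(counts) == 0 or np.std(amps) == 0:
        raise ValueError(
            f"unit {unit_id or '?'}: zero variance; correlation undefined"
        )
    res = pearsonr(counts, amps)
    return AmplitudeCouplingResult(
        unit_id=unit_id, r=float(res.statistic), p=float(res.pvalue),
        significant=bool(res.pvalue < significance_p),
    )


def quintile_scaling(
    population_amplitude: np.ndarray,
    unit_values: np.ndarray,
    signal_values: np.ndarray,
    hit_mask: np.ndarray,
    n_bins: int = 5,
) -> np.ndarray:
    """Quintile linear-scaling curve.

    Trials are ranked by the population bursting amplitude (stable sort)
    and split into ``n_bins`` near-equal bins.  Each bin's mean unit value
    and mean signal value are normalised to percent of the respective
    hit-trial average (hits = 100 %).  Returns an (n_bins, 2) array of
    (bf_pct, signal_pct), ordered weakest to strongest bursting.
    """
    pop = np.asarray(population_amplitude, dtype=float)
    uv = np.asarray(unit_values, dtype=float)
    sv = np.asarray(signal_values, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    if not (pop.size == uv.size == sv.size == hit_mask.size):
        raise ValueError("per-trial inputs must have equal length")
    if pop.size < n_bins:
        raise ValueError(f"need at least {n_bins} trials")
    hit_unit = uv[hit_mask].mean() if hit_mask.any() else np.nan
    hit_sig = sv[hit_mask].mean() if hit_mask.any() else np.nan
    if not hit_mask.any() or hit_unit == 0 or hit_sig == 0:
        raise ValueError("hit-trial average is zero or missing; "
                         "normalisation undefined")
    order = np.argsort(pop, kind="stable")
    bins = np.array_split(order, n_bins)
    out = np.empty((n_bins, 2))
    for k, b in enumerate(bins):
        out[k, 0] = uv[b].mean() * 100.0 / hit_unit
        out[k, 1] = sv[b].mean() * 100.0 / hit_sig
    return out
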