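"""Millisecond spike-EEG cross-correlation via concatenated flanked windows.

For each BF bursting neuron, spike counts (1 ms bins) and the frontal EEG
(downsampled to 1 kHz) in the [0, 170) ms window of selected trials are
concatenated into two long vectors, neighbouring trials separated by a
100 ms constant flank (the unit's session-mean rate / the channel-mean EEG
value), and the Pearson coefficient is computed with the EEG vector shifted
over lags -50..50 ms.  Only trials whose population bursting amplitude
exceeds 30 % of the mean hit-trial amplitude enter the analysis.  The
permutation null permutes the trial order of the EEG segments before
concatenation (1000 times, p < 0.01 two-sided).

Sign conventions (stated explicitly because the literature varies):

* the EEG sequence is polarity-rectified (multiplied by the sign of the
  session-average evoked deflection) so the maximal coefficient is
  positive for a neuron that drives the ERP;
* a *positive* best lag means BF spiking leads the ERP by that many ms
  (the EEG is shifted later in time to align).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ContinuousRecording, SpikeTrain, TrialEvents, ms_to_s
from .burst import BurstMetrics
from .coupling import evoked_sign

__all__ = [
    "CrossCorrResult",
    "select_trials",
    "trial_matrices",
    "concatenate_flanked",
    "build_concatenated_pair",
    "concatenated_xcorr",
    "xcorr_permutation",
    "cross_correlate_unit",
    "average_significant_xcorr",
    "delay_metric_correlations",
    "normalize_by_session_min",
    "DEFAULT_LAGS_MS",
    "TRIAL_WINDOW_MS",
    "FLANK_MS",
]

DEFAULT_LAGS_MS = np.arange(-50, 51)
TRIAL_WINDOW_MS = (0.0, 170.0)
FLANK_MS = 100


@dataclass(frozen=True)
class CrossCorrResult:
    unit_id: str
    lags_ms: np.ndarray
    r: np.ndarray
    band_lower: np.ndarray | None
    band_upper: np.ndarray | None
    best_lag_ms: int
    max_r: float
    significant_anywhere: bool

    def __post_init__(self):
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValueError("correlation coefficient out of [-1, 1]")
        if not self.lags_ms.min() <= self.best_lag_ms <= self.lags_ms.max():
            raise ValueError("best lag outside the lag grid")


def select_trials(
    population_amplitude: np.ndarray,
    hit_mask: np.ndarray,
    threshold_frac: float = 0.30,
) -> np.ndarray:
    """Boolean mask of trials whose population bursting amplitude exceeds
    ``threshold_frac`` of the mean hit-trial amplitude."""
    pop = np.asarray(population_amplitude, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    if not hit_mask.any():
        raise ValueError("trial selection requires at least one hit trial")
    thr = threshold_frac * pop[hit_mask].mean()
    return pop > thr


def _downsample_to_1khz(x: np.ndarray, fs_hz: float) -> np.ndarray:
    """2 kHz -> 1 kHz by two-sample mean then decimation; 1 kHz unchanged."""
    if fs_hz == 1000:
        return x
    if fs_hz == 2000:
        n = (x.size // 2) * 2
        return x[:n].reshape(-1, 2).mean(axis=1)
    raise ValueError(f"unsupported sampling rate {fs_hz}")


def trial_matrices(
    spikes: SpikeTrain,
    rec: ContinuousRecording,
    channel: str,
    onsets_s: np.ndarray,
    trial_window_ms=TRIAL_WINDOW_MS,
    rectify: bool = True,
):
    """Per-trial 1 ms-resolution segments and the flank constants.

    Returns ``(spike_mat, eeg_mat, spike_flank, eeg_flank)`` where the
    matrices are (n_trials, window length in ms), the spike flank is the
    unit's session-mean rate in counts per 1 ms bin, and the EEG flank is
    the mean of the (rectified) channel signal.
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    if onsets_s.size == 0:
        raise ValueError("no trials selected")
    w0, w1 = trial_window_ms
    n_bins = int(round(w1 - w0))
    edges_s = ms_to_s(np.arange(w0, w1 + 0.5))
    spike_mat = np.empty((onsets_s.size, n_bins))
    for k, t in enumerate(onsets_s):
        spike_mat[k], _ = np.histogram(spikes.spikes_s - t,
                                       bins=np.append(edges_s[:-1],
                                                      edges_s[-1] - 1e-9))
    spike_flank = spikes.mean_rate_hz / 1000.0  # counts per 1 ms bin

    x = _downsample_to_1khz(rec.channel(channel).astype(float), rec.fs_hz)
    if rectify:
        x = x * evoked_sign(rec, channel, onsets_s)
    i0 = np.floor((onsets_s + ms_to_s(w0) - rec.t0_s) * 1000.0
                  + 1e-9).astype(int)
    if i0.min() < 0 or i0.max() + n_bins > x.size:
        raise ValueError("trial window outside recorded span")
    eeg_mat = x[i0[:, None] + np.arange(n_bins)[None, :]]
    eeg_flank = float(x.mean())
    return spike_mat, eeg_mat, spike_flank, eeg_flank


def concatenate_flanked(mat: np.ndarray, flank_value: float,
                        flank_ms: int = FLANK_MS) -> np.ndarray:
    """Concatenate trial segments with a single shared constant flank
    between neighbours: flank, trial, flank, trial, ..., flank.  Length is
    ``n_trials * (T + flank) + flank``."""
    n, t = mat.shape
    out = np.full(n * (t + flank_ms) + flank_ms, flank_value, dtype=float)
    for k in range(n):
        start = flank_ms + k * (t + flank_ms)
        out[start : start + t] = mat[k]
    return out


def build_concatenated_pair(
    spikes: SpikeTrain,
    rec: ContinuousRecording,
    channel: str,
    onsets_s: np.ndarray,
    trial_window_ms=TRIAL_WINDOW_MS,
    flank_ms: int = FLANK_MS,
    rectify: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """The two aligned concatenated sequences (spike counts, EEG) at 1 ms
    resolution."""
    sm, em, sf, ef = trial_matrices(spikes, rec, channel, onsets_s,
                                    trial_window_ms, rectify)
    return (concatenate_flanked(sm, sf, flank_ms),
            concatenate_flanked(em, ef, flank_ms))


def _corr_at_lags(spike_seq: np.ndarray, eeg_seq: np.ndarray,
                  lags_ms: np.ndarray) -> np.ndarray:
    """Pearson r with the EEG sequence shifted by each lag: positive lag
    correlates spikes at t with EEG at t + lag (spikes lead)."""
    n = spike_seq.size
    out = np.empty(lags_ms.size)
    for i, lag in enumerate(lags_ms):
        lag = int(lag)
        if lag >= 0:
            a, b = spike_seq[: n - lag] if lag else spike_seq, eeg_seq[lag:]
        else:
            a, b = spike_seq[-lag:], eeg_seq[:lag]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            raise ValueError("degenerate (constant) sequence in correlation")
        out[i] = ((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)
    return out


def concatenated_xcorr(
    spike_seq: np.ndarray,
    eeg_seq: np.ndarray,
    lags_ms: np.ndarray = DEFAULT_LAGS_MS,
    unit_id: str = "",
) -> CrossCorrResult:
    """Normalized cross-correlation of the concatenated pair over the lag
    grid; the best lag maximises r (positive = BF leads the ERP)."""
    if spike_seq.size != eeg_seq.size:
        raise ValueError("sequences must be aligned (equal length)")
    r = _corr_at_lags(np.asarray(spike_seq, float),
                      np.asarray(eeg_seq, float), lags_ms)
    best = int(np.argmax(r))
    return CrossCorrResult(
        unit_id=unit_id, lags_ms=np.asarray(lags_ms), r=r,
        band_lower=None, band_upper=None,
        best_lag_ms=int(lags_ms[best]), max_r=float(r[best]),
        significant_anywhere=False,
    )


def xcorr_permutation(
    spike_mat: np.ndarray,
    eeg_mat: np.ndarray,
    spike_flank: float,
    eeg_flank: float,
    lags_ms: np.ndarray = DEFAULT_LAGS_MS,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed=None,
    flank_ms: int = FLANK_MS,
    band: str = "per_lag",
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation envelope for the concatenated cross-correlation.

    The null permutes the *trial order* of the EEG segments before
    concatenation.  ``band='per_lag'`` returns per-lag alpha/2 and
    1 - alpha/2 null quantiles; ``band='max'`` returns a flat envelope from
    the null distribution of the across-lag extrema (max statistic).
    """
    rng = np.random.default_rng(seed)
    spike_seq = concatenate_flanked(spike_mat, spike_flank, flank_ms)
    null = np.empty((n_perm, lags_ms.size))
    for k in range(n_perm):
        perm = rng.permutation(eeg_mat.shape[0])
        eeg_seq = concatenate_flanked(eeg_mat[perm], eeg_flank, flank_ms)
        null[k] = _corr_at_lags(spike_seq, eeg_seq, lags_ms)
    if band == "per_lag":
        lower = np.quantile(null, alpha / 2, axis=0)
        upper = np.quantile(null, 1 - alpha / 2, axis=0)
    elif band == "max":
        lo = np.quantile(null.min(axis=1), alpha / 2)
        hi = np.quantile(null.max(axis=1), 1 - alpha / 2)
        lower = np.full(lags_ms.size, lo)
        upper = np.full(lags_ms.size, hi)
    else:
        raise ValueError(f"unknown band mode {band!r}")
    return lower, upper


def cross_correlate_unit(
    spikes: SpikeTrain,
    rec: ContinuousRecording,
    channel: str,
    onsets_s: np.ndarray,
    lags_ms: np.ndarray = DEFAULT_LAGS_MS,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed=None,
    band: str = "per_lag",
) -> CrossCorrResult:
    """Full per-unit analysis: concatenated cross-correlation plus the
    trial-order permutation envelope."""
    sm, em, sf, ef = trial_matrices(spikes, rec, channel, onsets_s)
    res = concatenated_xcorr(concatenate_flanked(sm, sf),
                             concatenate_flanked(em, ef), lags_ms,
                             unit_id=spikes.unit_id)
    if n_perm == 0:
        return res
    lower, upper = xcorr_permutation(sm, em, sf, ef, lags_ms, n_perm, alpha,
                                     seed, band=band)
    sig = bool(np.any((res.r > upper) | (res.r < lower)))
    return CrossCorrResult(
        unit_id=res.unit_id, lags_ms=res.lags_ms, r=res.r,
        band_lower=lower, band_upper=upper,
        best_lag_ms=res.best_lag_ms, max_r=res.max_r,
        significant_anywhere=sig,
    )


def average_significant_xcorr(results: list) -> np.ndarray:
    """Mean correlation function over units significant anywhere."""
    sig = [r.r for r in results if r.significant_anywhere]
    if not sig:
        raise ValueError("no unit reached significance")
    return np.mean(sig, axis=0)


def delay_metric_correlations(results: list, metrics: list) -> dict:
    """Pearson (r, p) across units of best lag vs maximal coefficient,
    bursting index, and session-mean (baseline) rate."""
    from scipy.stats import pearsonr

    by_id = {m.unit_id: m for m in metrics}
    lag = np.array([res.best_lag_ms for res in results], dtype=float)
    if np.std(lag) == 0:
        raise ValueError("best lags are constant; correlation undefined")
    out = {}
    pairs = {
        "best_lag_vs_max_r": np.array([res.max_r for res in results]),
        "best_lag_vs_bursting_index": np.array(
            [by_id[res.unit_id].bursting_index for res in results]),
        "best_lag_vs_baseline_rate": np.array(
            [by_id[res.unit_id].session_mean_hz for res in results]),
    }
    for name, y in pairs.items():
        if np.std(y) == 0:
            raise ValueError(f"{name}: constant metric; correlation undefined")
        r = pearsonr(lag, y)
        out[name] = (float(r.statistic), float(r.pvalue))
    return out


def normalize_by_session_min(max_r: np.ndarray,
                             session: np.ndarray) -> np.ndarray:
    """|max_r| divided by the session's least-correlated bursting unit's
    |max_r|; the least correlated unit of each session maps to 1."""
    max_r = np.asarray(max_r, dtype=float)
    session = np.asarray(session)
    out = np.empty_like(max_r)
    for s in np.unique(session):
        m = session == s
        floor = np.abs(max_r[m]).min()
        if floor == 0:
            raise ValueError(f"session {s}: minimum |max_r| is zero")
        out[m] = np.abs(max_r[m]) / floor
    return out
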