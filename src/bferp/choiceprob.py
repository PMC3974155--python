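"""Windowed ROC "choice probability" with permutation significance.

The choice probability is the area under the ROC curve comparing a signal's
per-trial window-averaged amplitude between two trial groups (hit vs miss,
or oddball vs standard): 0.5 means complete overlap of the two
distributions; 1 (or 0) means complete non-overlap with group A larger (or
smaller).  Ties are handled by midranks (Mann-Whitney convention).  The
series is computed at lags -0.2..0.4 s from tone onset in 10 ms steps, each
lag using a 100 ms averaging window, with a 1000-permutation two-sided null
at alpha = 0.01.

Group A is fixed as the hit (or oddball) group, so a significant value
below 0.5 reads "signal more negative in hits" — the signature of the
negative-going frontal ERP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._rng import as_seed_sequence
from .io import ContinuousRecording

__all__ = [
    "ChoiceProbabilitySeries",
    "windowed_amplitude",
    "choice_probability",
    "permutation_significance",
    "choice_probability_series",
    "DEFAULT_LAGS_S",
]

#: Lag grid: [-0.2, 0.4] s from tone onset in 10 ms steps (left-aligned
#: 100 ms windows).
DEFAULT_LAGS_S = np.round(np.arange(-0.2, 0.4 + 1e-9, 0.01), 10)


@dataclass(frozen=True)
class ChoiceProbabilitySeries:
    lag_s: np.ndarray
    auc: np.ndarray
    p_two_sided: np.ndarray
    significant: np.ndarray
    alpha: float

    def __post_init__(self):
        if not (len(self.lag_s) == len(self.auc) == len(self.p_two_sided)
                == len(self.significant)):
            raise ValueError("series fields must have equal length")
        if np.any((self.auc < 0) | (self.auc > 1)):
            raise ValueError("AUC must lie in [0, 1]")


def windowed_amplitude(
    rec: ContinuousRecording,
    channel: str,
    onsets_s: np.ndarray,
    lag_s: float,
    window_s: float = 0.1,
) -> np.ndarray:
    """Per-trial mean signal amplitude in [onset + lag, onset + lag +
    window).  Trials whose window leaves the recorded span are excluded
    with a warning."""
    onsets_s = np.asarray(onsets_s, dtype=float)
    if onsets_s.size == 0:
        raise ValueError("windowed_amplitude requires at least one event")
    x = rec.channel(channel)
    w = int(round(window_s * rec.fs_hz))
    i0 = np.floor((onsets_s + lag_s - rec.t0_s) * rec.fs_hz + 1e-9).astype(int)
    ok = (i0 >= 0) & (i0 + w <= rec.n_samples)
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} trial window(s) outside recorded span excluded",
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("no trial window lies within the recorded span")
    idx = i0[ok, None] + np.arange(w)[None, :]
    return x[idx].mean(axis=1)


def choice_probability(values_a, values_b) -> float:
    """ROC area (AUC) with A as the first group and midrank tie handling:
    ``(#pairs a>b + 0.5 #ties) / (|A||B|)``.  Above 0.5 means group A's
    values are larger."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both trial groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    return float((r_a - a.size * (a.size + 1) / 2) / (a.size * b.size))


def _auc_from_ranks(ranks: np.ndarray, a_idx: np.ndarray, n_a: int,
                    n_b: int) -> np.ndarray:
    r_a = ranks[a_idx].sum(axis=-1)
    return (r_a - n_a * (n_a + 1) / 2) / (n_a * n_b)


def permutation_significance(
    values_a,
    values_b,
    n_perm: int = 1000,
    seed=None,
) -> float:
    """Two-sided permutation p-value for the choice probability.

    Group labels are permuted ``n_perm`` times; the add-one estimate
    ``p = (1 + #{|null - 0.5| >= |obs - 0.5|}) / (n_perm + 1)`` avoids
    p = 0 at finite permutation counts.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    obs = choice_probability(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = pooled.size
    perm = np.argsort(rng.random((n_perm, n)), axis=1)[:, : a.size]
    null = _auc_from_ranks(ranks, perm, a.size, b.size)
    more_extreme = np.abs(null - 0.5) >= np.abs(obs - 0.5) - 1e-12
    return float((1 + more_extreme.sum()) / (n_perm + 1))


def choice_probability_series(
    rec: ContinuousRecording,
    channel: str,
    onsets_a: np.ndarray,
    onsets_b: np.ndarray,
    lags_s: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed=None,
) -> ChoiceProbabilitySeries:
    """Choice probability and permutation significance over the lag grid."""
    lags = DEFAULT_LAGS_S if lags_s is None else np.asarray(lags_s, float)
    ss = as_seed_sequence(seed).spawn(len(lags))
    auc = np.empty(len(lags))
    p = np.ones(len(lags))
    for i, lag in enumerate(lags):
        va = windowed_amplitude(rec, channel, onsets_a, lag)
        vb = windowed_amplitude(rec, channel, onsets_b, lag)
        auc[i] = choice_probability(va, vb)
        if n_perm:
            p[i] = permutation_significance(va, vb, n_perm=n_perm, seed=ss[i])
    sig = p < alpha if n_perm else np.zeros(len(lags), dtype=bool)
    return ChoiceProbabilitySeries(lags, auc, p, sig, alpha)
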