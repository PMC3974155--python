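"""Laminar LFP layer profiles, cosine similarity, and stimulation analysis.

The *layer profile* is the trial-averaged mean LFP in a 60 ms window
centred on the peak of the population bursting response, one value per
laminar channel ordered by depth (a 32-dimension vector).  Profile
similarity between trial groups is the cosine of the angle between the two
vectors (amplitude-free), tested by permuting the 32 dimensions of one
vector (1000 times, two-sided).

For electrical-stimulation sessions, the momentary 32-channel LFP vector is
projected onto the task-derived reference profile at every millisecond
(scalar projection), normalised by its peak magnitude outside a +/-5 ms
artifact window around the pulse; the onset of significant similarity is
the first post-pulse time sustained above the permutation band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ContinuousRecording, StimEvents, ms_to_s
from .burst import PSTH

__all__ = [
    "LayerProfile",
    "SimilaritySeries",
    "burst_peak_time",
    "extract_layer_profile",
    "cosine_similarity",
    "profile_permutation_p",
    "normalize_profile",
    "stim_similarity_series",
    "similarity_onset",
]


@dataclass(frozen=True)
class LayerProfile:
    """Window-averaged LFP per laminar channel, ordered superficial->deep."""

    values: np.ndarray
    window_ms: tuple[float, float]
    n_trials: int
    normalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if self.values.shape != (32,):
            raise ValueError("layer profile must have exactly 32 dimensions")
        if self.normalized and not np.isclose(self.values.max(), 1.0):
            raise ValueError("normalized profile must peak at +1")


@dataclass(frozen=True)
class SimilaritySeries:
    """Normalized scalar-projection similarity around stimulation pulses."""

    t_ms: np.ndarray
    s_norm: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    onset_ms: float | None
    artifact_exclusion_ms: float


def burst_peak_time(psth: PSTH, search_ms: tuple[float, float] = (0.0, 300.0)
                    ) -> float:
    """Peri-stimulus time (ms) of the population bursting peak: argmax of
    the (smoothed) PSTH within the search window; earliest bin on ties."""
    centers = psth.bin_centers_ms
    m = (centers >= search_ms[0]) & (centers < search_ms[1])
    if not m.any():
        raise ValueError("search window contains no PSTH bins")
    rate = psth.rate_hz[m]
    if np.allclose(rate, rate[0]):
        raise ValueError("flat PSTH: bursting peak undefined")
    return float(centers[m][np.argmax(rate)])


def extract_layer_profile(
    rec: ContinuousRecording,
    onsets_s: np.ndarray,
    center_ms: float,
    width_ms: float = 60.0,
) -> LayerProfile:
    """Trial-averaged mean LFP per laminar channel in the half-open window
    [center - width/2, center + width/2) ms around tone onset."""
    onsets_s = np.asarray(onsets_s, dtype=float)
    if onsets_s.size == 0:
        raise ValueError("layer profile requires at least one trial")
    lam = rec.laminar_by_depth()
    a = ms_to_s(center_ms - width_ms / 2)
    w = int(round(ms_to_s(width_ms) * rec.fs_hz))
    i0 = np.floor((onsets_s + a - rec.t0_s) * rec.fs_hz + 1e-9).astype(int)
    if i0.min() < 0 or i0.max() + w > rec.n_samples:
        raise ValueError("profile window outside recorded span")
    vals = lam[:, i0[:, None] + np.arange(w)[None, :]].mean(axis=(1, 2))
    return LayerProfile(
        values=vals,
        window_ms=(center_ms - width_ms / 2, center_ms + width_ms / 2),
        n_trials=onsets_s.size,
    )


def _vec(a) -> np.ndarray:
    return a.values if isinstance(a, LayerProfile) else np.asarray(a, float)


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two layer-profile vectors: 1 at 0 deg,
    -1 at 180 deg, amplitude-free."""
    va, vb = _vec(a), _vec(b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


def profile_permutation_p(a, b, n_perm: int = 1000, seed=None) -> float:
    """Two-sided permutation p for the cosine similarity, permuting the 32
    dimensions of the second vector; add-one estimate."""
    va, vb = _vec(a), _vec(b)
    obs = cosine_similarity(va, vb)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = cosine_similarity(va, vb[rng.permutation(vb.size)])
    more_extreme = np.abs(null) >= np.abs(obs) - 1e-12
    return float((1 + more_extreme.sum()) / (n_perm + 1))


def normalize_profile(a: LayerProfile) -> LayerProfile:
    """Scale a profile by its peak positive value (deep positive peak -> 1)."""
    v = a.values
    if v.max() <= 0:
        raise ValueError("profile has no positive entry; peak normalisation "
                         "undefined")
    return LayerProfile(values=v / v.max(), window_ms=a.window_ms,
                        n_trials=a.n_trials, normalized=True)


def stim_similarity_series(
    rec: ContinuousRecording,
    stim: StimEvents,
    reference: LayerProfile,
    t_range_ms: tuple[float, float] = (-20.0, 100.0),
    artifact_exclusion_ms: float = 5.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    min_run_ms: float = 5.0,
) -> SimilaritySeries:
    """Normalized scalar-projection similarity around stimulation pulses.

    At each 1 ms time point the pulse-averaged 32-channel LFP vector is
    projected onto the unit-norm reference profile; the series (and its
    per-time-point permutation band from permuting the reference's 32
    dimensions) is normalised by the series' peak magnitude outside the
    artifact window.
    """
    ref = _vec(reference)
    nref = np.linalg.norm(ref)
    if nref == 0:
        raise ValueError("zero reference profile")
    if len(stim) == 0:
        raise ValueError("no stimulation pulses")
    lam = rec.laminar_by_depth()
    step = int(round(rec.fs_hz / 1000.0))  # samples per ms
    t_ms = np.arange(t_range_ms[0], t_range_ms[1] + 0.5)
    offs = (t_ms * step).astype(int)
    p0 = np.round((stim.pulse_times_s - rec.t0_s) * rec.fs_hz).astype(int)
    idx = p0[:, None] + offs[None, :]
    if idx.min() < 0 or idx.max() >= rec.n_samples:
        raise ValueError("similarity window outside recorded span")
    # pulse-averaged momentary depth vector, (32, n_times)
    v = lam[:, idx].mean(axis=1)
    s = ref @ v / nref

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, t_ms.size))
    for k in range(n_perm):
        null[k] = ref[rng.permutation(32)] @ v / nref

    outside = np.abs(t_ms) > artifact_exclusion_ms
    peak = np.abs(s[outside]).max()
    if peak == 0:
        peak = 1.0
    s_norm = s / peak
    band_lower = np.quantile(null, alpha / 2, axis=0) / peak
    band_upper = np.quantile(null, 1 - alpha / 2, axis=0) / peak
    series = SimilaritySeries(
        t_ms=t_ms, s_norm=s_norm, band_lower=band_lower,
        band_upper=band_upper, onset_ms=None,
        artifact_exclusion_ms=artifact_exclusion_ms,
    )
    onset = similarity_onset(series, min_run_ms=min_run_ms)
    return SimilaritySeries(
        t_ms=t_ms, s_norm=s_norm, band_lower=band_lower,
        band_upper=band_upper, onset_ms=onset,
        artifact_exclusion_ms=artifact_exclusion_ms,
    )


def similarity_onset(series: SimilaritySeries,
                     min_run_ms: float = 5.0) -> float | None:
    """First post-pulse time at which the similarity exceeds the upper
    permutation band for at least ``min_run_ms`` consecutive milliseconds,
    excluding the artifact window; ``None`` if never sustained."""
    t = series.t_ms
    eligible = t > series.artifact_exclusion_ms
    above = (series.s_norm > series.band_upper) & eligible
    need = int(round(min_run_ms))
    run = 0
    for i in range(t.size):
        run = run + 1 if above[i] else 0
        if run >= need:
            return float(t[i - need + 1])
    return None
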