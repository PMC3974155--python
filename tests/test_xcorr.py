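"""Concatenated flanked spike-EEG cross-correlation and lead/lag analyses."""

import numpy as np
import pytest

from bferp.burst import BurstMetrics, bursting_index, population_bursting_amplitude
from bferp.io import SpikeTrain
from bferp.xcorr import (
    CrossCorrResult,
    DEFAULT_LAGS_MS,
    FLANK_MS,
    average_significant_xcorr,
    build_concatenated_pair,
    concatenate_flanked,
    concatenated_xcorr,
    cross_correlate_unit,
    delay_metric_correlations,
    normalize_by_session_min,
    select_trials,
    trial_matrices,
    xcorr_permutation,
)
from conftest import make_events, make_recording


def brute_force_corr(a, b, lags):
    """Direct O(lags x length) correlation oracle via explicit sums."""
    out = []
    n = len(a)
    for lag in lags:
        if lag >= 0:
            x, y = a[: n - lag] if lag else a, b[lag:]
        else:
            x, y = a[-lag:], b[:lag]
        m = len(x)
        sx, sy = sum(x), sum(y)
        sxy = sum(xi * yi for xi, yi in zip(x, y))
        sxx = sum(xi * xi for xi in x)
        syy = sum(yi * yi for yi in y)
        num = sxy - sx * sy / m
        den = np.sqrt((sxx - sx * sx / m) * (syy - sy * sy / m))
        out.append(num / den)
    return np.array(out)


# ---- trial selection -----------------------------------------------------


def test_select_trials_threshold_example():
    pop = np.array([10.0, 50.0, 100.0])
    hits = np.array([False, False, True])  # hit mean 100 -> threshold 30
    np.testing.assert_array_equal(select_trials(pop, hits),
                                  [False, True, True])


def test_select_trials_zero_threshold_keeps_all():
    pop = np.array([1.0, 2.0, 3.0])
    hits = np.array([True, False, False])
    assert select_trials(pop, hits, threshold_frac=0.0).all()


def test_select_trials_degenerate():
    assert not select_trials(np.zeros(4), np.array([True] * 4)).any()
    with pytest.raises(ValueError, match="hit"):
        select_trials(np.ones(3), np.zeros(3, bool))


# ---- concatenation layout ------------------------------------------------


def test_concatenated_layout_two_trials():
    """Shared-flank layout: flank, trial, flank, trial, flank = 640 samples
    for two 170 ms trials with 100 ms flanks."""
    mat = np.arange(2 * 170.0).reshape(2, 170)
    seq = concatenate_flanked(mat, -7.0)
    assert seq.size == 100 + 170 + 100 + 170 + 100 == 640
    np.testing.assert_array_equal(seq[:100], -7.0)
    np.testing.assert_array_equal(seq[100:270], mat[0])
    np.testing.assert_array_equal(seq[270:370], -7.0)
    np.testing.assert_array_equal(seq[370:540], mat[1])
    np.testing.assert_array_equal(seq[540:], -7.0)


def test_flank_values_are_means(sim_session):
    tr = sim_session.events
    st = sim_session.spikes[0]
    sm, em, sf, ef = trial_matrices(st, sim_session.continuous, "FrEEG",
                                    tr.onset_s)
    assert sf == pytest.approx(st.mean_rate_hz / 1000.0)
    # EEG flank equals the mean of the (rectified) channel
    x = sim_session.continuous.channel("FrEEG").astype(float)
    assert abs(ef) == pytest.approx(abs(x.mean()), rel=1e-6)
    assert sm.shape == em.shape == (len(tr), 170)


def test_spike_counts_binned_correctly():
    ev = make_events("sso", t_first_s=1.0)
    onset = ev.onset_s[2]
    st = SpikeTrain("u", onset + np.array([0.0005, 0.0504, 0.0506, 0.1699]),
                    (0.0, 20.0))
    rec = make_recording(np.zeros((1, 20000), dtype=np.float32))
    sm, _, _, _ = trial_matrices(st, rec, "FrEEG", np.array([onset]),
                                 rectify=False)
    assert sm[0, 0] == 1 and sm[0, 50] == 2 and sm[0, 169] == 1
    assert sm.sum() == 4


# ---- cross-correlation ---------------------------------------------------


def test_shifted_copy_recovers_lag_and_unit_r():
    rng = np.random.default_rng(0)
    spike_seq = np.convolve(rng.random(800), np.ones(8) / 8, mode="same")
    eeg_seq = np.empty_like(spike_seq)
    eeg_seq[10:] = spike_seq[:-10]
    eeg_seq[:10] = spike_seq.mean()
    res = concatenated_xcorr(spike_seq, eeg_seq, np.arange(-50, 51))
    assert res.best_lag_ms == 10
    assert res.max_r > 0.999


def test_xcorr_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    for n in (500, 2000, 10_000):
        a = rng.normal(size=n)
        b = rng.normal(size=n) + 0.3 * a
        lags = np.arange(-50, 51, 10)
        res = concatenated_xcorr(a, b, lags)
        np.testing.assert_allclose(res.r, brute_force_corr(a, b, lags),
                                   atol=1e-12)


def test_xcorr_affine_invariance():
    rng = np.random.default_rng(2)
    a = rng.normal(size=1000)
    b = rng.normal(size=1000) + 0.5 * a
    lags = np.arange(-20, 21)
    r0 = concatenated_xcorr(a, b, lags).r
    r1 = concatenated_xcorr(a, 3.5 * b + 11.0, lags).r
    np.testing.assert_allclose(r0, r1, atol=1e-12)


def test_flanks_at_sequence_means_add_no_covariance():
    """When the flank constants equal the segment means the flank positions
    contribute exactly zero to the lag-0 covariance."""
    rng = np.random.default_rng(3)
    sm = rng.normal(size=(4, 170))
    em = rng.normal(size=(4, 170))
    fa, fb = sm.mean(), em.mean()
    a = concatenate_flanked(sm, fa)
    b = concatenate_flanked(em, fb)
    in_flank = np.ones(a.size, bool)
    for k in range(4):
        start = FLANK_MS + k * 270
        in_flank[start : start + 170] = False
    cov_total = ((a - a.mean()) * (b - b.mean())).sum()
    cov_trials = ((a - a.mean()) * (b - b.mean()))[~in_flank].sum()
    flank_contrib = (fa - a.mean()) * (fb - b.mean()) * in_flank.sum()
    assert cov_total - cov_trials == pytest.approx(flank_contrib, abs=1e-9)
    assert abs(flank_contrib) < 1e-9 * np.abs(cov_total) + 1e-9


def test_degenerate_sequence_rejected():
    with pytest.raises(ValueError, match="constant"):
        concatenated_xcorr(np.ones(300), np.random.default_rng(4).random(300),
                           np.arange(-5, 6))


# ---- permutation envelope ------------------------------------------------


def test_permutation_deterministic_and_copy_significant(sim_session):
    tr = sim_session.events
    st = sim_session.spikes[0]
    pop = population_bursting_amplitude(sim_session.spikes, tr)
    keep = select_trials(pop, tr.is_hit)
    sm, em, sf, ef = trial_matrices(st, sim_session.continuous, "FrEEG",
                                    tr.onset_s[keep])
    lo1, up1 = xcorr_permutation(sm, em, sf, ef, n_perm=100, seed=5)
    lo2, up2 = xcorr_permutation(sm, em, sf, ef, n_perm=100, seed=5)
    np.testing.assert_array_equal(lo1, lo2)
    np.testing.assert_array_equal(up1, up2)

    res = cross_correlate_unit(st, sim_session.continuous, "FrEEG",
                               tr.onset_s[keep], n_perm=100, seed=6)
    assert res.significant_anywhere
    # true coupling exceeds the envelope at the best lag itself
    i = np.flatnonzero(res.lags_ms == res.best_lag_ms)[0]
    assert res.r[i] > res.band_upper[i]


def test_permuted_trials_stay_inside_max_envelope(sim_session):
    """Null data (EEG trial order shuffled before pairing) stays inside the
    max-statistic envelope."""
    rng = np.random.default_rng(7)
    tr = sim_session.events
    st = sim_session.spikes[0]
    sm, em, sf, ef = trial_matrices(st, sim_session.continuous, "FrEEG",
                                    tr.onset_s)
    em_null = em[rng.permutation(em.shape[0])]
    lo, up = xcorr_permutation(sm, em_null, sf, ef, n_perm=200, alpha=0.01,
                               seed=8, band="max")
    r = concatenated_xcorr(concatenate_flanked(sm, sf),
                           concatenate_flanked(em_null, ef)).r
    assert np.all(r <= up + 1e-12) and np.all(r >= lo - 1e-12)


# ---- population summaries ------------------------------------------------


def _mk_result(uid, best_lag, max_r, sig=True):
    lags = np.arange(-50, 51)
    r = np.zeros(lags.size)
    r[lags == best_lag] = max_r
    return CrossCorrResult(uid, lags, r, None, None, best_lag, max_r, sig)


def test_average_significant_xcorr():
    a = _mk_result("a", 5, 0.5)
    b = _mk_result("b", -5, 0.3, sig=False)
    np.testing.assert_allclose(average_significant_xcorr([a, b]), a.r)
    mirrored = CrossCorrResult("c", a.lags_ms, -a.r, None, None, -5, 0.0,
                               True)
    np.testing.assert_allclose(average_significant_xcorr([a, mirrored]), 0.0)
    with pytest.raises(ValueError):
        average_significant_xcorr([b])


def test_delay_metric_correlations_sign_convention():
    """Units with larger leads (positive lags) have larger max r: positive
    association."""
    results = [_mk_result(f"u{i}", lag, 0.1 + 0.05 * lag)
               for i, lag in enumerate([0, 2, 4, 6, 8])]
    metrics = [BurstMetrics(f"u{i}", 20.0, 4.0 + 0.1 * i, 3.0 + i, True)
               for i in range(5)]
    out = delay_metric_correlations(results, metrics)
    assert out["best_lag_vs_max_r"][0] == pytest.approx(1.0)
    assert out["best_lag_vs_bursting_index"][0] == pytest.approx(1.0)

    const = [_mk_result(f"u{i}", 3, 0.2) for i in range(5)]
    with pytest.raises(ValueError, match="constant"):
        delay_metric_correlations(const, metrics)


def test_normalize_by_session_min():
    np.testing.assert_allclose(
        normalize_by_session_min([0.2, 0.4], ["s1", "s1"]), [1.0, 2.0])
    np.testing.assert_allclose(normalize_by_session_min([-0.3], ["s1"]),
                               [1.0])
    with pytest.raises(ValueError, match="zero"):
        normalize_by_session_min([0.0, 0.5], ["s1", "s1"])


def test_graded_ensemble_strong_neurons_lead(sim_session):
    """Forward-model prediction: stronger-bursting neurons lead the ERP
    (their early bursts precede the population-average drive), so the best
    lag correlates positively with the bursting index."""
    tr = sim_session.events
    pop = population_bursting_amplitude(sim_session.spikes, tr)
    keep = select_trials(pop, tr.is_hit)
    onsets = tr.onset_s[keep]
    results, metrics = [], []
    for u in sim_session.spikes:
        results.append(cross_correlate_unit(u, sim_session.continuous,
                                            "FrEEG", onsets, n_perm=0))
        metrics.append(bursting_index(u, tr))
    lags = np.array([r.best_lag_ms for r in results])
    assert lags[0] > lags[-1]  # strongest neuron leads the weakest
    out = delay_metric_correlations(results, metrics)
    assert out["best_lag_vs_bursting_index"][0] > 0.5
    assert out["best_lag_vs_max_r"][0] > 0.5
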