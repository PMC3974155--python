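"""Forward-model generator: trial grammar, intensities, Poisson realisation,
renderer linearity, and determinism."""

import numpy as np
import pytest

from bferp.io import TrialEvents
from bferp.synth import (
    ForwardModelParams,
    default_layer_profile,
    generate_trial_sequence,
    neuron_intensity,
    render_erp,
    render_laminar_lfp,
    simulate_bf_ensemble,
    simulate_stim_session,
    simulate_session,
    trial_scales,
)


# ---- trial grammar -------------------------------------------------------


def test_trial_sequence_grammar():
    tr = generate_trial_sequence(50, 0.8, seed=1)
    np.testing.assert_allclose(np.diff(tr.onset_s), 2.0)
    odd = np.flatnonzero(tr.is_oddball)
    gaps = np.diff(odd) - 1
    assert set(gaps) <= set(range(2, 7))
    # oddball-to-oddball gaps are 6-14 s
    odd_dt = np.diff(tr.onset_s[tr.is_oddball])
    assert odd_dt.min() >= 6.0 and odd_dt.max() <= 14.0
    assert set(tr.outcome[tr.is_oddball]) <= {"hit", "miss"}
    assert set(tr.outcome[~tr.is_oddball]) == {"none"}


def test_trial_sequence_no_oddballs_only_standards():
    tr = generate_trial_sequence(0, 0.5, seed=2)
    assert tr.is_oddball.sum() == 0
    np.testing.assert_allclose(np.diff(tr.onset_s), 2.0)


def test_trial_sequence_mean_intervening_standards():
    tr = generate_trial_sequence(1000, 0.5, seed=3)
    gaps = np.diff(np.flatnonzero(tr.is_oddball)) - 1
    # uniform on {2..6}: mean 4, var 2
    se = np.sqrt(2.0 / gaps.size)
    assert abs(gaps.mean() - 4.0) < 3 * se


def test_hit_labelling_rate():
    tr = generate_trial_sequence(1000, 0.8, seed=4)
    n = tr.is_oddball.sum()
    se = np.sqrt(0.8 * 0.2 / n)
    assert abs(tr.is_hit.sum() / n - 0.8) < 3 * se


# ---- intensities ---------------------------------------------------------


def test_intensity_flat_baseline_at_zero_scale(default_params):
    f = neuron_intensity(default_params, 0, trial_scale=0.0)
    t = np.linspace(-0.1, 0.4, 100)
    np.testing.assert_allclose(f(t), default_params.baseline_rate_hz)


def test_intensity_peak_ratio_and_stagger(default_params):
    p = default_params
    f1 = neuron_intensity(p, 0, 1.0)
    f10 = neuron_intensity(p, 9, 1.0)
    t = np.arange(0, 0.4, 1e-4)
    peak1 = f1(t).max() - p.baseline_rate_hz
    peak10 = f10(t).max() - p.baseline_rate_hz
    assert peak1 / peak10 == pytest.approx(100.0 / 20.0, rel=1e-6)
    # consecutive neurons' onsets (and hence peaks) stagger by 5 ms
    for i in range(9):
        assert (p.neuron_onset_ms(i + 1) - p.neuron_onset_ms(i)
                ) == pytest.approx(5.0)
    assert t[np.argmax(f10(t))] - t[np.argmax(f1(t))] == pytest.approx(
        0.045, abs=1e-3)


def test_intensity_rejects_negative_scale(default_params):
    with pytest.raises(ValueError):
        neuron_intensity(default_params, 0, -0.5)


# ---- Poisson ensemble ----------------------------------------------------


def test_ensemble_deterministic_under_seed(default_params):
    tr = generate_trial_sequence(5, 1.0, seed=5)
    a = simulate_bf_ensemble(default_params, tr, seed=6)
    b = simulate_bf_ensemble(default_params, tr, seed=6)
    c = simulate_bf_ensemble(default_params, tr, seed=7)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.spikes_s, y.spikes_s)
    assert not np.array_equal(a[0].spikes_s, c[0].spikes_s)


def test_zero_duration_session_gives_empty_trains(default_params):
    empty = TrialEvents([], [], [], [], [])
    assert simulate_bf_ensemble(default_params, empty, seed=0) == []


def test_expected_window_count_matches_intensity_integral(default_params):
    """Mean spike count in [50, 200) ms of hit trials equals the numeric
    integral of the configured intensity (within 3 SE, Poisson)."""
    p = default_params
    tr = generate_trial_sequence(400, 1.0, seed=8)
    sp = simulate_bf_ensemble(p, tr, seed=9)
    hits = tr.onset_s[tr.is_hit]
    t = np.linspace(0.05, 0.2, 3001)
    expected = np.trapezoid(neuron_intensity(p, 0, 1.0)(t), t)
    counts = [sp[0].count_in_window(h + 0.05, h + 0.2) for h in hits]
    se = np.sqrt(expected / len(hits))
    assert abs(np.mean(counts) - expected) < 3 * se


def test_psth_of_simulated_hits_matches_intensity(default_params):
    """Empirical PSTH of 2000 simulated hit trials tracks the configured
    intensity within 3 SE per 10 ms bin."""
    from bferp.burst import compute_psth

    p = ForwardModelParams(n_neurons=1, peak_rates_hz=(100.0,))
    tr = generate_trial_sequence(400, 1.0, seed=10)
    # five repeats of the ensemble give 2000 independent hit trials
    rates = []
    n_hits = int(tr.is_hit.sum())
    for rep in range(5):
        sp = simulate_bf_ensemble(p, tr, seed=100 + rep)
        psth = compute_psth(sp[0], tr.onset_s[tr.is_hit],
                            window_ms=(0, 300), bin_ms=10.0)
        rates.append(psth.rate_hz)
    n_trials = 5 * n_hits
    rate = np.mean(rates, axis=0)
    centers = psth.bin_centers_ms / 1000.0
    f = neuron_intensity(p, 0, 1.0)
    # bin-averaged intensity (the binned expectation of the point process)
    fine = np.linspace(0, 0.3, 6001)
    lam = f(fine)
    lam_bin = np.array([
        lam[(fine >= c - 0.005) & (fine < c + 0.005)].mean() for c in centers
    ])
    se = np.sqrt(lam_bin / (n_trials * 0.010))
    assert np.all(np.abs(rate - lam_bin) < 3 * se)


# ---- renderers -----------------------------------------------------------


def test_erp_zero_scale_noise_free_is_flat_zero(default_params):
    p = ForwardModelParams(attenuated_scale=0.0)
    tr = generate_trial_sequence(3, 0.0, seed=11)  # all misses/standards
    rec = render_erp(p, tr, mode="noise_free_intensity")
    assert np.all(rec.channel("FrEEG") == 0.0)


@pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0])
def test_renderers_linear_in_trial_scale(alpha):
    tr = generate_trial_sequence(4, 0.0, seed=12)  # all trials attenuated
    ref = ForwardModelParams(attenuated_scale=1.0)
    scaled = ForwardModelParams(attenuated_scale=alpha)
    e1 = render_erp(ref, tr, mode="noise_free_intensity").channel("FrEEG")
    ea = render_erp(scaled, tr, mode="noise_free_intensity").channel("FrEEG")
    np.testing.assert_allclose(ea, alpha * e1, rtol=1e-5, atol=1e-5)
    l1 = render_laminar_lfp(ref, tr, mode="noise_free_intensity")
    la = render_laminar_lfp(scaled, tr, mode="noise_free_intensity")
    np.testing.assert_allclose(la.samples, alpha * l1.samples,
                               rtol=1e-4, atol=1e-4)


def test_erp_extremum_lags_intensity_peak_by_delay():
    """Shift theorem: with a symmetric kernel the noise-free single-neuron
    ERP extremum occurs exactly erp_delay_ms after the intensity peak."""
    p = ForwardModelParams(n_neurons=1, peak_rates_hz=(100.0,))
    tr = generate_trial_sequence(1, 1.0, seed=13, lead_standards=0,
                                 tail_standards=0)
    rec = render_erp(p, tr, mode="noise_free_intensity")
    erp = rec.channel("FrEEG")
    t_ext_ms = np.argmin(erp)  # negative polarity -> minimum
    onset_ms = tr.onset_s[0] * 1000
    t_peak_ms = onset_ms + p.neuron_peak_time_ms(0)
    assert t_ext_ms - t_peak_ms == pytest.approx(p.erp_delay_ms, abs=0.5)


def test_laminar_profile_proportionality(noisefree_session, default_params):
    """Noise-free: the window-averaged 32-channel response is proportional
    to the true laminar profile; a zero profile entry gives a zero channel."""
    lam = noisefree_session.continuous.laminar_by_depth()
    tr = noisefree_session.events
    onset = tr.onset_s[tr.is_hit][0]
    w = slice(int((onset + 0.08) * 1000), int((onset + 0.14) * 1000))
    resp = np.asarray(lam[:, w]).mean(axis=1)
    prof = default_params.profile
    cos = resp @ prof / np.linalg.norm(resp) / np.linalg.norm(prof)
    assert cos == pytest.approx(1.0, abs=1e-6)  # float32 sample storage

    zeroed = np.array(default_params.profile)
    zeroed[0] = 0.0
    p2 = ForwardModelParams(layer_profile_true=tuple(zeroed))
    tr2 = generate_trial_sequence(2, 1.0, seed=14)
    rec2 = render_laminar_lfp(p2, tr2, mode="noise_free_intensity")
    assert np.all(rec2.laminar_by_depth()[0] == 0.0)


# ---- stimulation sessions ------------------------------------------------


def test_stim_pulses_every_2s(default_params):
    stim, rec = simulate_stim_session(default_params, 10, seed=15)
    np.testing.assert_allclose(np.diff(stim.pulse_times_s), 2.0)
    assert rec.laminar_by_depth().shape[0] == 32


def test_stim_evoked_profile_and_latency(default_params):
    """Noise-free: the evoked depth pattern matches the true profile and
    begins exactly stim_latency_ms after the pulse."""
    stim, rec = simulate_stim_session(default_params, 3, seed=16,
                                      noise_sd_uv=0.0)
    lam = rec.laminar_by_depth()
    i = int(stim.pulse_times_s[0] * 1000)
    lat = int(default_params.stim_latency_ms)
    assert np.all(lam[:, i + 6 : i + lat] == 0.0)  # after artifact, pre-onset
    v = lam[:, i + lat + 20]  # mid-bump depth vector
    prof = default_params.profile
    assert v @ prof / np.linalg.norm(v) / np.linalg.norm(prof) == (
        pytest.approx(1.0, abs=1e-6))


# ---- whole sessions ------------------------------------------------------


def test_simulated_session_is_valid_and_deterministic(default_params):
    a = simulate_session(default_params, n_oddballs=4, hit_rate=1.0, seed=17)
    b = simulate_session(default_params, n_oddballs=4, hit_rate=1.0, seed=17)
    np.testing.assert_array_equal(a.continuous.samples, b.continuous.samples)
    for x, y in zip(a.spikes, b.spikes):
        np.testing.assert_array_equal(x.spikes_s, y.spikes_s)
    assert a.continuous.roles.count("laminar_lfp") == 32
    assert a.continuous.roles.count("frontal_eeg") == 1


def test_trial_scales_hit_vs_attenuated(default_params):
    tr = generate_trial_sequence(10, 0.5, seed=18)
    s = trial_scales(default_params, tr)
    assert set(s[tr.is_hit]) == {1.0}
    assert set(s[~tr.is_hit]) == {default_params.attenuated_scale}


def test_default_layer_profile_shape():
    prof = default_layer_profile()
    assert prof.shape == (32,)
    assert np.linalg.norm(prof) == pytest.approx(1.0)
    assert prof[20:30].max() > 0  # deep channels positive
    assert prof.argmax() > 16
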