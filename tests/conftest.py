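import numpy as np
import pytest

from bferp.io import ContinuousRecording, Session, SpikeTrain, TrialEvents
from bferp.synth import ForwardModelParams, simulate_session


def make_events(tones, t_first_s=5.0, outcomes=None):
    """TrialEvents from a tone-letter string ('o'/'s'), onsets 2 s apart.

    Oddballs default to hits.
    """
    tone = np.array(
        ["oddball" if c == "o" else "standard" for c in tones], dtype=object
    )
    if outcomes is None:
        outcome = np.where(tone == "oddball", "hit", "none").astype(object)
    else:
        outcome = np.asarray(outcomes, dtype=object)
    n = len(tone)
    return TrialEvents(
        trial_id=np.arange(n),
        onset_s=t_first_s + 2.0 * np.arange(n),
        tone=tone,
        outcome=outcome,
        response_time_s=np.where(outcome == "hit", 0.5, np.nan),
    )


def make_recording(samples, fs_hz=1000.0, roles=None, t0_s=0.0):
    samples = np.atleast_2d(samples)
    n_ch = samples.shape[0]
    roles = roles or ["frontal_eeg"] + ["control_eeg"] * (n_ch - 1)
    ranks = [None] * n_ch
    labels = []
    for i, r in enumerate(roles):
        labels.append({"frontal_eeg": "FrEEG", "control_eeg": f"Ctrl{i}"}.get(
            r, f"LFP{i:02d}"))
    if roles.count("laminar_lfp"):
        lam = [i for i, r in enumerate(roles) if r == "laminar_lfp"]
        for k, i in enumerate(lam):
            ranks[i] = k + 1
    return ContinuousRecording(
        fs_hz=fs_hz, labels=labels, roles=roles, depth_rank=ranks,
        samples=samples, t0_s=t0_s,
    )


@pytest.fixture(scope="session")
def default_params():
    return ForwardModelParams()


@pytest.fixture(scope="session")
def sim_session(default_params):
    """Shared mid-sized synthetic session (10-neuron forward model,
    spike-driven signals with noise)."""
    return simulate_session(
        default_params, n_oddballs=25, hit_rate=0.7, seed=42,
        mode="spike_driven",
    )


@pytest.fixture(scope="session")
def noisefree_session(default_params):
    """Noise-free session: signals rendered from exact intensities."""
    return simulate_session(
        default_params, n_oddballs=12, hit_rate=0.75, seed=43,
        mode="noise_free_intensity",
    )


@pytest.fixture()
def minimal_session():
    """Tiny hand-built session: 2 oddballs, 5 standards, 1 unit,
    3-channel signal."""
    events = make_events("ssosso", outcomes=None)
    # 2 oddballs separated by 2 standards; 4 standards total -> adjust:
    events = make_events("ssossso")
    rng = np.random.default_rng(7)
    span = (0.0, events.onset_s[-1] + 2.0)
    spikes = [SpikeTrain("u01", np.round(np.sort(
        rng.uniform(span[0], span[1], 40)), 6), span)]
    rec = make_recording(
        rng.normal(0, 1, (3, int(span[1] * 1000))).astype(np.float32))
    return Session(events=events, spikes=spikes, continuous=rec, stim=None)
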