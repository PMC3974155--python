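"""Simulate a synthetic oddball session and inspect its structure.

The forward model drives 10 basal-forebrain bursting neurons (peak rates
graded 100 -> 20 spikes/s, onsets staggered 5 ms) whose summed, delayed
activity generates a negative frontal ERP and a deep-positive laminar LFP.
"""

import numpy as np

from bferp import ForwardModelParams, simulate_session, write_session

params = ForwardModelParams()
session = simulate_session(params, n_oddballs=20, hit_rate=0.75, seed=1)

tr = session.events
print(f"trials: {len(tr)} ({int(tr.is_oddball.sum())} oddballs, "
      f"{int((~tr.is_oddball).sum())} standards)")
print(f"hit rate: {tr.is_hit.sum() / tr.is_oddball.sum():.2f}")
for u in session.spikes[:3]:
    print(f"unit {u.unit_id}: {len(u)} spikes, "
          f"session mean {u.mean_rate_hz:.2f} Hz")
rec = session.continuous
print(f"recording: {len(rec.labels)} channels at {rec.fs_hz:.0f} Hz, "
      f"{rec.duration_s:.0f} s")

# The frontal ERP is negative-going: the mean trace right after hit tones
# dips well below the pre-tone baseline.
hit = tr.onset_s[tr.is_hit]
idx = (hit[:, None] * 1000).astype(int) + np.arange(0, 300)[None, :]
erp = rec.channel("FrEEG")[idx].mean(axis=0)
print(f"hit-trial ERP minimum: {erp.min():.1f} uV at {erp.argmin()} ms "
      "(negative deflection ~100-110 ms after tone onset)")

write_session(session, "scratch/session_bundle")
print("bundle written to scratch/session_bundle/ "
      "(events.tsv, spikes.tsv, continuous.bin/json)")
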