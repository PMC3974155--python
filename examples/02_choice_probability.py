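"""ROC choice probability: does the frontal EEG discriminate trial types?

For each 10 ms lag in [-0.2, 0.4] s the per-trial EEG amplitude (100 ms
window) is compared between oddball and standard trials by the area under
the ROC curve.  Values significantly below 0.5 mean the EEG is *more
negative* on oddball trials — the frontal ERP signature.  The control
channel carries no task-locked signal and stays near 0.5.
"""

import numpy as np

from bferp import ForwardModelParams, simulate_session
from bferp.choiceprob import choice_probability_series

session = simulate_session(ForwardModelParams(), n_oddballs=25,
                           hit_rate=0.75, seed=2)
tr = session.events
odd, std = tr.onset_s[tr.is_oddball], tr.onset_s[~tr.is_oddball]

for label in ("FrEEG", "CtrlEEG"):
    series = choice_probability_series(session.continuous, label, odd, std,
                                       n_perm=500, alpha=0.01, seed=3)
    sig = series.significant
    i = np.argmax(np.abs(series.auc - 0.5))
    print(f"{label}: {sig.sum()}/{sig.size} significant lags; most extreme "
          f"AUC {series.auc[i]:.3f} at lag {series.lag_s[i]*1000:.0f} ms")

print("frontal AUC << 0.5 in the burst window = oddball trials carry the "
      "deeper negative ERP; control channel shows no discrimination")
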