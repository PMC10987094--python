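"""Recover the injected contrast evidence from synthetic EEG.

Simulates 40 trials of frequency-tagged EEG, runs the preprocessing
chain (filter, average reference, epoching, artifact rejection, CSD) and
extracts the marginal SSVEP (target minus non-target tag amplitude) in
the 680-975 ms window. With a 12% contrast differential the marginal
SSVEP should be positive on nearly every trial.
"""

import numpy as np

from ssveptag.containers import default_montage
from ssveptag.paradigm import generate_session
from ssveptag.preprocess import preprocess_trials
from ssveptag.spectral import trial_ssvep_measures
from ssveptag.synthetic_eeg import GenParams, simulate_behaviour, simulate_trial_eeg

montage = default_montage()
params = GenParams(seed=0)
trials = generate_session(48, seed=1)[:40]

records, rts = [], []
for t in trials:
    rt_s, _ = simulate_behaviour(t, seed=t.trial_index)
    records.append(simulate_trial_eeg(t, params=params, montage=montage,
                                      rt_ms=rt_s * 1000))
    rts.append(rt_s * 1000)

prep = preprocess_trials(records, rts)
print(f"artifact rejection: {len(prep['rejection_log'])} of {len(trials)} "
      f"trials removed ({', '.join(prep['rejection_log']['reason'].unique()) or 'none'})")

uid_to_trial = {f"s{t.session_index}_t{t.trial_index}": t for t in trials}
marginals = []
for ep in prep["evidence"]:
    t = uid_to_trial[ep.trial_uid]
    m = trial_ssvep_measures(ep, ["O1", "Oz", "O2"], t.target_tag_hz)
    marginals.append(m["marginal"].window_mean(680, 975))

marginals = np.array(marginals)
print(f"marginal SSVEP, 680-975 ms: mean {marginals.mean():.2f} (CSD units), "
      f"positive on {np.mean(marginals > 0):.0%} of trials")
# the positive mean recovers the injected 12% contrast differential; the
# per-trial sign rate reflects the generator's (synthetic, optimistic) SNR
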