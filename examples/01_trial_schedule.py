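"""Generate a session schedule and inspect the task's design invariants.

Builds a short (768-trial) session, checks the cue ratio and pulse-cell
balance, and prints the contrast time course around a reverse pulse for
the worked example of a 60%-contrast target.
"""

import collections

from ssveptag.paradigm import TrialSpec, contrast_timecourse, generate_session

schedule = generate_session(768, seed=0)

cues = collections.Counter(t.cue for t in schedule)
cells = collections.Counter((t.pulse_type, t.pulse_onset_ms) for t in schedule)
directional = [t for t in schedule if t.cue != "neutral"]
predictive = sum(t.cue_direction == t.target_tilt for t in directional) / len(directional)

print(f"cue counts: {dict(cues)}  (valid = 4 x invalid, invalid = neutral)")
print(f"directional-cue predictiveness: {predictive:.0%}")
print(f"pulse cells: {len(cells)} conditions x {cells.most_common(1)[0][1]} trials; "
      f"{sum(t.pulse_type != 'none' for t in schedule)} pulse trials")

# worked example: 60% target with a reverse pulse at 180 ms
trial = TrialSpec(0, 0, "neutral", "left", 25, "reverse", 180, 10.0)
tc = contrast_timecourse(trial)
for label, t in (("baseline", 800), ("evidence", 1300),
                 ("during pulse", tc.evidence_on_ms + 200),
                 ("after pulse", tc.evidence_on_ms + 400)):
    tgt, non = tc.at(t)
    print(f"{label:>13s}: target {tgt:4.0f}%  non-target {non:4.0f}%")
# the contrasts always sum to 100% after fade-in, and the reverse pulse
# swaps them, producing a summed contrast change of 40% at onset
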