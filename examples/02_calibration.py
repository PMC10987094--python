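"""Titrate task difficulty against a simulated observer.

Runs the one-up-two-down staircase, the one-up-one-down flicker-bias
staircase and the 60-trial QUEST procedure against a Weibull observer
whose 70%-correct threshold is a 15% contrast differential, then
verifies the titration with a 30-trial block.
"""

import numpy as np

from ssveptag.calibration import (Observer, observer_respond, quest_run,
                                  staircase_convergence_level, verify_titration)

obs = Observer(threshold_pct=15.0)
rng = np.random.default_rng(0)

level_1u2d = staircase_convergence_level(
    "one_up_two_down", lambda lvl, r: observer_respond(obs, lvl, r),
    rng, start_level_pct=100.0)
acc = obs.p_correct(level_1u2d)
print(f"1-up-2-down converged at {level_1u2d:.1f}% differential "
      f"-> {acc:.1%} correct (theory: 70.7%)")

biased = Observer(threshold_pct=15.0, flicker_bias_pct=6.0)
boost = staircase_convergence_level(
    "one_up_one_down",
    lambda lvl, r: bool(r.random() >= biased.p_choose_favoured(lvl)),
    rng, start_level_pct=0.0, lower_bound=-100.0)
print(f"1-up-1-down converged boost {boost:.1f}% "
      f"(true flicker bias 6.0%) -> favoured-grating choice rate "
      f"{biased.p_choose_favoured(boost):.1%} (theory: 50%)")

quest = quest_run(obs, n_trials=60, seed=1, initial_level_pct=30.0)
print(f"QUEST estimate after 60 trials: {quest.estimate_pct:.1f}% "
      f"(true 70%-threshold: 15.0%), margin {quest.sd_pct:.1f}%, "
      f"insufficient-practice flag: {quest.insufficient_practice}")

ver = verify_titration(obs, quest.estimate_pct, n_trials=30,
                       quest_margin_pct=quest.sd_pct, seed=2)
print(f"verification block: {ver.accuracy:.1%} correct -> "
      f"{'rerun' if ver.rerun else 'proceed'} at "
      f"{ver.adjusted_contrast_pct:.1f}% differential")
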