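# Registry of the statistical model battery.
#
# Each entry maps one analysis to a trial-level model: `response` and
# `fixed` form the model formula (a per-subject intercept is always
# added by the engine), `link` selects linear vs logistic, `subset` is
# the trial-inclusion rule, `pairwise` requests uncorrected pairwise
# contrasts of a factor, and `focal` identifies the term that carries
# the scientific question (used by calibration/recovery suites):
# `contains` are substrings the term name must include and `interaction`
# says whether the focal term is an interaction.

models:
  rt_by_validity_accuracy:
    response: rt_s
    link: identity
    fixed: "C(cue, Treatment('neutral')) * C(correct) + C(pulse_type) + C(target_tag_hz)"
    subset: "rt_s > 0.1"
    pairwise: cue
    focal: {contains: ["C(cue", "C(correct)"], interaction: true}

  rt_correct:
    response: rt_s
    link: identity
    fixed: "C(cue, Treatment('neutral')) * task_exposure_bin + C(pulse_type) + C(target_tag_hz)"
    subset: "rt_s > 0.1 and correct == 1"
    pairwise: cue
    focal: {contains: ["C(cue"], interaction: false}

  rt_error:
    response: rt_s
    link: identity
    fixed: "C(cue, Treatment('neutral')) * task_exposure_bin + C(pulse_type) + C(target_tag_hz)"
    subset: "rt_s > 0.1 and correct == 0"
    pairwise: cue
    focal: {contains: ["C(cue"], interaction: false}

  accuracy:
    response: correct
    link: logit
    fixed: "C(cue, Treatment('neutral')) * task_exposure_bin + C(pulse_type) + C(target_tag_hz)"
    subset: "rt_s > 0.1"
    pairwise: cue
    focal: {contains: ["C(cue"], interaction: false}

  ssvep_evidence:
    response: marginal_ssvep_evidence
    link: identity
    fixed: "C(cue, Treatment('neutral')) + C(pulse_type) + C(target_tag_hz)"
    subset: "rt_s > 0.1"
    pairwise: cue
    focal: {contains: ["C(cue"], interaction: false}

  ssvep_evidence_exposure:
    response: marginal_ssvep_evidence
    link: identity
    fixed: "C(cue, Treatment('neutral')) * task_exposure_bin + C(pulse_type) + C(target_tag_hz)"
    subset: "rt_s > 0.1"
    pairwise: cue
    focal: {contains: ["C(cue", "task_exposure_bin"], interaction: true}

  ssvep_baseline:
    response: marginal_ssvep_baseline
    link: identity
    fixed: "C(cue_directional, Treatment('neutral')) + C(target_tag_hz)"
    subset: "rt_s > 0.1"
    pairwise: cue_directional
    focal: {contains: ["C(cue_directional"], interaction: false}

  ssvep_target_nontarget:
    response: ssvep_amplitude
    link: identity
    fixed: "C(cue, Treatment('neutral')) * C(signal_role) + C(pulse_type) + C(target_tag_hz)"
    subset: "rt_s > 0.1"
    focal: {contains: ["C(cue", "C(signal_role)"], interaction: true}

  ssvep_prepost_response:
    response: ssvep_prepost_diff
    link: identity
    fixed: "C(cue, Treatment('neutral')) * task_exposure_bin + C(pulse_type) + C(target_tag_hz)"
    subset: "rt_s > 0.1"
    pairwise: cue
    focal: {contains: ["C(cue"], interaction: false}

  ssvep_accuracy_link:
    response: correct
    link: logit
    fixed: "marginal_ssvep_evidence + C(cue, Treatment('neutral'))"
    subset: "rt_s > 0.68"
    focal: {contains: ["marginal_ssvep_evidence"], interaction: false}

  ssvep_rt_link:
    response: rt_s
    link: identity
    fixed: "marginal_ssvep_evidence + C(cue, Treatment('neutral'))"
    subset: "rt_s > 0.68"
    focal: {contains: ["marginal_ssvep_evidence"], interaction: false}

  mb_lateralization:
    response: mb_lateralization_baseline
    link: identity
    fixed: "C(cue_directional, Treatment('neutral')) * task_exposure_bin"
    subset: null
    pairwise: cue_directional
    focal: {contains: ["C(cue_directional"], interaction: false}

  alpha_engagement:
    response: alpha_pre
    link: identity
    fixed: "C(cue_directional, Treatment('neutral'))"
    subset: null
    pairwise: cue_directional
    focal: {contains: ["C(cue_directional"], interaction: false}
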