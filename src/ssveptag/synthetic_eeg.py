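"""Synthetic multichannel EEG and behaviour with known ground truth.

The forward model is deliberately simple — every component the pipeline
measures is injected with a known parameter so downstream stages can be
tested for recovery:

* two phase-reversal SSVEP carriers (20/25 Hz) over occipital cortex
  whose instantaneous amplitude tracks each grating's contrast time
  course (``ssvep_gain`` µV per % contrast), with an optional
  cue-dependent encoding gain on the contrast differential that can ramp
  with task exposure (the mechanism behind the invalid-cue reduction);
* mu-beta (8–30 Hz) band noise over left/right motor cortex, with
  desynchronisation contralateral to the cued hand before evidence onset
  and contralateral to the executed response around the response;
* occipito-parietal alpha (8–14 Hz) whose amplitude is scaled per cue
  condition (lower = more desynchronised = more engaged);
* 1/f background noise on every channel;
* Poisson blinks on the VEOG pair with frontal scalp propagation.

Trial records are "continuous" single-trial recordings spanning the
fixation through the end of evidence, from which the preprocessing
module cuts the cue-, evidence- and response-locked epochs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import (
    ALPHA_MIDLINE, EEGEpoch, FS_HZ, Montage, default_montage, save_epochs,
)
from .paradigm import (
    BASELINE_MS, EVIDENCE_MS, FADE_MS, TrialSpec, contrast_timecourse,
    generate_session, schedule_to_frame,
)

RECORD_SPAN_MS = (-1800.0, 2080.0)  # relative to evidence onset


@dataclass
class GenParams:
    """Ground-truth parameters of the EEG forward model."""

    fs_hz: int = FS_HZ
    seed: int = 0
    ssvep_gain: float = 0.02            # µV per % contrast
    ssvep_center: str = "Oz"
    ssvep_spread: float = 0.4           # gaussian width, unit-sphere chord
    # encoding gain on the contrast differential, per cue condition
    cue_encoding_gain: dict = field(default_factory=lambda: {
        "valid": 1.0, "invalid": 1.0, "neutral": 1.0})
    # end-of-session invalid-cue gain when the exposure ramp is on
    invalid_gain_end: float = 0.7
    exposure_ramp: bool = False
    mb_base_uv: float = 1.0
    mb_lateralization_uv: float = 0.3   # pre-evidence desync contra to cued hand
    mb_response_desync_uv: float = 0.5  # extra desync contra to response
    mb_spread: float = 0.35
    alpha_base_uv: float = 2.0
    alpha_engagement: dict = field(default_factory=lambda: {
        "valid": 1.0, "invalid": 1.0, "neutral": 0.8})
    alpha_center: str = "POz"
    alpha_spread: float = 0.4
    noise_uv: float = 1.5               # broadband 1/f noise SD per channel
    noise_exponent: float = 1.0
    blink_rate_hz: float = 0.05
    blink_amplitude_uv: float = 300.0
    blink_width_ms: float = 120.0

    def encoding_gain(self, cue: str, exposure_frac: float = 0.0) -> float:
        g = self.cue_encoding_gain[cue]
        if self.exposure_ramp and cue == "invalid":
            g = g + (self.invalid_gain_end - g) * float(exposure_frac)
        return g


def _gauss_weights(montage: Montage, center: str, spread: float) -> np.ndarray:
    c = montage.position(center)
    d = np.linalg.norm(montage.positions - c, axis=1)
    return np.exp(-0.5 * (d / spread) ** 2)


def _band_noise(rng, n, fs, lo, hi, order=4) -> np.ndarray:
    b, a = sps.butter(order, [lo, hi], btype="bandpass", fs=fs)
    x = sps.filtfilt(b, a, rng.standard_normal(n + 2 * fs))[fs:-fs]
    sd = x.std()
    return x / sd if sd > 0 else x


def _one_over_f_noise(rng, shape, fs, exponent) -> np.ndarray:
    """Unit-variance noise with amplitude spectrum ~ f^(-exponent/2)."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    white = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    spec = white[..., : len(freqs)] * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _trial_rng(params: GenParams, trial: TrialSpec, seed=None) -> np.random.Generator:
    if seed is not None:
        return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ss = np.random.SeedSequence(
        entropy=params.seed,
        spawn_key=(trial.session_index, max(trial.trial_index, 0)),
    )
    return np.random.default_rng(ss)


def simulate_trial_eeg(
    trial: TrialSpec,
    timecourse=None,
    params: GenParams = None,
    montage: Optional[Montage] = None,
    rt_ms: Optional[float] = None,
    exposure_frac: float = 0.0,
    seed=None,
) -> EEGEpoch:
    """Forward-model one trial; returns a continuous trial record.

    Deterministic given the trial and ``params.seed`` (or an explicit
    ``seed``). ``rt_ms`` places the response-locked motor desync;
    ``exposure_frac`` in [0, 1] drives the invalid-cue encoding ramp.
    """
    params = params or GenParams()
    montage = montage or default_montage()
    if timecourse is None:
        timecourse = contrast_timecourse(trial)
    rng = _trial_rng(params, trial, seed)
    fs = params.fs_hz

    t0, t1 = RECORD_SPAN_MS
    n = int(round((t1 - t0) * fs / 1000.0))
    t_ms = t0 + 1000.0 * np.arange(n) / fs  # relative to evidence onset
    n_scalp = montage.n_scalp
    data = np.zeros((n_scalp + 2, n))

    # --- SSVEP carriers -----------------------------------------------------
    ev_on_tc = timecourse.evidence_on_ms  # evidence onset on the fade axis
    t_tc = t_ms + ev_on_tc
    idx = np.clip(
        np.searchsorted(timecourse.time_ms, t_tc, side="right") - 1,
        0, len(timecourse.time_ms) - 1,
    )
    c_tgt = timecourse.contrast_target_pct[idx].copy()
    c_non = timecourse.contrast_nontarget_pct[idx].copy()
    c_tgt[t_tc < 0] = 0.0
    c_non[t_tc < 0] = 0.0
    g = params.encoding_gain(trial.cue, exposure_frac)
    mid = np.where((c_tgt > 0) | (c_non > 0), 50.0, 0.0)
    c_tgt_eff = mid + g * (c_tgt - mid)
    c_non_eff = mid + g * (c_non - mid)

    w_ssvep = _gauss_weights(montage, params.ssvep_center, params.ssvep_spread)
    phase = np.pi if trial.half_cycle_phase else 0.0
    f_tgt = trial.target_tag_hz
    f_non = 45 - f_tgt  # the other tag (20 <-> 25)
    t_s = (t_ms - t0) / 1000.0
    carrier_tgt = params.ssvep_gain * c_tgt_eff * np.sin(2 * np.pi * f_tgt * t_s + phase)
    carrier_non = params.ssvep_gain * c_non_eff * np.sin(2 * np.pi * f_non * t_s + phase)
    data[:n_scalp] += w_ssvep[:, None] * (carrier_tgt + carrier_non)

    # --- mu-beta ------------------------------------------------------------
    w_left = _gauss_weights(montage, "C3", params.mb_spread)
    w_right = _gauss_weights(montage, "C4", params.mb_spread)
    cue_dir = trial.cue_direction
    amp_left = np.full(n, params.mb_base_uv)
    amp_right = np.full(n, params.mb_base_uv)
    cue_on = -(BASELINE_MS + FADE_MS)
    if cue_dir is not None:
        # hemisphere contralateral to the cued hand desynchronises after the cue
        contra = amp_right if cue_dir == "left" else amp_left
        contra[t_ms >= cue_on] -= params.mb_lateralization_uv
    if rt_ms is not None and rt_ms > 0:
        resp_side = trial.target_tilt  # executed response on correct trials
        contra = amp_right if resp_side == "left" else amp_left
        ramp = np.clip((t_ms - (rt_ms - 400.0)) / 400.0, 0.0, 1.0)
        contra -= params.mb_response_desync_uv * ramp
    amp_left = np.clip(amp_left, 0.0, None)
    amp_right = np.clip(amp_right, 0.0, None)
    mb_l = _band_noise(rng, n, fs, 8.0, 30.0) * amp_left
    mb_r = _band_noise(rng, n, fs, 8.0, 30.0) * amp_right
    data[:n_scalp] += w_left[:, None] * mb_l + w_right[:, None] * mb_r

    # --- alpha --------------------------------------------------------------
    w_alpha = _gauss_weights(montage, params.alpha_center, params.alpha_spread)
    a_amp = params.alpha_base_uv * params.alpha_engagement[trial.cue]
    alpha = _band_noise(rng, n, fs, 8.0, 14.0) * a_amp
    data[:n_scalp] += w_alpha[:, None] * alpha

    # --- 1/f background -----------------------------------------------------
    if params.noise_uv > 0:
        data[:n_scalp] += params.noise_uv * _one_over_f_noise(
            rng, (n_scalp, n), fs, params.noise_exponent
        )

    # --- blinks -------------------------------------------------------------
    duration_s = (t1 - t0) / 1000.0
    n_blinks = rng.poisson(params.blink_rate_hz * duration_s)
    if n_blinks > 0:
        w_front = _gauss_weights(montage, "Fp1", 0.35) + _gauss_weights(montage, "Fp2", 0.35)
        w_front = 0.3 * w_front / w_front.max()
        sigma = params.blink_width_ms
        for bt in rng.uniform(t0, t1, size=n_blinks):
            bump = np.exp(-0.5 * ((t_ms - bt) / sigma) ** 2)
            data[n_scalp] += params.blink_amplitude_uv * bump        # VEOG upper
            data[n_scalp + 1] -= 0.5 * params.blink_amplitude_uv * bump  # VEOG lower
            data[:n_scalp] += params.blink_amplitude_uv * w_front[:, None] * bump

    return EEGEpoch(
        data=data, t0_ms=t0, alignment="continuous", montage=montage,
        trial_uid=f"s{trial.session_index}_t{trial.trial_index}", fs_hz=fs,
    )


# ---------------------------------------------------------------------------
# behaviour

@dataclass
class BehaviourParams:
    """Cue effects on accuracy (logit scale) and reaction time (seconds)."""

    base_accuracy: float = 0.70
    # contrasts vs the neutral condition on the logit scale
    accuracy_logit_shift: dict = field(default_factory=lambda: {
        "valid": 0.184, "invalid": -0.219, "neutral": 0.0})
    # additive shifts of the RT distribution, correct and error responses
    rt_shift_correct_s: dict = field(default_factory=lambda: {
        "valid": -0.043, "invalid": 0.085, "neutral": 0.0})
    rt_shift_error_s: dict = field(default_factory=lambda: {
        "valid": 0.084, "invalid": -0.047, "neutral": 0.0})
    rt_shift_s: float = 0.25
    rt_log_mu: float = np.log(0.6)
    rt_log_sigma: float = 0.25


def simulate_behaviour(trial: TrialSpec, behav: BehaviourParams = None, seed=None):
    """Draw (rt_s, correct) for one trial.

    Accuracy is Bernoulli with the base rate shifted per cue on the
    logit scale; RT is a shifted lognormal with additive per-cue shifts,
    separate for correct and error responses.
    """
    behav = behav or BehaviourParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_logit = np.log(behav.base_accuracy / (1 - behav.base_accuracy))
    p = 1.0 / (1.0 + np.exp(-(base_logit + behav.accuracy_logit_shift[trial.cue])))
    correct = bool(rng.random() < p)
    shift = (behav.rt_shift_correct_s if correct else behav.rt_shift_error_s)[trial.cue]
    rt = behav.rt_shift_s + shift + float(
        np.exp(rng.normal(behav.rt_log_mu, behav.rt_log_sigma))
    )
    return rt, correct


# ---------------------------------------------------------------------------
# datasets

def make_dataset(
    out_dir,
    n_subjects: int = 2,
    sessions_per_subject: int = 1,
    trials_per_session: int = 96,
    params: GenParams = None,
    behav: BehaviourParams = None,
    seed: int = 0,
    marginal_contrast_pct: float = 12.0,
    montage: Optional[Montage] = None,
) -> Path:
    """Write a synthetic dataset: epochs + trial tables + manifest.

    Layout: ``sub-XX_ses-YY_epochs.npy/.json`` and
    ``sub-XX_ses-YY_trials.csv`` per subject-session, plus
    ``manifest.json`` listing every injected parameter. Deterministic
    given ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or GenParams()
    behav = behav or BehaviourParams()
    montage = montage or default_montage()

    for subj in range(n_subjects):
        for ses in range(sessions_per_subject):
            sess_seed = int(np.random.SeedSequence(
                entropy=seed, spawn_key=(subj, ses)).generate_state(1)[0] % (2**31))
            schedule = generate_session(
                trials_per_session, seed=sess_seed, session_index=ses,
                marginal_contrast_pct=marginal_contrast_pct,
            )
            tparams = dataclasses.replace(params, seed=sess_seed)
            rows, records = [], []
            n_tr = len(schedule)
            brng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(subj, ses, 1)))
            for k, trial in enumerate(schedule):
                rt_s, correct = simulate_behaviour(trial, behav, brng)
                exposure = (ses * n_tr + k) / max(sessions_per_subject * n_tr - 1, 1)
                rec = simulate_trial_eeg(
                    trial, params=tparams, montage=montage,
                    rt_ms=rt_s * 1000.0, exposure_frac=exposure,
                )
                rec.trial_uid = f"sub{subj:02d}_ses{ses:02d}_t{trial.trial_index:04d}"
                records.append(rec)
                rows.append({
                    "trial_uid": rec.trial_uid,
                    "subject_id": subj, "session_index": ses,
                    "rt_s": rt_s, "correct": int(correct),
                    "exposure_frac": exposure,
                    "encoding_gain": tparams.encoding_gain(trial.cue, exposure),
                })
            stem = out / f"sub-{subj:02d}_ses-{ses:02d}"
            save_epochs(stem.with_suffix(".npy").with_name(stem.name + "_epochs"), records)
            table = pd.concat(
                [schedule_to_frame(schedule).reset_index(drop=True),
                 pd.DataFrame(rows)], axis=1)
            table.to_csv(f"{stem}_trials.csv", index=False)

    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "sessions_per_subject": sessions_per_subject,
        "trials_per_session": trials_per_session,
        "gen_params": {k: (v if not isinstance(v, dict) else dict(v))
                       for k, v in dataclasses.asdict(params).items()},
        "behaviour_params": dataclasses.asdict(behav),
        "marginal_contrast_pct": marginal_contrast_pct,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


# ---------------------------------------------------------------------------
# measure-level table simulator (for the statistics battery)

# per-exposure-bin mean marginal contrast (%), following the session-on-
# session titration trajectory reported for this task
DEFAULT_CONTRAST_BY_BIN = [16.3, 13.08, 11.38, 11.5, 11.4]


@dataclass
class TableParams:
    """Generator for trial-level measure tables fed to the model battery.

    ``ssvep_coupling`` converts marginal contrast (%) into marginal SSVEP
    (µV-scale); cue encoding gains and the exposure ramp mirror
    :class:`GenParams`. All noise terms are gaussian; a subject random
    intercept is added to every measure.
    """

    n_subjects: int = 12
    trials_per_subject: int = 480
    ssvep_coupling: float = 0.12          # µV per % marginal contrast
    cue_encoding_gain: dict = field(default_factory=lambda: {
        "valid": 1.0, "invalid": 1.0, "neutral": 1.0})
    invalid_gain_end: float = 0.7
    exposure_ramp: bool = False
    ssvep_noise: float = 1.0
    ssvep_role_base: float = 1.0          # common per-grating amplitude level
    ssvep_baseline_mean: float = 0.0      # anticipatory modulation (off by default)
    mb_lateralization_cued: float = 0.3
    mb_lateralization_neutral: float = 0.0
    mb_noise: float = 1.0
    alpha_cued: float = 2.0
    alpha_neutral: float = 1.6
    alpha_noise: float = 1.0
    subject_sd: float = 0.2
    rt_subject_sd_s: float = 0.05
    prepost_subject_sd: float = 0.1       # subject spread of post-minus-pre shift
    accuracy_subject_sd_logit: float = 0.2
    contrast_by_bin: list = field(default_factory=lambda: list(DEFAULT_CONTRAST_BY_BIN))
    # causal link from single-trial SSVEP fluctuation to behaviour
    ssvep_to_accuracy_logit: float = 0.0
    ssvep_to_rt_s: float = 0.0
    behav: BehaviourParams = field(default_factory=BehaviourParams)

    def encoding_gain(self, cue, exposure_frac):
        g = self.cue_encoding_gain[cue]
        if self.exposure_ramp and cue == "invalid":
            g = g + (self.invalid_gain_end - g) * float(exposure_frac)
        return g


def null_table_params(n_subjects: int = 6, trials_per_subject: int = 192) -> TableParams:
    """Generator conditions with every condition effect switched off.

    Subject-level variance and the titration-driven contrast decline are
    retained; cue conditions differ in nothing, and single-trial SSVEP
    fluctuations are causally unlinked from behaviour. Used for type-I
    calibration of the model battery.
    """
    return TableParams(
        n_subjects=n_subjects,
        trials_per_subject=trials_per_subject,
        mb_lateralization_cued=0.0,
        alpha_cued=1.6,
        alpha_neutral=1.6,
        behav=BehaviourParams(
            accuracy_logit_shift={"valid": 0.0, "invalid": 0.0, "neutral": 0.0},
            rt_shift_correct_s={"valid": 0.0, "invalid": 0.0, "neutral": 0.0},
            rt_shift_error_s={"valid": 0.0, "invalid": 0.0, "neutral": 0.0},
        ),
    )


def simulate_analysis_table(tp: TableParams = None, seed: int = 0) -> pd.DataFrame:
    """Simulate a per-trial AnalysisTable directly at the measure level.

    Used to exercise the statistics battery at scales where full EEG
    simulation is not needed (type-I calibration, power-style recovery).
    """
    tp = tp or TableParams()
    rng = np.random.default_rng(seed)
    n = tp.trials_per_subject
    cues = np.array(["valid"] * 4 + ["invalid"] + ["neutral"])
    rows = []
    for subj in range(tp.n_subjects):
        intercept = rng.normal(0.0, tp.subject_sd)
        rt_intercept = rng.normal(0.0, tp.rt_subject_sd_s)
        prepost_intercept = rng.normal(0.0, tp.prepost_subject_sd)
        acc_intercept = rng.normal(0.0, tp.accuracy_subject_sd_logit)
        cue_seq = rng.choice(cues, size=n)
        pulse_seq = rng.choice(["none", "reverse", "gap", "positive"], size=n)
        tag_seq = rng.choice([20, 25], size=n)
        bin_edges = np.linspace(0, n, 6).astype(int)
        for k in range(n):
            b = int(np.searchsorted(bin_edges[1:], k, side="right"))
            exposure = k / max(n - 1, 1)
            cue = str(cue_seq[k])
            contrast = tp.contrast_by_bin[b]
            gain = tp.encoding_gain(cue, exposure)
            ssvep_mean = gain * tp.ssvep_coupling * contrast + intercept
            half_noise = tp.ssvep_noise / np.sqrt(2.0)
            ssvep_target = rng.normal(
                tp.ssvep_role_base + intercept + ssvep_mean / 2.0, half_noise)
            ssvep_nontarget = rng.normal(
                tp.ssvep_role_base + intercept - ssvep_mean / 2.0, half_noise)
            ssvep = ssvep_target - ssvep_nontarget  # marginal == difference
            ssvep_resid = ssvep - ssvep_mean
            behav = tp.behav
            base_logit = np.log(behav.base_accuracy / (1 - behav.base_accuracy))
            logit = (base_logit + behav.accuracy_logit_shift[cue] + acc_intercept
                     + tp.ssvep_to_accuracy_logit * ssvep_resid)
            correct = bool(rng.random() < 1.0 / (1.0 + np.exp(-logit)))
            shift = (behav.rt_shift_correct_s if correct else behav.rt_shift_error_s)[cue]
            rt = (behav.rt_shift_s + shift + rt_intercept
                  + float(np.exp(rng.normal(behav.rt_log_mu, behav.rt_log_sigma)))
                  + tp.ssvep_to_rt_s * ssvep_resid)
            mb_lat = rng.normal(
                (tp.mb_lateralization_neutral if cue == "neutral"
                 else tp.mb_lateralization_cued) + intercept, tp.mb_noise)
            alpha = rng.normal(
                (tp.alpha_neutral if cue == "neutral" else tp.alpha_cued) + intercept,
                tp.alpha_noise)
            rows.append({
                "subject_id": subj,
                "trial_uid": f"sub{subj:02d}_t{k:05d}",
                "trial_order": k,
                "cue": cue,
                "cue_directional": "neutral" if cue == "neutral" else "cued",
                "task_exposure_bin": b + 1,
                "pulse_type": str(pulse_seq[k]),
                "target_tag_hz": int(tag_seq[k]),
                "rt_s": rt,
                "correct": int(correct),
                "marginal_contrast_pct": contrast,
                "marginal_ssvep_evidence": ssvep,
                "ssvep_target_evidence": ssvep_target,
                "ssvep_nontarget_evidence": ssvep_nontarget,
                "marginal_ssvep_baseline": rng.normal(
                    tp.ssvep_baseline_mean + intercept, tp.ssvep_noise),
                "mb_lateralization_baseline": mb_lat,
                "alpha_pre": alpha,
                "ssvep_pre_response": rng.normal(ssvep_mean, tp.ssvep_noise),
                "ssvep_post_response": rng.normal(
                    ssvep_mean + prepost_intercept, tp.ssvep_noise),
            })
    return pd.DataFrame(rows)
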