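"""End-to-end orchestration: simulate → preprocess → extract → analyze.

Each stage reads and writes only the documented file interfaces (trial
tables and epoch containers from the generator, a measures CSV from
extraction, effect-table CSVs from the analysis), so stages can be run
separately or through :func:`run_pipeline`. A run directory always
contains a manifest recording the configuration, seeds and package
version, and re-running with the same configuration reproduces the
trial tables and measures byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    bin_task_exposure, effect_tables_to_frame, load_registry,
    marginal_contrast_trend, prepare_table, run_battery,
)
from .containers import (
    ALPHA_MIDLINE, LEFT_CENTRAL, OCCIPITAL_POOL, RIGHT_CENTRAL,
    default_montage, load_epochs,
)
from .preprocess import PreprocConfig, preprocess_trials
from .spectral import (
    alpha_band, mu_beta, select_mb_electrodes, select_ssvep_electrodes,
    trial_ssvep_measures,
)
from .synthetic_eeg import BehaviourParams, GenParams, make_dataset

logger = logging.getLogger(__name__)

# measurement windows (ms), half-open on the STFT midpoint axis
EVIDENCE_WINDOW = (680.0, 975.0)
BASELINE_WINDOW = (-752.0, -214.0)
ALPHA_WINDOW = (-410.0, -70.0)
PRE_RESPONSE_WINDOW = (-200.0, -50.0)
POST_RESPONSE_WINDOW = (50.0, 200.0)

PRESETS = {
    # n_subjects, sessions_per_subject, trials_per_session
    "smoke": (2, 1, 48),
    "desk": (6, 2, 96),
    "full_scale": (12, 5, 768),
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/run0"
    preset: str = "smoke"
    gen: GenParams = field(default_factory=GenParams)
    behav: BehaviourParams = field(default_factory=BehaviourParams)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    ssvep_pool: list = field(default_factory=lambda: list(OCCIPITAL_POOL))
    left_central_pool: list = field(default_factory=lambda: list(LEFT_CENTRAL))
    right_central_pool: list = field(default_factory=lambda: list(RIGHT_CENTRAL))
    alpha_channels: list = field(default_factory=lambda: list(ALPHA_MIDLINE))
    n_selection_trials: int = 48
    apply_csd: bool = True
    registry_path: Optional[str] = None

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# extraction

def _cued_tag(cue: str, target_tag: int) -> int:
    """Tag of the grating the cue points at (target tag on neutral trials)."""
    return target_tag if cue in ("valid", "neutral") else 45 - target_tag


def _reference_side(cue: str, cue_dir: Optional[str], tilt: str) -> str:
    """Side defining contra/ipsi: cue direction, or the correct response."""
    return cue_dir if cue_dir is not None else tilt


def extract_measures(
    dataset_dir,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess a dataset and extract the per-trial measures table.

    Runs the preprocessing chain per subject-session, selects SSVEP and
    mu-beta electrodes per subject from the data, and computes the
    windowed per-trial scalars used by the statistics battery. Trials
    rejected for an epoch type get NaN for the measures of that type.
    Returns ``(measures, rejection_log)``.
    """
    dataset_dir = Path(dataset_dir)
    trial_files = sorted(dataset_dir.glob("sub-*_trials.csv"))
    if not trial_files:
        raise FileNotFoundError(f"no trial tables under {dataset_dir}")

    all_rows = []
    rejection_frames = []
    for tf in trial_files:
        trials = pd.read_csv(tf)
        stem = tf.name.replace("_trials.csv", "")
        records = load_epochs(dataset_dir / f"{stem}_epochs")
        rts = (trials["rt_s"] * 1000.0).tolist()
        prep = preprocess_trials(records, rts, cfg.preproc, cfg.apply_csd)
        rejection_frames.append(prep["rejection_log"].assign(session=stem))

        info = trials.set_index("trial_uid")
        ev_by_uid = {e.trial_uid: e for e in prep["evidence"]}
        cue_by_uid = {e.trial_uid: e for e in prep["cue"]}
        resp_by_uid = {e.trial_uid: e for e in prep["response"]}

        # per-session data-driven electrode selection
        sel_uids = [u for u in list(ev_by_uid)[: cfg.n_selection_trials]]
        ssvep_chs = select_ssvep_electrodes(
            [ev_by_uid[u] for u in sel_uids],
            [int(info.loc[u, "target_tag_hz"]) for u in sel_uids],
            cfg.ssvep_pool,
        )
        resp_uids = list(resp_by_uid)[: cfg.n_selection_trials]
        if len(resp_uids) >= 4:
            mb_sel = select_mb_electrodes(
                [resp_by_uid[u] for u in resp_uids],
                [str(info.loc[u, "target_tilt"]) for u in resp_uids],
                cfg.left_central_pool, cfg.right_central_pool,
            )
            left_chs, right_chs = mb_sel["left"], mb_sel["right"]
        else:
            left_chs = cfg.left_central_pool[:2]
            right_chs = cfg.right_central_pool[:2]
        logger.info("%s: SSVEP electrodes %s, MB %s/%s",
                    stem, ssvep_chs, left_chs, right_chs)

        for uid, row in info.iterrows():
            tag = int(row["target_tag_hz"])
            cue = str(row["cue"])
            cue_dir = (None if cue == "neutral"
                       else (str(row["target_tilt"]) if cue == "valid"
                             else ("left" if row["target_tilt"] == "right" else "right")))
            out = {
                "trial_uid": uid,
                "subject_id": int(row["subject_id"]),
                "session_index": int(row["session_index"]),
                "trial_index": int(row["trial_index"]),
                "cue": cue,
                "target_tilt": str(row["target_tilt"]),
                "target_tag_hz": tag,
                "pulse_type": str(row["pulse_type"]),
                "marginal_contrast_pct": float(row["marginal_contrast_pct"]),
                "rt_s": float(row["rt_s"]),
                "correct": int(row["correct"]),
            }
            ev = ev_by_uid.get(uid)
            if ev is not None:
                m = trial_ssvep_measures(ev, ssvep_chs, tag)
                out["marginal_ssvep_evidence"] = m["marginal"].window_mean(*EVIDENCE_WINDOW)
                out["ssvep_target_evidence"] = m["target"].window_mean(*EVIDENCE_WINDOW)
                out["ssvep_nontarget_evidence"] = m["nontarget"].window_mean(*EVIDENCE_WINDOW)
            cuep = cue_by_uid.get(uid)
            if cuep is not None:
                m = trial_ssvep_measures(cuep, ssvep_chs, _cued_tag(cue, tag))
                out["marginal_ssvep_baseline"] = m["marginal"].window_mean(*BASELINE_WINDOW)
                side = _reference_side(cue, cue_dir, str(row["target_tilt"]))
                mb = mu_beta(cuep, left_chs, right_chs, side)
                # preparation-positive sign: ipsi minus contra amplitude
                out["mb_lateralization_baseline"] = -mb["lateralization"].window_mean(
                    *BASELINE_WINDOW)
                out["alpha_pre"] = alpha_band(cuep, cfg.alpha_channels).window_mean(
                    *ALPHA_WINDOW)
            resp = resp_by_uid.get(uid)
            if resp is not None:
                m = trial_ssvep_measures(resp, ssvep_chs, tag)
                out["ssvep_pre_response"] = m["marginal"].window_mean(*PRE_RESPONSE_WINDOW)
                out["ssvep_post_response"] = m["marginal"].window_mean(*POST_RESPONSE_WINDOW)
            all_rows.append(out)

    measures = pd.DataFrame(all_rows)
    # chronological task-exposure quintiles per subject
    measures = measures.sort_values(
        ["subject_id", "session_index", "trial_index"]).reset_index(drop=True)
    measures["trial_order"] = measures.groupby("subject_id").cumcount()
    measures["task_exposure_bin"] = bin_task_exposure(measures)
    rejections = (pd.concat(rejection_frames, ignore_index=True)
                  if rejection_frames else pd.DataFrame())
    return measures, rejections


def measures_to_long(measures: pd.DataFrame) -> pd.DataFrame:
    """Long-format TrialMeasures (trial_uid, measure, value)."""
    value_cols = [c for c in measures.columns if c.startswith(("marginal_", "ssvep_",
                                                               "mb_", "alpha_"))]
    return measures.melt(id_vars=["trial_uid"], value_vars=value_cols,
                         var_name="measure", value_name="value")


# ---------------------------------------------------------------------------
# the full run

def run_pipeline(cfg: RunConfig) -> Path:
    """Simulate, preprocess, extract and analyse; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    n_subj, n_ses, n_trials = PRESETS[cfg.preset]

    logger.info("stage 1/3: simulating %d subjects x %d sessions x %d trials",
                n_subj, n_ses, n_trials)
    data_dir = make_dataset(
        out / "data", n_subjects=n_subj, sessions_per_subject=n_ses,
        trials_per_session=n_trials, params=cfg.gen, behav=cfg.behav,
        seed=cfg.seed,
    )

    logger.info("stage 2/3: preprocessing and extracting measures")
    measures, rejection_log = extract_measures(data_dir, cfg)
    measures.to_csv(out / "measures.csv", index=False)
    rejection_log.to_csv(out / "rejection_log.csv", index=False)
    measures_to_long(measures).to_csv(out / "measures_long.csv", index=False)

    logger.info("stage 3/3: statistical battery")
    registry = load_registry(cfg.registry_path)
    table = prepare_table(measures.dropna(subset=["marginal_ssvep_evidence"]))
    results = run_battery(table, registry)
    effect_tables_to_frame(results).to_csv(out / "effect_tables.csv", index=False)
    trend = marginal_contrast_trend(table)
    (out / "contrast_trend.json").write_text(json.dumps(dataclasses.asdict(trend)))

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "n_trials_measured": int(len(measures)),
        "models_run": list(results),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("run complete: %s", out)
    return out


def make_fixtures(out_dir, seed: int = 0) -> Path:
    """A small golden dataset for tests: all 16 pulse cells, plus trials
    constructed to exercise each artifact-rejection reason."""
    import dataclasses as dc

    from .containers import default_montage
    from .synthetic_eeg import simulate_trial_eeg

    out = Path(out_dir)
    gen = GenParams(seed=seed, blink_rate_hz=0.15)
    make_dataset(out, n_subjects=1, sessions_per_subject=1,
                 trials_per_session=16, params=gen, seed=seed)
    # a deterministic pair of pathological epochs alongside the dataset
    montage = default_montage()
    from .paradigm import generate_session
    trial = generate_session(16, seed=seed)[0]
    clean = simulate_trial_eeg(trial, params=GenParams(seed=seed, blink_rate_hz=0.0),
                               montage=montage)
    blink = simulate_trial_eeg(trial, params=GenParams(seed=seed, blink_rate_hz=0.0),
                               montage=montage)
    blink.data[montage.n_scalp] += 400.0      # VEOG artifact
    noisy = simulate_trial_eeg(trial, params=GenParams(seed=seed, blink_rate_hz=0.0),
                               montage=montage)
    noisy.data[montage.names.index("Cz")] += 150.0  # scalp-threshold artifact
    from .containers import save_epochs
    for name, ep in (("clean", clean), ("veog_artifact", blink),
                     ("scalp_artifact", noisy)):
        ep.trial_uid = name
    save_epochs(out / "artifact_epochs", [clean, blink, noisy])
    return out
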