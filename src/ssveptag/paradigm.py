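"""Trial-schedule generation for the cued contrast-discrimination task.

The task: two overlaid orthogonal gratings whose contrasts always sum to
100%. After a 400 ms fade-in (0 -> 50% both) and an 800 ms equal-contrast
baseline, the target grating steps up and the non-target steps down by the
titrated marginal contrast for a 2000 ms evidence phase. A predictive cue
(valid : invalid : neutral = 4 : 1 : 1, so directional cues are 80%
predictive) precedes the evidence. Each grating phase-reverses at its own
tag frequency (20 or 25 Hz), counterbalanced across trials. Brief 150 ms
evidence "pulses" (reverse / gap / positive, onset 180..500 ms in 80 ms
steps) occur on 15/16 of trials; the 16 pulse cells are equally
represented in a session.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

# display runs at 100 Hz; contrast time courses are frame-accurate
FRAME_MS = 10
FADE_MS = 400
BASELINE_MS = 800
EVIDENCE_MS = 2000
PULSE_MS = 150
RESPONSE_DEADLINE_MS = 1800
BLOCK_SIZE = 48

CUES = ("valid", "invalid", "neutral")
TILTS = ("left", "right")
TAGS = (20, 25)
PULSE_TYPES = ("none", "reverse", "gap", "positive")
# valid cues occur four times as often as invalid; invalid == neutral
CUE_WEIGHTS = {"valid": 4, "invalid": 1, "neutral": 1}


def pulse_onsets() -> list[int]:
    """Five pulse onset times (ms after evidence onset): 180 + 80k."""
    return [180 + 80 * k for k in range(5)]


def pulse_cells() -> list[tuple[str, Optional[int]]]:
    """The 16 equally represented pulse conditions: 3 types x 5 onsets + none."""
    cells: list[tuple[str, Optional[int]]] = [("none", None)]
    for ptype in ("reverse", "gap", "positive"):
        for onset in pulse_onsets():
            cells.append((ptype, onset))
    return cells


@dataclass(frozen=True)
class TrialSpec:
    """One trial's design parameters."""

    session_index: int
    trial_index: int
    cue: str
    target_tilt: str
    target_tag_hz: int
    pulse_type: str
    pulse_onset_ms: Optional[int]
    marginal_contrast_pct: float
    pulse_duration_ms: int = PULSE_MS
    immutable: bool = False
    # the gratings' starting phase is shifted a half cycle on every trial;
    # only the EEG forward model consumes this
    half_cycle_phase: bool = False

    def __post_init__(self):
        if self.cue not in CUES:
            raise ValueError(f"unknown cue {self.cue!r}")
        if self.target_tilt not in TILTS:
            raise ValueError(f"unknown tilt {self.target_tilt!r}")
        if self.target_tag_hz not in TAGS:
            raise ValueError(f"tag frequency must be 20 or 25, got {self.target_tag_hz}")
        if self.pulse_type not in PULSE_TYPES:
            raise ValueError(f"unknown pulse type {self.pulse_type!r}")
        if self.pulse_type != "none" and self.pulse_onset_ms not in pulse_onsets():
            raise ValueError(f"pulse onset must be one of {pulse_onsets()}")

    @property
    def cue_direction(self) -> Optional[str]:
        """Side the cue points to (None for neutral cues)."""
        if self.cue == "valid":
            return self.target_tilt
        if self.cue == "invalid":
            return "left" if self.target_tilt == "right" else "right"
        return None


@dataclass
class ContrastTimecourse:
    """Per-grating contrast (%) sampled at the display frame rate.

    ``time_ms`` runs from fade-in onset; phase markers give the onsets of
    the fade-in, baseline and evidence phases on that axis.
    """

    time_ms: np.ndarray
    contrast_target_pct: np.ndarray
    contrast_nontarget_pct: np.ndarray
    fade_on_ms: int = 0
    baseline_on_ms: int = FADE_MS
    evidence_on_ms: int = FADE_MS + BASELINE_MS

    def at(self, t_ms: float) -> tuple[float, float]:
        """(target, non-target) contrast at time t (ms from fade onset)."""
        i = int(np.clip(np.searchsorted(self.time_ms, t_ms, side="right") - 1,
                        0, len(self.time_ms) - 1))
        return float(self.contrast_target_pct[i]), float(self.contrast_nontarget_pct[i])


@dataclass(frozen=True)
class FeedbackOutcome:
    points_delta: int
    outcome: str  # correct | error | too_fast | too_slow


def _largest_cue_composition(n: int) -> dict[str, int]:
    """Largest 4:1:1 valid:invalid:neutral composition; remainder to valid."""
    base = n // 6
    counts = {"valid": 4 * base, "invalid": base, "neutral": base}
    counts["valid"] += n - sum(counts.values())
    return counts


def generate_session(
    n_trials: Optional[int] = None,
    long_session: bool = False,
    seed: int = 0,
    session_index: int = 0,
    marginal_contrast_pct: float = 12.0,
) -> list[TrialSpec]:
    """Generate a randomised session schedule.

    ``n_trials`` defaults to the long (~1152) or short (~768) session
    length. The 16 pulse cells are represented as equally as possible,
    cue counts follow the 4:1:1 ratio within each pulse cell, and tag
    frequency / target tilt are counterbalanced within every cue x pulse
    cell. Deterministic given ``seed``.
    """
    if n_trials is None:
        n_trials = 1152 if long_session else 768
    if n_trials < 16:
        raise ValueError("n_trials must be >= 16 to represent all pulse conditions")

    rng = np.random.default_rng(seed)
    cells = pulse_cells()

    # equal split of trials over the 16 pulse cells (remainder spread by rng)
    per_cell = np.full(len(cells), n_trials // len(cells), dtype=int)
    extra = rng.permutation(len(cells))[: n_trials % len(cells)]
    per_cell[extra] += 1
    cell_ids = np.repeat(np.arange(len(cells)), per_cell)

    # cue ratio is a session-level constraint; pair shuffled cue labels
    # with shuffled cell slots so cue and pulse condition stay unconfounded
    cue_counts = _largest_cue_composition(n_trials)
    cue_labels = np.array([c for c in CUES for _ in range(cue_counts[c])])
    rng.shuffle(cue_labels)
    rng.shuffle(cell_ids)

    trials: list[TrialSpec] = []
    groups: dict[tuple[str, int], list[int]] = {}
    for i, (cue, cid) in enumerate(zip(cue_labels, cell_ids)):
        groups.setdefault((str(cue), int(cid)), []).append(i)
    assembled: list[Optional[TrialSpec]] = [None] * n_trials
    for (cue, cid), members in groups.items():
        ptype, onset = cells[cid]
        # counterbalance tag frequency and tilt within the cue x pulse cell
        k = len(members)
        tags = np.tile(TAGS, k // 2 + 1)[:k]
        tilts = np.tile(TILTS, k // 2 + 1)[:k]
        rng.shuffle(tilts)
        for i, tag, tilt in zip(members, tags, tilts):
            assembled[i] = TrialSpec(
                session_index=session_index,
                trial_index=-1,
                cue=cue,
                target_tilt=str(tilt),
                target_tag_hz=int(tag),
                pulse_type=ptype,
                pulse_onset_ms=onset,
                marginal_contrast_pct=float(marginal_contrast_pct),
            )
    trials = [t for t in assembled if t is not None]

    order = rng.permutation(len(trials))
    return [
        dataclasses.replace(trials[j], trial_index=i, half_cycle_phase=bool(i % 2))
        for i, j in enumerate(order)
    ]


def contrast_timecourse(trial: TrialSpec, frame_ms: int = FRAME_MS) -> ContrastTimecourse:
    """Frame-accurate contrast time course for one trial.

    Contrasts rise monotonically 0 -> 50 during fade-in, sit at 50/50
    through the baseline, then diverge reciprocally by the marginal
    contrast. Pulses are applied instantaneously at their onset and
    reverted at onset + 150 ms:

    * reverse -- the two contrasts swap (evidence flips sign),
    * gap     -- both gratings to 50% (evidence removed),
    * positive -- the differential evidence (2d) is added to the target
      contrast and subtracted from the non-target, matching the reverse
      pulse's total contrast change.
    """
    d = float(trial.marginal_contrast_pct)
    # positive pulse adds the differential evidence (2d) on top of the
    # evidence-phase contrasts: 60/40 -> 80/20, total change 40%
    if trial.pulse_type == "positive" and 50.0 + 3.0 * d > 100.0:
        raise ValueError(
            f"marginal contrast {d}% is infeasible for a positive pulse "
            "(target contrast would exceed 100%)"
        )

    total_ms = FADE_MS + BASELINE_MS + EVIDENCE_MS
    t = np.arange(0, total_ms, frame_ms, dtype=float)
    target = np.empty_like(t)
    nontarget = np.empty_like(t)

    fade = t < FADE_MS
    # reach 50% on the final fade frame, strictly increasing from frame 0
    target[fade] = 50.0 * (t[fade] + frame_ms) / FADE_MS
    nontarget[fade] = target[fade]

    base = (t >= FADE_MS) & (t < FADE_MS + BASELINE_MS)
    target[base] = 50.0
    nontarget[base] = 50.0

    ev = t >= FADE_MS + BASELINE_MS
    target[ev] = 50.0 + d
    nontarget[ev] = 50.0 - d

    if trial.pulse_type != "none":
        onset = FADE_MS + BASELINE_MS + trial.pulse_onset_ms
        pulse = (t >= onset) & (t < onset + trial.pulse_duration_ms)
        if trial.pulse_type == "reverse":
            target[pulse], nontarget[pulse] = 50.0 - d, 50.0 + d
        elif trial.pulse_type == "gap":
            target[pulse], nontarget[pulse] = 50.0, 50.0
        else:  # positive
            target[pulse], nontarget[pulse] = 50.0 + 3 * d, 50.0 - 3 * d

    return ContrastTimecourse(t, target, nontarget)


@dataclass(frozen=True)
class ResponseEvent:
    """A response, timed relative to evidence onset (negative = early)."""

    trial_index: int
    time_ms: float


def apply_replacement(
    schedule: Sequence[TrialSpec],
    responses: Iterable[ResponseEvent],
    seed: int = 0,
    block_size: int = BLOCK_SIZE,
) -> list[TrialSpec]:
    """Apply the trial-replacement bookkeeping to a schedule.

    * A response before evidence onset appends an exact replica of that
      trial to the end of its current block.
    * A response before pulse onset (on a pulse trial) adds a triple to
      the end-of-session extra block: an immutable replica plus two
      mutable trials with different cue x pulse-onset combinations,
      sampled uniformly without replacement from the remaining
      alternatives. Subsequent early responses swap a mutable trial for
      a replica when one is available; a fresh triple is added when no
      mutable trial remains or more than 20% of the extra block already
      shares the pulse type.

    With an empty response list the schedule is returned unchanged.
    """
    schedule = list(schedule)
    rng = np.random.default_rng(seed)
    n_main = len(schedule)
    # per-block lists so replicas land at the end of their own block
    blocks: list[list[TrialSpec]] = [
        schedule[i : i + block_size] for i in range(0, n_main, block_size)
    ]
    extra: list[TrialSpec] = []

    def alternative_conditions(trial: TrialSpec) -> list[tuple[str, int]]:
        combos = [
            (cue, onset)
            for cue in CUES
            for onset in pulse_onsets()
            if not (cue == trial.cue and onset == trial.pulse_onset_ms)
        ]
        return combos

    def add_triple(trial: TrialSpec) -> None:
        extra.append(dataclasses.replace(trial, immutable=True))
        combos = alternative_conditions(trial)
        picks = rng.choice(len(combos), size=2, replace=False)
        for p in picks:
            cue, onset = combos[p]
            extra.append(
                dataclasses.replace(trial, cue=cue, pulse_onset_ms=onset, immutable=False)
            )

    for ev in responses:
        trial = schedule[ev.trial_index]
        if ev.time_ms < 0:
            block = blocks[ev.trial_index // block_size]
            block.append(dataclasses.replace(trial, immutable=False))
            continue
        if trial.pulse_type == "none" or ev.time_ms >= trial.pulse_onset_ms:
            continue
        # early response on a pulse trial: re-present via the extra block
        mutable = [i for i, tr in enumerate(extra) if not tr.immutable]
        same_type = sum(tr.pulse_type == trial.pulse_type for tr in extra)
        crowded = len(extra) > 0 and same_type / len(extra) > 0.20
        if not mutable or crowded:
            add_triple(trial)
        else:
            extra[mutable[0]] = dataclasses.replace(trial, immutable=True)

    out = [tr for block in blocks for tr in block] + extra
    return [
        dataclasses.replace(tr, trial_index=i, half_cycle_phase=bool(i % 2))
        for i, tr in enumerate(out)
    ]


def score_response(
    correct: Optional[bool],
    rt_ms: Optional[float],
    deadline_ms: int = RESPONSE_DEADLINE_MS,
) -> FeedbackOutcome:
    """Points feedback: +50 correct, -25 error / too-fast / too-slow."""
    if rt_ms is None:
        return FeedbackOutcome(-25, "too_slow")
    if rt_ms < 0:
        return FeedbackOutcome(-25, "too_fast")
    if rt_ms > deadline_ms:
        return FeedbackOutcome(-25, "too_slow")
    if correct:
        return FeedbackOutcome(+50, "correct")
    return FeedbackOutcome(-25, "error")


# ---------------------------------------------------------------------------
# schedule CSV round-trip

SCHEDULE_COLUMNS = [
    "session_index", "trial_index", "cue", "target_tilt", "target_tag_hz",
    "pulse_type", "pulse_onset_ms", "marginal_contrast_pct",
    "pulse_duration_ms", "immutable", "half_cycle_phase",
]


def schedule_to_frame(schedule: Sequence[TrialSpec]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(t) for t in schedule])
    return df[SCHEDULE_COLUMNS]


def schedule_to_csv(schedule: Sequence[TrialSpec], path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def schedule_from_csv(path) -> list[TrialSpec]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if pd.isna(d["pulse_onset_ms"]):
            d["pulse_onset_ms"] = None
        else:
            d["pulse_onset_ms"] = int(d["pulse_onset_ms"])
        out.append(TrialSpec(**{k: d[k] for k in SCHEDULE_COLUMNS if k in d}))
    return out
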