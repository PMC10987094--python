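"""Adaptive titration procedures and a simulated psychometric observer.

A session's calibration phase estimates the contrast differential that
yields ~70% correct: two interleaved one-up-two-down staircases (same-
frequency gratings), a one-up-one-down staircase probing the perceptual
"flicker bias" between the 20 and 25 Hz gratings (converges to the 50%
choice point), a 60-trial QUEST run targeting 70% correct, and a 30-trial
verification block with a +/-5% adjust-or-rerun rule.

The human participant is stood in for by :class:`Observer`, a Weibull
2AFC psychometric observer parameterised directly by its 70%-correct
threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TARGET_P = 0.70  # accuracy the titration procedures aim for


@dataclass(frozen=True)
class Observer:
    """Weibull 2AFC observer.

    ``threshold_pct`` is the contrast differential (%) at which the
    observer scores ``target_p`` (70%) correct. ``flicker_bias_pct`` is a
    perceptual bias toward the 20 Hz grating, expressed as the contrast
    boost (%) the 25 Hz grating needs to be chosen half the time;
    ``bias_slope_pct`` is the logistic width of that choice function.
    """

    threshold_pct: float = 15.0
    slope: float = 3.5
    lapse_rate: float = 0.02
    guess_rate: float = 0.5
    target_p: float = TARGET_P
    flicker_bias_pct: float = 0.0
    bias_slope_pct: float = 4.0

    def __post_init__(self):
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if self.guess_rate != 0.5:
            raise ValueError("guess_rate is 0.5 for 2AFC")

    def p_correct(self, contrast_diff_pct) -> np.ndarray:
        """P(correct) at a contrast differential (vectorised)."""
        x = np.asarray(contrast_diff_pct, dtype=float)
        return weibull_p_correct(
            x, self.threshold_pct, self.slope, self.lapse_rate,
            self.guess_rate, self.target_p,
        )

    def p_choose_favoured(self, boost_pct) -> np.ndarray:
        """P(choose the favoured 20 Hz grating) given a 25 Hz boost (%)."""
        b = np.asarray(boost_pct, dtype=float)
        return 1.0 / (1.0 + np.exp((b - self.flicker_bias_pct) / self.bias_slope_pct))


def weibull_scale(threshold: float, slope: float, lapse: float,
                  guess: float, target_p: float) -> float:
    """Weibull scale parameter placing ``threshold`` at ``target_p`` correct."""
    top = 1.0 - lapse - guess
    frac = (target_p - guess) / top
    if not 0.0 < frac < 1.0:
        raise ValueError("target_p unreachable for these guess/lapse rates")
    return threshold / (-np.log1p(-frac)) ** (1.0 / slope)


def weibull_p_correct(x, threshold, slope, lapse, guess, target_p=TARGET_P):
    s = weibull_scale(threshold, slope, lapse, guess, target_p)
    x = np.asarray(x, dtype=float)
    return guess + (1.0 - lapse - guess) * (1.0 - np.exp(-((x / s) ** slope)))


def observer_respond(obs: Observer, contrast_diff_pct: float, seed=None) -> bool:
    """One Bernoulli correct/error draw. ``seed`` may be an int or Generator."""
    if not 0.0 <= contrast_diff_pct <= 100.0:
        raise ValueError("contrast differential must lie in [0, 100]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return bool(rng.random() < obs.p_correct(contrast_diff_pct))


# ---------------------------------------------------------------------------
# up-down staircases

@dataclass
class StaircaseState:
    """State of a transformed up-down staircase on the contrast axis.

    ``one_up_two_down`` steps down after two consecutive correct
    responses and up after any error (converges at p = sqrt(0.5) ~ 70.7%
    correct); ``one_up_one_down`` steps down after each correct and up
    after each error (50% point). The step halves at each reversal down
    to ``step_floor_pct``. Terminates after ``max_reversals`` reversals
    or ``max_trials`` trials, whichever comes first.
    """

    rule: str = "one_up_two_down"
    current_level_pct: float = 100.0
    step_pct: float = 8.0
    step_floor_pct: float = 1.0
    max_reversals: int = 4
    max_trials: int = 50
    lower_bound: float = 0.0
    upper_bound: float = 100.0
    n_reversals: int = 0
    trial_count: int = 0
    history: list = field(default_factory=list)
    reversal_levels: list = field(default_factory=list)
    _streak: int = 0
    _last_direction: int = 0

    def __post_init__(self):
        if self.rule not in ("one_up_two_down", "one_up_one_down"):
            raise ValueError(f"unknown staircase rule {self.rule!r}")

    @property
    def terminated(self) -> bool:
        return self.n_reversals >= self.max_reversals or self.trial_count >= self.max_trials

    def converged_level(self) -> float:
        """Level estimate: mean of reversal levels (current level if none)."""
        if self.reversal_levels:
            return float(np.mean(self.reversal_levels))
        return float(self.current_level_pct)


def staircase_step(state: StaircaseState, response: bool) -> StaircaseState:
    """Advance a staircase by one trial; returns a new state."""
    if state.terminated:
        raise RuntimeError("cannot step a terminated staircase")

    s = dataclasses.replace(
        state,
        history=state.history + [(state.current_level_pct, bool(response))],
        trial_count=state.trial_count + 1,
    )
    direction = 0
    if s.rule == "one_up_one_down":
        direction = -1 if response else +1
    else:  # one_up_two_down
        if response:
            s._streak += 1
            if s._streak >= 2:
                direction = -1
                s._streak = 0
        else:
            s._streak = 0
            direction = +1

    if direction != 0:
        if s._last_direction != 0 and direction != s._last_direction:
            s.n_reversals += 1
            s.reversal_levels = s.reversal_levels + [s.current_level_pct]
            s.step_pct = max(s.step_pct / 2.0, s.step_floor_pct)
        s._last_direction = direction
        s.current_level_pct = float(
            np.clip(s.current_level_pct + direction * s.step_pct,
                    s.lower_bound, s.upper_bound)
        )
    return s


def run_staircase(
    state: StaircaseState,
    respond,
    rng: np.random.Generator,
) -> StaircaseState:
    """Drive a staircase against ``respond(level, rng) -> bool`` until it stops."""
    while not state.terminated:
        state = staircase_step(state, respond(state.current_level_pct, rng))
    return state


def staircase_convergence_level(
    rule: str,
    respond,
    rng: np.random.Generator,
    start_level_pct: float,
    n_trials: int = 400,
    burn_reversals: int = 4,
    step_pct: float = 8.0,
    lower_bound: float = 0.0,
    upper_bound: float = 100.0,
) -> float:
    """Convergence point of an up-down rule, from an extended run.

    The session procedure terminates a staircase after four reversals,
    which leaves the level estimate far from the rule's equilibrium when
    the run starts at 100% differential (a lapse anywhere on the descent
    spends a reversal). To characterise where the rule converges, run it
    for ``n_trials`` with the reversal cap lifted and average the
    reversal levels after discarding the first ``burn_reversals``
    (standard burn-in practice).
    """
    state = StaircaseState(
        rule=rule, current_level_pct=start_level_pct, step_pct=step_pct,
        max_trials=n_trials, max_reversals=10**9,
        lower_bound=lower_bound, upper_bound=upper_bound,
    )
    state = run_staircase(state, respond, rng)
    levels = state.reversal_levels[burn_reversals:]
    if not levels:
        return state.converged_level()
    return float(np.mean(levels))


# ---------------------------------------------------------------------------
# QUEST

@dataclass
class QuestState:
    """Grid posterior over log10 threshold for a fixed Weibull shape.

    The assumed psychometric model is a Weibull with beta=3.5, gamma=0.5
    and a 2% lapse; the threshold parameter is defined at 70% correct (the
    same parameterisation as :class:`Observer`). The prior is lognormal,
    centred at 20% differential.
    """

    beta: float = 3.5
    gamma: float = 0.5
    lapse: float = 0.02
    target_p: float = TARGET_P
    grid_lo_pct: float = 0.5
    grid_hi_pct: float = 100.0
    n_grid: int = 256
    prior_mode_pct: float = 20.0
    prior_sd_log10: float = 0.5
    trial_count: int = 0
    log_grid: np.ndarray = field(init=False)
    posterior: np.ndarray = field(init=False)

    def __post_init__(self):
        self.log_grid = np.linspace(
            np.log10(self.grid_lo_pct), np.log10(self.grid_hi_pct), self.n_grid
        )
        prior = np.exp(-0.5 * ((self.log_grid - np.log10(self.prior_mode_pct))
                               / self.prior_sd_log10) ** 2)
        self.posterior = prior / prior.sum()

    def p_correct_given_threshold(self, level_pct: float) -> np.ndarray:
        th = 10.0 ** self.log_grid
        return weibull_p_correct(level_pct, th, self.beta, self.lapse,
                                 self.gamma, self.target_p)

    def update(self, level_pct: float, response: bool) -> None:
        p = self.p_correct_given_threshold(level_pct)
        like = p if response else 1.0 - p
        post = self.posterior * like
        total = post.sum()
        if total <= 0 or not np.isfinite(total):
            raise RuntimeError("degenerate QUEST posterior (all mass at a bound)")
        self.posterior = post / total
        self.trial_count += 1

    def mean_threshold_pct(self) -> float:
        return float(10.0 ** np.dot(self.posterior, self.log_grid))

    def median_threshold_pct(self) -> float:
        """Posterior-median threshold; better calibrated than the mean here."""
        c = np.cumsum(self.posterior)
        return float(10.0 ** self.log_grid[np.searchsorted(c, 0.5)])


@dataclass(frozen=True)
class QuestResult:
    estimate_pct: float
    sd_pct: float  # posterior spread, the "margin of error" of the estimate
    insufficient_practice: bool
    n_trials: int


INSUFFICIENT_PRACTICE_PCT = 65.0  # estimate above this flags too little practice


def quest_run(
    obs: Observer,
    n_trials: int = 60,
    seed=None,
    initial_level_pct: Optional[float] = None,
    quest: Optional[QuestState] = None,
) -> QuestResult:
    """Run a QUEST titration against a simulated observer.

    Each trial is placed at the current posterior-median threshold (the
    first at ``initial_level_pct`` when given, standing in for the final
    practice-block differential). Returns the posterior-median estimate
    (the mean of the right-skewed posterior overshoots the 70% point by
    ~2 accuracy points at 60 trials) and flags estimates above 65% as
    indicating insufficient practice.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    q = quest if quest is not None else QuestState()
    level = float(initial_level_pct) if initial_level_pct is not None else q.median_threshold_pct()
    for _ in range(n_trials):
        level = float(np.clip(level, q.grid_lo_pct, q.grid_hi_pct))
        q.update(level, observer_respond(obs, level, rng))
        level = q.median_threshold_pct()
    est = q.median_threshold_pct()
    mean_log = np.dot(q.posterior, q.log_grid)
    sd_log = np.sqrt(np.dot(q.posterior, (q.log_grid - mean_log) ** 2))
    sd_pct = est * (10.0 ** sd_log - 1.0)
    return QuestResult(
        estimate_pct=est,
        sd_pct=float(sd_pct),
        insufficient_practice=est > INSUFFICIENT_PRACTICE_PCT,
        n_trials=q.trial_count,
    )


@dataclass(frozen=True)
class VerificationResult:
    accuracy: float
    adjusted_contrast_pct: float
    rerun: bool


def verify_titration(
    obs: Observer,
    contrast_diff_pct: float,
    n_trials: int = 30,
    quest_margin_pct: float = 1.0,
    seed=None,
) -> VerificationResult:
    """30-trial verification of a titrated differential.

    If accuracy differs from 70% by less than 5 percentage points the
    differential is nudged by the QUEST margin in the corrective
    direction and the main task proceeds; a deviation of 5 points or
    more also sets the rerun flag. Accuracy of exactly 70% leaves the
    contrast untouched.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    correct = rng.random(n_trials) < obs.p_correct(contrast_diff_pct)
    acc = float(correct.mean())
    direction = np.sign(TARGET_P - acc)  # below target -> raise the contrast
    adjusted = float(np.clip(contrast_diff_pct + direction * quest_margin_pct, 0.0, 100.0))
    return VerificationResult(
        accuracy=acc,
        adjusted_contrast_pct=adjusted,
        rerun=abs(acc - TARGET_P) >= 0.05,
    )


def flicker_bias_staircase(
    obs: Observer,
    seed=None,
    initial_boost_pct: float = 0.0,
    step_pct: float = 8.0,
    max_trials: int = 60,
) -> StaircaseState:
    """One-up-one-down staircase on the 25 Hz contrast boost.

    The 25 Hz grating is always the nominal correct answer; choosing it
    counts as "correct" and lowers the boost, so the staircase converges
    on the boost at which the two gratings are chosen equally often.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    state = StaircaseState(
        rule="one_up_one_down",
        current_level_pct=initial_boost_pct,
        step_pct=step_pct,
        max_trials=max_trials,
        lower_bound=-100.0,
    )
    def respond(level, rng):
        return bool(rng.random() >= obs.p_choose_favoured(level))  # chose 25 Hz
    return run_staircase(state, respond, rng)
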