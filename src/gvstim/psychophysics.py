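"""3-down-1-up two-alternative forced-choice staircase for tilt-perception JND.

The stimulator evokes a virtual tilt whose direction follows the
current's polarity (+ right, - left).  The just-noticeable difference
(JND) is estimated adaptively: after three consecutive correct
left/right judgements the intensity drops one step, after any incorrect
judgement it rises one step, and the session ends after a fixed number
of reversals (trials at which the step direction changes).  The 3D1U
rule converges on the stimulus level answered correctly with
probability ``0.5^(1/3) ~ 0.794``.

For validation the module provides a simulated observer with a
cumulative-Gaussian psychometric function

    P(correct | x) = gamma + (1 - gamma - lambda) * Phi((x - theta)/s)

with guess rate ``gamma = 0.5`` (2AFC), lapse rate ``lambda`` and
threshold/spread ``theta``/``s``; its analytic 79.37 %-correct point is
``theta + s * Phi^{-1}((0.7937 - 0.5)/(0.5 - lambda))``, which seeded
sessions should recover.

Group statistics (per-sex means/SDs, Welch's t-test) mirror how JND
results are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConfigError,
    InsufficientDataError,
    RunawayError,
    StaircaseStateError,
)


@dataclass(frozen=True)
class StaircaseConfig:
    """Adaptive-track rule parameters (currents in mA)."""

    initial_mA: float = 1.6
    step_mA: float = 0.1
    down_count: int = 3
    up_count: int = 1
    reversal_limit: int = 6
    min_mA: float = 0.1
    max_mA: float = 1.8

    def __post_init__(self) -> None:
        if self.step_mA <= 0:
            raise ConfigError("step_mA must be > 0")
        if not (self.min_mA < self.initial_mA <= self.max_mA):
            raise ConfigError("require min_mA < initial_mA <= max_mA")
        if self.reversal_limit < 2:
            raise ConfigError("reversal_limit must be >= 2")
        if self.down_count < 1 or self.up_count != 1:
            raise ConfigError("rule is n-down-1-up: down_count >= 1, up_count == 1")
        if self.max_mA > 4.0:
            raise ConfigError("max_mA above the 4 mA safety limit")


@dataclass(frozen=True)
class StaircaseState:
    """Immutable snapshot of an adaptive track between trials."""

    level_mA: float
    correct_streak: int = 0
    last_step_direction: int = 0  # -1 down, 0 none yet, +1 up
    reversal_levels: tuple = ()
    trial_index: int = 0
    finished: bool = False


def initial_state(cfg: StaircaseConfig) -> StaircaseState:
    return StaircaseState(level_mA=cfg.initial_mA)


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial: polarity +1 means rightward tilt, -1 leftward."""

    participant_id: str
    trial_index: int
    polarity: int
    intensity_mA: float
    response: str  # "left" or "right"
    correct: bool
    reversal: bool


@dataclass(frozen=True)
class ObserverModel:
    """Cumulative-Gaussian 2AFC observer for staircase validation."""

    threshold_mA: float
    spread_mA: float
    lapse_rate: float = 0.02
    guess_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold_mA <= 0 or self.spread_mA <= 0:
            raise ConfigError("threshold_mA and spread_mA must be > 0")
        if not (0.0 <= self.lapse_rate < 0.5):
            raise ConfigError("lapse_rate must be in [0, 0.5)")

    def p_correct(self, intensity_mA: float) -> float:
        g, lam = self.guess_rate, self.lapse_rate
        z = (intensity_mA - self.threshold_mA) / self.spread_mA
        return g + (1.0 - g - lam) * stats.norm.cdf(z)

    def analytic_convergence_mA(self, down_count: int = 3) -> float:
        """Stimulus level where P(correct) equals the n-down-1-up point."""
        p = convergence_point(down_count)
        target = (p - self.guess_rate) / (1.0 - self.guess_rate - self.lapse_rate)
        return self.threshold_mA + self.spread_mA * stats.norm.ppf(target)


@dataclass(frozen=True)
class JndEstimate:
    """JND summary for one session (or participant)."""

    jnd_mA: float
    n_trials: int
    n_reversals: int
    reversal_levels: tuple


def staircase_update(
    cfg: StaircaseConfig, state: StaircaseState, correct: bool
) -> StaircaseState:
    """Advance the staircase by one trial outcome.

    Three consecutive correct responses step the level down; any
    incorrect response steps it up; the streak resets after every step
    and after every incorrect response.  A step whose direction differs
    from the previous step's records a reversal at the pre-step level.
    The track finishes once ``reversal_limit`` reversals are recorded;
    levels are clamped to ``[min_mA, max_mA]`` (a clamped step still
    counts as a reversal only via its direction).
    """
    if state.finished:
        raise StaircaseStateError("staircase already finished")
    step_dir = 0
    streak = state.correct_streak
    if correct:
        streak += 1
        if streak >= cfg.down_count:
            step_dir = -1
            streak = 0
    else:
        step_dir = +1
        streak = 0
    reversals = state.reversal_levels
    level = state.level_mA
    if step_dir != 0:
        if state.last_step_direction != 0 and step_dir != state.last_step_direction:
            reversals = reversals + (level,)
        level = min(max(level + step_dir * cfg.step_mA, cfg.min_mA), cfg.max_mA)
    return StaircaseState(
        level_mA=round(level, 12),
        correct_streak=streak,
        last_step_direction=step_dir if step_dir != 0 else state.last_step_direction,
        reversal_levels=reversals,
        trial_index=state.trial_index + 1,
        finished=len(reversals) >= cfg.reversal_limit,
    )


def observer_response(
    obs: ObserverModel, intensity_mA: float, polarity: int, rng: np.random.Generator
) -> str:
    """Simulated left/right judgement for one stimulus presentation."""
    if intensity_mA < 0:
        raise ConfigError("intensity_mA must be >= 0")
    correct = rng.random() < obs.p_correct(intensity_mA)
    toward = "right" if polarity > 0 else "left"
    away = "left" if polarity > 0 else "right"
    return toward if correct else away


def run_session(
    cfg: StaircaseConfig,
    observer: ObserverModel,
    seed: int,
    participant_id: str = "sim",
    trial_cap: int = 500,
) -> "tuple[list[TrialRecord], JndEstimate]":
    """Drive one full staircase session with a simulated observer.

    Polarity is drawn uniformly per trial; the observer's judgement
    feeds :func:`staircase_update` until the reversal limit is reached.
    Fully reproducible per seed.

    Raises
    ------
    RunawayError
        If the track has not finished after ``trial_cap`` trials.
    """
    rng = np.random.default_rng(seed)
    state = initial_state(cfg)
    records: list[TrialRecord] = []
    while not state.finished:
        if state.trial_index >= trial_cap:
            raise RunawayError(
                f"staircase not finished after {trial_cap} trials"
            )
        polarity = 1 if rng.random() < 0.5 else -1
        response = observer_response(observer, state.level_mA, polarity, rng)
        correct = response == ("right" if polarity > 0 else "left")
        prev_reversals = len(state.reversal_levels)
        new_state = staircase_update(cfg, state, correct)
        records.append(
            TrialRecord(
                participant_id=participant_id,
                trial_index=state.trial_index,
                polarity=polarity,
                intensity_mA=state.level_mA,
                response=response,
                correct=correct,
                reversal=len(new_state.reversal_levels) > prev_reversals,
            )
        )
        state = new_state
    return records, estimate_jnd(state.reversal_levels, n_trials=state.trial_index)


def estimate_jnd(
    reversal_levels: Sequence[float],
    n_trials: Optional[int] = None,
    last_n: Optional[int] = None,
) -> JndEstimate:
    """JND as the mean of recorded reversal levels.

    By default all reversals are averaged; ``last_n`` selects only the
    final ``n`` (a common alternative that discards the initial descent).

    Raises
    ------
    InsufficientDataError
        With fewer than two reversals.
    """
    levels = tuple(float(x) for x in reversal_levels)
    if len(levels) < 2:
        raise InsufficientDataError(
            f"need >= 2 reversals to estimate a JND, got {len(levels)}"
        )
    used = levels[-last_n:] if last_n else levels
    if len(used) < 2:
        raise InsufficientDataError("last_n leaves fewer than 2 reversals")
    return JndEstimate(
        jnd_mA=float(np.mean(used)),
        n_trials=n_trials if n_trials is not None else 0,
        n_reversals=len(levels),
        reversal_levels=levels,
    )


def jnd_from_records(records: Iterable[TrialRecord], last_n: Optional[int] = None) -> JndEstimate:
    """JND from a trial log: reversal trials' intensities are averaged."""
    records = list(records)
    levels = [r.intensity_mA for r in records if r.reversal]
    return estimate_jnd(levels, n_trials=len(records), last_n=last_n)


def convergence_point(down_count: int, up_count: int = 1) -> float:
    """Equilibrium P(correct) of the n-down-1-up rule: ``0.5**(1/n)``."""
    if down_count < 1 or up_count != 1:
        raise ConfigError("rule is n-down-1-up: down_count >= 1, up_count == 1")
    return 0.5 ** (1.0 / down_count)


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]):
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite fractional
    degrees of freedom and a two-sided p-value.  Two zero-variance
    groups with equal means return ``(0, n-2, 1)`` rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise InsufficientDataError("zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def summarize_group(
    jnds_mA: Sequence[float], labels: Optional[Sequence] = None
) -> dict:
    """Sample mean and SD (n-1 denominator) overall or per group label.

    Returns ``{group: (mean, sd, n)}``; with no labels the single key is
    ``"all"``.  A single-member group reports SD 0.0.
    """
    jnds = np.asarray(jnds_mA, dtype=float)
    if len(jnds) == 0:
        raise InsufficientDataError("empty group")
    if labels is None:
        labels = ["all"] * len(jnds)
    if len(labels) != len(jnds):
        raise ConfigError("labels and jnds lengths differ")
    out: dict = {}
    for g in dict.fromkeys(labels):  # preserves first-seen order
        vals = jnds[[i for i, lab in enumerate(labels) if lab == g]]
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[g] = (float(np.mean(vals)), sd, int(len(vals)))
    return out
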