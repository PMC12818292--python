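"""Adaptive forced-choice threshold staircase: state machine, scorer, simulator.

The clinical threshold test presents n-butanol triplets at 16 dilution levels
(level 1 strongest, level 16 weakest).  The procedure has two phases:

* **initial descent** — triplets 16, 14, 12, … are presented in order of
  increasing intensity until one is identified correctly twice in succession;
  that level is the first turning point.  A participant who reaches level 1
  without two successive corrects is excluded (suspected anosmia).
* **main staircase** — a single 2-down/1-up staircase on concentration: two
  successive corrects at a level move one level weaker (level number + 1),
  any incorrect moves one level stronger (level number − 1).  Each direction
  reversal records a turning point at the level at which it occurred.

The run ends when seven turning points have been recorded; the T score is the
mean of the last four.  Boundary rule: two successive corrects at the weakest
level (or an incorrect at the strongest) record a turning point at the
boundary and hold the level, so that extreme observers still terminate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Phase",
    "Direction",
    "StaircaseConfig",
    "StaircaseState",
    "ThresholdResult",
    "StaircaseStateError",
    "IncompleteStaircaseError",
    "new_staircase",
    "staircase_step",
    "threshold_score",
    "run_threshold_test",
    "step_responder",
]


class Phase(enum.Enum):
    INITIAL = "initial"
    MAIN = "main"
    DONE = "done"
    EXCLUDED = "excluded"


class Direction(enum.Enum):
    TOWARD_WEAKER = "toward_weaker"
    TOWARD_STRONGER = "toward_stronger"
    NONE = "none"


class StaircaseStateError(RuntimeError):
    """Stepping a finished or excluded staircase."""


class IncompleteStaircaseError(ValueError):
    """Scoring a staircase without the required number of turning points."""


@dataclass(frozen=True)
class StaircaseConfig:
    n_levels: int = 16
    initial_start: int = 16
    initial_step: int = 2  # descent in level number per initial-phase miss
    required_turning_points: int = 7
    t_from_last: int = 4
    max_main_presentations: int = 60

    def __post_init__(self) -> None:
        if self.required_turning_points <= self.t_from_last:
            raise ValueError("required_turning_points must exceed t_from_last")
        if not 1 <= self.initial_start <= self.n_levels:
            raise ValueError("initial_start outside level range")


@dataclass(frozen=True)
class StaircaseState:
    phase: Phase
    current_level: int
    direction: Direction
    consecutive_correct: int
    turning_points: tuple[int, ...]
    history: tuple[tuple[int, bool], ...] = ()

    @property
    def n_presentations(self) -> int:
        return len(self.history)


@dataclass(frozen=True)
class ThresholdResult:
    t_score: float | None
    excluded_anosmia: bool
    incomplete: bool
    turning_points: tuple[int, ...]
    history: tuple[tuple[int, bool], ...]


def new_staircase(config: StaircaseConfig = StaircaseConfig()) -> StaircaseState:
    return StaircaseState(
        phase=Phase.INITIAL,
        current_level=config.initial_start,
        direction=Direction.NONE,
        consecutive_correct=0,
        turning_points=(),
    )


def staircase_step(
    state: StaircaseState,
    correct: bool,
    config: StaircaseConfig = StaircaseConfig(),
) -> StaircaseState:
    """Advance the staircase by one presentation at ``state.current_level``."""
    if state.phase in (Phase.DONE, Phase.EXCLUDED):
        raise StaircaseStateError(f"cannot step a staircase in phase {state.phase.value}")
    history = state.history + ((state.current_level, bool(correct)),)
    if state.phase is Phase.INITIAL:
        return _step_initial(state, correct, history, config)
    return _step_main(state, correct, history, config)


def _step_initial(
    state: StaircaseState,
    correct: bool,
    history: tuple[tuple[int, bool], ...],
    config: StaircaseConfig,
) -> StaircaseState:
    level = state.current_level
    if correct:
        if state.consecutive_correct + 1 >= 2:
            # First turning point; the staircase now moves toward weaker.
            return StaircaseState(
                phase=Phase.MAIN,
                current_level=min(level + 1, config.n_levels),
                direction=Direction.TOWARD_WEAKER,
                consecutive_correct=0,
                turning_points=(level,),
                history=history,
            )
        return replace(state, consecutive_correct=1, history=history)
    if level == 1:
        return replace(
            state, phase=Phase.EXCLUDED, consecutive_correct=0, history=history
        )
    # Resume the descent toward stronger triplets (smaller level numbers).
    next_level = max(level - config.initial_step, 1)
    return StaircaseState(
        phase=Phase.INITIAL,
        current_level=next_level,
        direction=Direction.NONE,
        consecutive_correct=0,
        turning_points=(),
        history=history,
    )


def _step_main(
    state: StaircaseState,
    correct: bool,
    history: tuple[tuple[int, bool], ...],
    config: StaircaseConfig,
) -> StaircaseState:
    level = state.current_level
    tps = state.turning_points
    if correct:
        streak = state.consecutive_correct + 1
        if streak < 2:
            return replace(state, consecutive_correct=streak, history=history)
        # Two in a row: move toward weaker; a reversal if we were heading stronger.
        if state.direction is Direction.TOWARD_STRONGER or level == config.n_levels:
            tps = tps + (level,)
        next_level = min(level + 1, config.n_levels)
        direction = Direction.TOWARD_WEAKER
    else:
        # Any incorrect moves toward stronger; a reversal if we were heading weaker.
        if state.direction is Direction.TOWARD_WEAKER or level == 1:
            tps = tps + (level,)
        next_level = max(level - 1, 1)
        direction = Direction.TOWARD_STRONGER
    if len(tps) >= config.required_turning_points:
        return StaircaseState(
            phase=Phase.DONE,
            current_level=level,
            direction=direction,
            consecutive_correct=0,
            turning_points=tps[: config.required_turning_points],
            history=history,
        )
    return StaircaseState(
        phase=Phase.MAIN,
        current_level=next_level,
        direction=direction,
        consecutive_correct=0,
        turning_points=tps,
        history=history,
    )


def threshold_score(
    turning_points: Sequence[int],
    config: StaircaseConfig = StaircaseConfig(),
) -> float:
    """T score: arithmetic mean of the last ``t_from_last`` turning points."""
    if len(turning_points) != config.required_turning_points:
        raise IncompleteStaircaseError(
            f"expected {config.required_turning_points} turning points, "
            f"got {len(turning_points)}"
        )
    return float(np.mean(turning_points[-config.t_from_last :]))


def step_responder(cutoff: float) -> Callable[[int], float]:
    """Deterministic observer: correct iff the level is at most ``cutoff``.

    Level numbers grow with dilution, so low levels (strong odors) are easy.
    """

    def p_correct(level: int) -> float:
        return 1.0 if level <= cutoff else 0.0

    return p_correct


def run_threshold_test(
    responder: Callable[[int], float],
    seed: int | np.random.Generator,
    config: StaircaseConfig = StaircaseConfig(),
) -> ThresholdResult:
    """Drive the staircase against a psychometric function.

    ``responder`` maps a level (1..n_levels) to a probability of a correct
    triplet identification; draws are Bernoulli with the given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = new_staircase(config)
    main_presentations = 0
    while state.phase in (Phase.INITIAL, Phase.MAIN):
        if state.phase is Phase.MAIN:
            if main_presentations >= config.max_main_presentations:
                return ThresholdResult(
                    t_score=None,
                    excluded_anosmia=False,
                    incomplete=True,
                    turning_points=state.turning_points,
                    history=state.history,
                )
            main_presentations += 1
        p = float(responder(state.current_level))
        correct = bool(rng.random() < p)
        state = staircase_step(state, correct, config)
    if state.phase is Phase.EXCLUDED:
        return ThresholdResult(
            t_score=None,
            excluded_anosmia=True,
            incomplete=False,
            turning_points=(),
            history=state.history,
        )
    return ThresholdResult(
        t_score=threshold_score(state.turning_points, config),
        excluded_anosmia=False,
        incomplete=False,
        turning_points=state.turning_points,
        history=state.history,
    )
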