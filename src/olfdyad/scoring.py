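"""Test scoring, ability-similarity and collective-benefit statistics,
conflict classification, and the quartile-based dyad matching procedure.

Scores follow the clinical battery conventions: the discrimination (D) and
identification (I) scores are counts of correct trials out of 16, the
threshold (T) score is a real number in [1, 16], and D+I is used to rank
participants for dyadic matching.  The two dyad-level statistics at the heart
of the analysis are

* similarity ratio  r = S_min / S_max  — the lower over the higher individual
  score within a dyad (1 = equally able members), and
* collective benefit  CB = S_dyad / S_max — the dyad's joint score over its
  better member's score (CB > 1 = the pair beats its best individual).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

N_TRIALS_PER_TASK = 16

__all__ = [
    "SubjectScore",
    "SimilarityMetrics",
    "CollectiveBenefit",
    "ConflictOutcome",
    "ConflictSummary",
    "Dyad",
    "PairedComparison",
    "UndefinedRatioError",
    "MissingDataError",
    "similarity_ratio",
    "collective_benefit",
    "classify_conflict",
    "resolve_conflict_outcome",
    "summarize_conflicts",
    "conflict_percentage",
    "match_dyads",
    "compare_dyad_baselines",
    "paired_comparison",
]


class UndefinedRatioError(ValueError):
    """Raised when a ratio statistic has a zero denominator."""


class MissingDataError(ValueError):
    """Raised when a required answer or joint decision is absent."""


@dataclass(frozen=True)
class SubjectScore:
    """Per-subject, per-day battery scores.

    ``t_score`` is only defined for day 1 (the staircase procedure does not
    admit joint testing and is not repeated on day 2).
    """

    subject_id: str
    day: int
    d_score: int
    i_score: int
    t_score: float | None = None
    age: float | None = None
    gender: str | None = None

    def __post_init__(self) -> None:
        if self.day not in (1, 2):
            raise ValueError(f"day must be 1 or 2, got {self.day}")
        for name, value in (("d_score", self.d_score), ("i_score", self.i_score)):
            if not 0 <= value <= N_TRIALS_PER_TASK:
                raise ValueError(f"{name}={value} outside [0, {N_TRIALS_PER_TASK}]")
        if self.t_score is not None and self.day != 1:
            raise ValueError("t_score is only defined on day 1")

    @property
    def di_sum(self) -> int:
        return self.d_score + self.i_score


@dataclass(frozen=True)
class SimilarityMetrics:
    dyad_id: str | None
    task: str | None
    s_min: float
    s_max: float

    @property
    def ratio(self) -> float:
        return self.s_min / self.s_max


@dataclass(frozen=True)
class CollectiveBenefit:
    dyad_id: str | None
    task: str | None
    s_dyad: float
    s_max: float

    @property
    def cb(self) -> float:
        return self.s_dyad / self.s_max


class ConflictOutcome(enum.Enum):
    SUCCESS = "success"
    FAILURE = "failure"
    EXCLUDED_BOTH_WRONG = "excluded_both_wrong"
    EXCLUDED_BOTH_CORRECT = "excluded_both_correct"
    NOT_CONFLICT = "not_conflict"


@dataclass(frozen=True)
class ConflictSummary:
    """Conflict counts for one dyad/task block of trials.

    ``n_resolvable`` counts conflicts with exactly one correct member; the
    resolution rate is computed over that restricted denominator, because a
    conflict in which both members are wrong cannot be "resolved" by picking
    either initial answer.
    """

    dyad_id: str | None
    task: str | None
    n_trials: int
    n_conflicts: int
    n_resolvable: int
    n_resolved: int
    n_both_wrong: int
    n_both_correct_agreeing: int

    @property
    def pct_conflicts(self) -> float:
        return conflict_percentage(self.n_conflicts, self.n_trials)

    @property
    def resolution_rate(self) -> float | None:
        if self.n_resolvable == 0:
            return None
        return self.n_resolved / self.n_resolvable


def similarity_ratio(
    score_a: float,
    score_b: float,
    *,
    dyad_id: str | None = None,
    task: str | None = None,
) -> SimilarityMetrics:
    """S_min / S_max for the two members' scores (order-invariant)."""
    if score_a < 0 or score_b < 0:
        raise ValueError("scores must be non-negative")
    s_min, s_max = sorted((float(score_a), float(score_b)))
    if s_max == 0:
        raise UndefinedRatioError("similarity ratio undefined when both scores are 0")
    return SimilarityMetrics(dyad_id=dyad_id, task=task, s_min=s_min, s_max=s_max)


def collective_benefit(
    s_dyad: float,
    score_a: float,
    score_b: float,
    *,
    dyad_id: str | None = None,
    task: str | None = None,
) -> CollectiveBenefit:
    """Dyad joint score over the better member's individual score."""
    s_max = max(float(score_a), float(score_b))
    if s_max <= 0:
        raise UndefinedRatioError("collective benefit undefined when the best score is 0")
    return CollectiveBenefit(dyad_id=dyad_id, task=task, s_dyad=float(s_dyad), s_max=s_max)


def classify_conflict(answer_a: object, answer_b: object) -> bool:
    """True iff the two private answers differ (exact label equality)."""
    if answer_a is None or answer_b is None:
        raise MissingDataError("both individual answers are required")
    return answer_a != answer_b


def resolve_conflict_outcome(
    answer_a: object,
    answer_b: object,
    correct_answer: object,
    joint_answer: object,
) -> ConflictOutcome:
    """Classify one trial's conflict-resolution outcome.

    Resolution success/failure is only defined for conflicts where exactly one
    member was initially correct; both-wrong and (the logically impossible for
    forced choice, but guarded) both-correct conflicts are flagged excluded.
    """
    if not classify_conflict(answer_a, answer_b):
        return ConflictOutcome.NOT_CONFLICT
    if joint_answer is None:
        raise MissingDataError("joint answer required to resolve a conflict")
    correct_a = answer_a == correct_answer
    correct_b = answer_b == correct_answer
    if correct_a and correct_b:
        return ConflictOutcome.EXCLUDED_BOTH_CORRECT
    if not correct_a and not correct_b:
        return ConflictOutcome.EXCLUDED_BOTH_WRONG
    if joint_answer == correct_answer:
        return ConflictOutcome.SUCCESS
    return ConflictOutcome.FAILURE


def summarize_conflicts(
    trials: Iterable[tuple[object, object, object, object]],
    *,
    dyad_id: str | None = None,
    task: str | None = None,
) -> ConflictSummary:
    """Summarize conflicts over one dyad/task block.

    ``trials`` yields ``(answer_a, answer_b, correct_answer, joint_answer)``
    tuples.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("empty trial set")
    n_conflicts = n_resolvable = n_resolved = n_both_wrong = n_both_correct = 0
    for answer_a, answer_b, correct_answer, joint_answer in trials:
        outcome = resolve_conflict_outcome(answer_a, answer_b, correct_answer, joint_answer)
        if outcome is ConflictOutcome.NOT_CONFLICT:
            continue
        n_conflicts += 1
        if outcome is ConflictOutcome.EXCLUDED_BOTH_WRONG:
            n_both_wrong += 1
        elif outcome is ConflictOutcome.EXCLUDED_BOTH_CORRECT:
            n_both_correct += 1
        else:
            n_resolvable += 1
            if outcome is ConflictOutcome.SUCCESS:
                n_resolved += 1
    return ConflictSummary(
        dyad_id=dyad_id,
        task=task,
        n_trials=len(trials),
        n_conflicts=n_conflicts,
        n_resolvable=n_resolvable,
        n_resolved=n_resolved,
        n_both_wrong=n_both_wrong,
        n_both_correct_agreeing=n_both_correct,
    )


def conflict_percentage(n_conflicts: float, n_trials: int) -> float:
    """Conflicts as a percentage of trials (accepts fractional means)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return 100.0 * n_conflicts / n_trials


@dataclass(frozen=True)
class Dyad:
    dyad_id: str
    member_a: str
    member_b: str
    similarity_group: str  # "high_similarity" | "low_similarity"

    @property
    def members(self) -> tuple[str, str]:
        return (self.member_a, self.member_b)


def match_dyads(
    day1_scores: Sequence[SubjectScore],
    seed: int | np.random.Generator,
) -> list[Dyad]:
    """Quartile-based dyadic matching on day-1 D+I scores.

    Participants are ranked by D+I; the middle two quartiles are randomly
    paired with each other (high-similarity dyads) while top-quartile members
    are randomly paired with bottom-quartile members (low-similarity dyads).
    Quartile boundaries for n not divisible by 4 are ``ceil(n/4)`` and
    ``floor(3n/4)`` on the ranked list, with ties broken by stable subject-id
    order.  Odd leftovers in a pool are dropped with a logged warning.
    """
    if len(day1_scores) < 4:
        raise ValueError("dyadic matching needs at least 4 participants")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    ranked = sorted(day1_scores, key=lambda s: (s.di_sum, str(s.subject_id)))
    n = len(ranked)
    lo_cut = math.ceil(n / 4)
    hi_cut = math.floor(3 * n / 4)
    bottom = [s.subject_id for s in ranked[:lo_cut]]
    middle = [s.subject_id for s in ranked[lo_cut:hi_cut]]
    top = [s.subject_id for s in ranked[hi_cut:]]

    def _shuffled(ids: list[str]) -> list[str]:
        ids = list(ids)
        rng.shuffle(ids)
        return ids

    dyads: list[Dyad] = []
    mid = _shuffled(middle)
    if len(mid) % 2:
        dropped = mid.pop()
        logger.warning("dropping unpaired middle-quartile subject %s", dropped)
    for a, b in zip(mid[0::2], mid[1::2]):
        dyads.append(Dyad(f"dyad{len(dyads) + 1:02d}", a, b, "high_similarity"))

    hi, lo = _shuffled(top), _shuffled(bottom)
    if len(hi) != len(lo):
        k = min(len(hi), len(lo))
        for dropped in hi[k:] + lo[k:]:
            logger.warning("dropping unpaired extreme-quartile subject %s", dropped)
        hi, lo = hi[:k], lo[:k]
    for a, b in zip(hi, lo):
        dyads.append(Dyad(f"dyad{len(dyads) + 1:02d}", a, b, "low_similarity"))
    return dyads


@dataclass(frozen=True)
class PairedComparison:
    """Two-sided paired t-test with a 95% CI on the mean difference."""

    label: str
    mean_diff: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    n: int


def paired_comparison(
    x: Sequence[float],
    y: Sequence[float],
    label: str = "",
    *,
    alpha: float = 0.05,
) -> PairedComparison:
    """Paired t-test of ``x`` against ``y`` (difference = x − y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    n = diff.size
    if np.allclose(diff, diff[0]) and np.isclose(diff.std(ddof=1), 0.0):
        # degenerate paired test: zero-variance differences
        d = float(diff[0])
        t = 0.0 if d == 0 else np.inf * np.sign(d)
        return PairedComparison(
            label=label, mean_diff=d, t=t, df=n - 1,
            p=1.0 if d == 0 else 0.0, ci_low=d, ci_high=d, n=n,
        )
    res = stats.ttest_rel(x, y)
    ci = res.confidence_interval(1 - alpha)
    return PairedComparison(
        label=label,
        mean_diff=float(diff.mean()),
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n=n,
    )


def compare_dyad_baselines(
    dyad_scores: Sequence[float],
    best_scores: Sequence[float],
    mean_scores: Sequence[float],
) -> dict[str, PairedComparison]:
    """Dyad joint score against its two individual baselines.

    Returns two-sided paired tests of the joint score against (a) the better
    member's score and (b) the members' average — the latter being the
    prediction of the coin-flip voting model of joint decisions.
    """
    if not (len(dyad_scores) == len(best_scores) == len(mean_scores)):
        raise ValueError("per-dyad score vectors must be aligned")
    return {
        "dyad_vs_best": paired_comparison(dyad_scores, best_scores, "dyad_vs_best"),
        "dyad_vs_average": paired_comparison(dyad_scores, mean_scores, "dyad_vs_average"),
    }
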