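"""Signal-detection observer model for nAFC olfactory decisions with
confidence, plus dyadic aggregation rules and closed-form benchmarks.

Individual model
----------------
On each m-alternative forced-choice trial the observer draws one evidence
sample per alternative: the target alternative from ``Normal(ability, 1)``,
each distractor independently from ``Normal(0, 1)``.  The choice is the
argmax of the evidence vector, so ``ability`` is the mean evidence advantage
of the target in units of the (unit-variance) sensory noise; ability 0 gives
chance performance (1/m).  Confidence is an ordinal rating obtained by
binning the decision margin (top evidence minus runner-up) after adding
``Normal(0, meta_noise)`` metacognitive noise — a noisy readout of decision
quality, so larger ``meta_noise`` means weaker confidence–accuracy coupling.

Dyadic aggregation rules
------------------------
Agreement always yields the common choice.  On disagreement:

* ``coin_flip_voting`` — pick either member's choice with probability 1/2.
  Expected dyad accuracy is exactly the mean of the members' accuracies.
* ``defer_to_higher_confidence`` — the more confident member's choice wins
  (ties broken by a fair coin).
* ``evidence_sum`` — argmax of the summed evidence vectors; an ideal-pooling
  upper benchmark that no verbal protocol can exceed in this model.

For two-alternative tasks, confidence-based aggregation has the classic
weighted-confidence-sharing closed form s_dyad = (s1 + s2)/sqrt(2), exposed
here as :func:`wcs_oracle`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "TASK_ALTERNATIVES",
    "DyadRule",
    "ObserverParams",
    "SimTrial",
    "default_conf_edges",
    "simulate_individual_trial",
    "simulate_trials",
    "combine_dyad_decision",
    "combine_dyad_decisions",
    "wcs_oracle",
    "simulate_session",
]

TASK_ALTERNATIVES = {"discrimination": 3, "identification": 4}


class DyadRule(enum.Enum):
    COIN_FLIP_VOTING = "coin_flip_voting"
    DEFER_TO_HIGHER_CONFIDENCE = "defer_to_higher_confidence"
    EVIDENCE_SUM = "evidence_sum"


@lru_cache(maxsize=8)
def default_conf_edges(m: int, n_conf_levels: int = 4) -> tuple[float, ...]:
    """Confidence bin edges at the quartiles of the null margin distribution.

    The null margin is the gap between the top two of ``m`` i.i.d. standard
    normals (ability 0); its quantiles are estimated once from a large
    fixed-seed sample, so the edges are deterministic.
    """
    if m < 2 or n_conf_levels < 2:
        raise ValueError("need m >= 2 and at least 2 confidence levels")
    rng = np.random.default_rng(20260921)
    evidence = rng.standard_normal((200_000, m))
    evidence.sort(axis=1)
    margins = evidence[:, -1] - evidence[:, -2]
    qs = np.linspace(0, 1, n_conf_levels + 1)[1:-1]
    return tuple(float(q) for q in np.quantile(margins, qs))


@dataclass(frozen=True)
class ObserverParams:
    """Latent sensitivity and metacognitive parameters of one observer."""

    ability: float
    meta_noise: float = 0.0
    n_conf_levels: int = 4
    conf_bin_edges: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.ability < 0:
            raise ValueError("ability must be non-negative")
        if self.meta_noise < 0:
            raise ValueError("meta_noise must be non-negative")
        if self.n_conf_levels < 2:
            raise ValueError("need at least 2 confidence levels")
        if self.conf_bin_edges is not None:
            edges = tuple(self.conf_bin_edges)
            if list(edges) != sorted(set(edges)):
                raise ValueError("conf_bin_edges must be strictly increasing")
            if len(edges) != self.n_conf_levels - 1:
                raise ValueError("need n_conf_levels - 1 bin edges")

    def edges_for(self, m: int) -> tuple[float, ...]:
        if self.conf_bin_edges is not None:
            return tuple(self.conf_bin_edges)
        return default_conf_edges(m, self.n_conf_levels)


@dataclass(frozen=True)
class SimTrial:
    task: str
    target_index: int
    evidence: tuple[float, ...]
    choice: int
    correct: bool
    conf_margin: float
    confidence: int


def simulate_trials(
    params: ObserverParams,
    m: int,
    n: int,
    rng: np.random.Generator,
    target_index: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized simulation of ``n`` m-AFC trials for one observer.

    Returns arrays: ``evidence`` (n, m) in alternative order, ``choice``,
    ``correct``, ``conf_margin``, ``confidence`` and ``target_index``
    (0-based alternatives).
    """
    if m < 2:
        raise ValueError("need at least 2 alternatives")
    if target_index is None:
        target_index = rng.integers(0, m, size=n)
    else:
        target_index = np.asarray(target_index)
    evidence = rng.standard_normal((n, m))
    evidence[np.arange(n), target_index] += params.ability
    choice = evidence.argmax(axis=1)
    top2 = np.partition(evidence, m - 2, axis=1)[:, -2:]
    margin = top2[:, 1] - top2[:, 0]
    conf_signal = margin + (
        rng.normal(0.0, params.meta_noise, size=n) if params.meta_noise > 0 else 0.0
    )
    edges = np.asarray(params.edges_for(m))
    confidence = np.searchsorted(edges, conf_signal) + 1
    return {
        "evidence": evidence,
        "target_index": target_index,
        "choice": choice,
        "correct": choice == target_index,
        "conf_margin": np.asarray(conf_signal, dtype=float),
        "confidence": confidence,
    }


def simulate_individual_trial(
    params: ObserverParams,
    m: int,
    rng: np.random.Generator,
    task: str | None = None,
) -> SimTrial:
    """One m-AFC trial; see :func:`simulate_trials` for the generative model."""
    arrays = simulate_trials(params, m, 1, rng)
    if task is None:
        task = {3: "discrimination", 4: "identification"}.get(m, f"{m}afc")
    return SimTrial(
        task=task,
        target_index=int(arrays["target_index"][0]),
        evidence=tuple(float(e) for e in arrays["evidence"][0]),
        choice=int(arrays["choice"][0]),
        correct=bool(arrays["correct"][0]),
        conf_margin=float(arrays["conf_margin"][0]),
        confidence=int(arrays["confidence"][0]),
    )


def combine_dyad_decisions(
    trials_a: dict[str, np.ndarray],
    trials_b: dict[str, np.ndarray],
    rule: DyadRule,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorized joint decision for aligned trial arrays of two members."""
    if not np.array_equal(trials_a["target_index"], trials_b["target_index"]):
        raise ValueError("members must face the same targets on each trial")
    choice_a, choice_b = trials_a["choice"], trials_b["choice"]
    n = choice_a.size
    conflict = choice_a != choice_b
    if rule is DyadRule.EVIDENCE_SUM:
        pooled = trials_a["evidence"] + trials_b["evidence"]
        joint = pooled.argmax(axis=1)
    elif rule is DyadRule.COIN_FLIP_VOTING:
        pick_a = rng.random(n) < 0.5
        joint = np.where(pick_a, choice_a, choice_b)
        joint = np.where(conflict, joint, choice_a)
    elif rule is DyadRule.DEFER_TO_HIGHER_CONFIDENCE:
        conf_a, conf_b = trials_a["confidence"], trials_b["confidence"]
        tie_pick_a = rng.random(n) < 0.5
        pick_a = np.where(conf_a == conf_b, tie_pick_a, conf_a > conf_b)
        joint = np.where(pick_a, choice_a, choice_b)
        joint = np.where(conflict, joint, choice_a)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown rule {rule}")
    return {
        "joint_choice": joint,
        "joint_correct": joint == trials_a["target_index"],
        "conflict": conflict,
    }


def combine_dyad_decision(
    trial_a: SimTrial,
    trial_b: SimTrial,
    rule: DyadRule,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    """Joint choice and correctness for a single aligned trial pair."""
    if trial_a.task != trial_b.task or trial_a.target_index != trial_b.target_index:
        raise ValueError("trials are not aligned (task/target mismatch)")
    arrays = combine_dyad_decisions(
        _as_arrays(trial_a), _as_arrays(trial_b), rule, rng
    )
    return int(arrays["joint_choice"][0]), bool(arrays["joint_correct"][0])


def _as_arrays(trial: SimTrial) -> dict[str, np.ndarray]:
    return {
        "evidence": np.asarray([trial.evidence]),
        "target_index": np.asarray([trial.target_index]),
        "choice": np.asarray([trial.choice]),
        "correct": np.asarray([trial.correct]),
        "confidence": np.asarray([trial.confidence]),
    }


def wcs_oracle(s_low: float, s_high: float) -> tuple[float, float]:
    """Weighted-confidence-sharing prediction for a 2AFC dyad.

    Returns ``(s_dyad, cb)`` with ``s_dyad = (s_low + s_high)/sqrt(2)`` and
    ``cb = s_dyad / s_high``.  The collective benefit exceeds 1 exactly when
    the ability ratio s_low/s_high exceeds sqrt(2) − 1.
    """
    if s_low <= 0 or s_high <= 0:
        raise ValueError("sensitivities must be positive")
    if s_low > s_high:
        raise ValueError("s_low must not exceed s_high")
    s_dyad = (s_low + s_high) / math.sqrt(2)
    return s_dyad, s_dyad / s_high


def simulate_session(
    params_a: ObserverParams,
    params_b: ObserverParams,
    rule: DyadRule,
    n_trials: int,
    task: str,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Simulate one dyadic block: private answers, confidences, joint answers.

    Answers are reported 1-based (pen position / choice-card slot).  The
    ``conflict`` column is by construction the disagreement of the two
    private answers.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if task not in TASK_ALTERNATIVES:
        raise ValueError(f"unknown task {task!r}")
    m = TASK_ALTERNATIVES[task]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = rng.integers(0, m, size=n_trials)
    trials_a = simulate_trials(params_a, m, n_trials, rng, target_index=target)
    trials_b = simulate_trials(params_b, m, n_trials, rng, target_index=target)
    joint = combine_dyad_decisions(trials_a, trials_b, rule, rng)
    return pd.DataFrame(
        {
            "task": task,
            "trial_index": np.arange(1, n_trials + 1),
            "correct_answer": target + 1,
            "answer_a": trials_a["choice"] + 1,
            "answer_b": trials_b["choice"] + 1,
            "correct_a": trials_a["correct"],
            "correct_b": trials_b["correct"],
            "confidence_a": trials_a["confidence"],
            "confidence_b": trials_b["confidence"],
            "joint_answer": joint["joint_choice"] + 1,
            "joint_correct": joint["joint_correct"],
            "conflict": joint["conflict"],
        }
    )
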