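"""Conversation metrics: whitespace tokenization, confidence-lexicon counts,
the word-use variance decomposition, and talkative-wins outcome coding.

The transcript pipeline is deliberately lightweight: utterances are tokenized
by whitespace (punctuation is not stripped), and confidence/certainty/
uncertainty expressions are counted by case-insensitive, non-overlapping,
leftmost-longest phrase matching against an editable lexicon.  The shipped
:data:`DEFAULT_LEXICON` is a configuration artifact seeded with common
English hedging and certainty phrases, not a canonical list.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LEXICON",
    "UtteranceRecord",
    "WordUseComponents",
    "TalkativeOutcome",
    "count_words",
    "count_lexicon_matches",
    "word_use_components",
    "talkative_outcome",
]

DEFAULT_LEXICON: tuple[str, ...] = (
    "i'm sure",
    "i am sure",
    "i'm not sure",
    "i am not sure",
    "not sure",
    "i'm confident",
    "i am confident",
    "i'm certain",
    "i am certain",
    "pretty sure",
    "quite sure",
    "really sure",
    "for sure",
    "no idea",
    "i think",
    "i guess",
    "i doubt",
    "maybe",
    "probably",
    "definitely",
    "certainly",
    "possibly",
    "perhaps",
    "confident",
    "uncertain",
)


class TalkativeOutcome(enum.Enum):
    MORE_TALKATIVE_WON = "more_talkative_won"
    LESS_TALKATIVE_WON = "less_talkative_won"
    TIE_OR_EXCLUDED = "tie_or_excluded"


@dataclass(frozen=True)
class UtteranceRecord:
    """One speaker turn with its derived counts."""

    dyad_id: str
    task: str
    trial_index: int
    speaker: str
    utterance: str
    word_count: int
    lexicon_count: int

    @classmethod
    def from_text(
        cls,
        dyad_id: str,
        task: str,
        trial_index: int,
        speaker: str,
        utterance: str,
        lexicon: Sequence[str] = DEFAULT_LEXICON,
    ) -> "UtteranceRecord":
        return cls(
            dyad_id=dyad_id,
            task=task,
            trial_index=trial_index,
            speaker=speaker,
            utterance=utterance,
            word_count=count_words(utterance),
            lexicon_count=count_lexicon_matches(utterance, lexicon),
        )


def count_words(utterance: str) -> int:
    """Number of maximal nonempty whitespace-separated tokens."""
    return len(utterance.split())


def _lexicon_pattern(lexicon: Sequence[str]) -> re.Pattern[str]:
    # Longest-first alternation makes the regex scan leftmost-longest; findall
    # consumes matches, so counts are non-overlapping.
    phrases = sorted({p.strip().lower() for p in lexicon if p.strip()}, key=len, reverse=True)
    if not phrases:
        raise ValueError("lexicon must contain at least one phrase")
    alternation = "|".join(re.escape(p) for p in phrases)
    return re.compile(rf"\b(?:{alternation})\b", re.IGNORECASE)


def count_lexicon_matches(utterance: str, lexicon: Sequence[str] = DEFAULT_LEXICON) -> int:
    """Count confidence-lexicon phrase occurrences in an utterance.

    Matching is case-insensitive, non-overlapping and leftmost-longest, so
    "I'm not sure" counts once against {"i'm not sure", "i'm sure"}.
    """
    return len(_lexicon_pattern(lexicon).findall(utterance))


@dataclass(frozen=True)
class WordUseComponents:
    """Per-trial decomposition of dyad word counts on conflict trials.

    ``words = grand_mean + between + within_dev`` holds exactly:
    ``within_dev`` is the trial's deviation from its dyad's conflict-trial
    mean, ``between`` the dyad mean centered on the grand mean, and
    ``imbalance`` the dyad-level talkativeness-imbalance index
    |mean_1 − mean_2| / (mean_1 + mean_2) in [0, 1].
    """

    dyad_id: str
    trial_index: int
    words: float
    within_dev: float
    between: float
    imbalance: float


def word_use_components(
    conflict_trials: pd.DataFrame,
    grand_mean: float | None = None,
) -> pd.DataFrame:
    """Decompose per-trial word counts into within/between/imbalance terms.

    ``conflict_trials`` needs columns ``dyad_id``, ``trial_index``,
    ``words_a``, ``words_b`` (conflict trials only).  ``grand_mean`` defaults
    to the mean of per-trial totals over the supplied trials.
    """
    required = {"dyad_id", "trial_index", "words_a", "words_b"}
    missing = required - set(conflict_trials.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if conflict_trials.empty:
        raise ValueError("need at least one conflict trial")
    df = conflict_trials.copy()
    df["words"] = df["words_a"] + df["words_b"]
    if grand_mean is None:
        grand_mean = float(df["words"].mean())
    dyad_mean = df.groupby("dyad_id")["words"].transform("mean")
    mean_a = df.groupby("dyad_id")["words_a"].transform("mean")
    mean_b = df.groupby("dyad_id")["words_b"].transform("mean")
    denom = mean_a + mean_b
    if (denom == 0).any():
        bad = df.loc[denom == 0, "dyad_id"].unique()
        raise ValueError(f"imbalance undefined for silent dyads: {list(bad)}")
    out = df[["dyad_id", "trial_index", "words"]].copy()
    out["within_dev"] = df["words"] - dyad_mean
    out["between"] = dyad_mean - grand_mean
    out["imbalance"] = (mean_a - mean_b).abs() / denom
    out.attrs["grand_mean"] = grand_mean
    return out


def talkative_outcome(
    words_a: float,
    words_b: float,
    answer_a: object,
    answer_b: object,
    joint_answer: object,
) -> TalkativeOutcome:
    """Label a conflict trial by whether the more talkative member "won".

    The winner is the member whose private answer was adopted as the joint
    answer.  Word-count ties, and joint answers matching neither private
    answer (e.g., a third alternative emerging in discussion), are excluded.
    """
    if answer_a == answer_b:
        raise ValueError("talkative outcome is only defined for conflict trials")
    if joint_answer == answer_a:
        winner = "a"
    elif joint_answer == answer_b:
        winner = "b"
    else:
        logger.info("joint answer matches neither private answer; excluded")
        return TalkativeOutcome.TIE_OR_EXCLUDED
    if words_a == words_b:
        return TalkativeOutcome.TIE_OR_EXCLUDED
    more_talkative = "a" if words_a > words_b else "b"
    if winner == more_talkative:
        return TalkativeOutcome.MORE_TALKATIVE_WON
    return TalkativeOutcome.LESS_TALKATIVE_WON
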