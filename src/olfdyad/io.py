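"""Delimited-text table formats, schema validation, and run manifests.

All artifacts are diff-able UTF-8 CSV files with a header row.  Three tables
are defined:

* **trial table** — one row per trial; day-1 rows carry a single subject's
  private answer and confidence, day-2 rows additionally carry the partner's
  answer, the joint decision, the conflict flag, and per-member conversation
  counts.  Answers are stored as strings: identification uses choice labels,
  discrimination uses pen positions "1".."3".
* **score table** — one row per subject per day with T/D/I scores, D+I sum,
  demographics, and dyad assignment.
* **transcript table** — one row per speaker turn (or per-member per-trial
  count aggregate) with word and confidence-lexicon counts.

Validators raise :class:`SchemaError` naming the offending row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "TRIAL_COLUMNS",
    "SCORE_COLUMNS",
    "TRANSCRIPT_COLUMNS",
    "validate_trial_table",
    "read_trial_table",
    "write_trial_table",
    "validate_score_table",
    "read_score_table",
    "write_score_table",
    "read_transcript_table",
    "write_transcript_table",
    "write_manifest",
    "read_manifest",
]

TRIAL_COLUMNS = [
    "study_day", "dyad_id", "subject_a", "subject_b", "task", "trial_index",
    "answer_a", "answer_b", "correct_answer", "correct_a", "correct_b",
    "confidence_a", "confidence_b", "joint_answer", "joint_correct",
    "conflict", "words_a", "words_b", "lexicon_count",
]

SCORE_COLUMNS = [
    "subject_id", "day", "t_score", "d_score", "i_score", "di_sum",
    "age", "gender", "dyad_id", "similarity_group",
]

TRANSCRIPT_COLUMNS = [
    "dyad_id", "task", "trial_index", "speaker", "word_count", "lexicon_count",
]

TASKS = ("discrimination", "identification")


class SchemaError(ValueError):
    """A table violates the documented schema; the message names the row."""


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns {missing}")
    unknown = [c for c in df.columns if c not in columns]
    if unknown:
        raise SchemaError(f"{what} has unknown columns {unknown}")


def _fail_rows(mask: pd.Series, message: str) -> None:
    if mask.any():
        rows = list(mask[mask].index[:5])
        raise SchemaError(f"{message} (rows {rows})")


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the trial table; returns the (typed) frame on success."""
    _require_columns(df, TRIAL_COLUMNS, "trial table")
    df = df.copy()
    _fail_rows(~df["study_day"].isin([1, 2]), "study_day must be 1 or 2")
    _fail_rows(~df["task"].isin(TASKS), f"task must be one of {TASKS}")
    _fail_rows(
        ~df["trial_index"].between(1, 16), "trial_index must be within 1..16"
    )
    day2 = df["study_day"] == 2
    _fail_rows(day2 & df["dyad_id"].isna(), "day-2 rows need a dyad_id")
    _fail_rows(~day2 & df["dyad_id"].notna(), "day-1 rows must not carry a dyad_id")
    for col in ("answer_b", "joint_answer", "joint_correct", "conflict"):
        _fail_rows(day2 & df[col].isna(), f"day-2 rows need {col}")
        _fail_rows(~day2 & df[col].notna(), f"day-1 rows must not carry {col}")
    _fail_rows(df["answer_a"].isna(), "answer_a is required")
    _fail_rows(df["correct_answer"].isna(), "correct_answer is required")

    # Values compare by equality, not string form: integer answers survive a
    # CSV round-trip as int in one column and float in another (2 == 2.0).
    conflict = df.loc[day2, "conflict"].astype(bool)
    _fail_rows(
        conflict != (df.loc[day2, "answer_a"] != df.loc[day2, "answer_b"]),
        "conflict flag inconsistent with the two answers",
    )
    joint_ok = df.loc[day2, "joint_answer"] == df.loc[day2, "correct_answer"]
    _fail_rows(
        df.loc[day2, "joint_correct"].astype(bool) != joint_ok,
        "joint_correct disagrees with joint_answer vs correct_answer",
    )
    correct_ok = df["answer_a"] == df["correct_answer"]
    _fail_rows(df["correct_a"].astype(bool) != correct_ok,
               "correct_a disagrees with answer_a vs correct_answer")

    keys = df.assign(
        unit=np.where(day2, df["dyad_id"].astype(str), df["subject_a"].astype(str))
    )[["study_day", "unit", "task", "trial_index"]]
    _fail_rows(keys.duplicated(), "duplicate trial_index within (unit, task, day)")
    return df


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_trial_table(df)
    df.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"dyad_id": "string", "subject_a": "string", "subject_b": "string"},
    )
    for col in ("correct_a", "correct_b", "joint_correct", "conflict"):
        if col in df.columns:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False}
            ).astype("boolean")
    return validate_trial_table(df)


def validate_score_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, SCORE_COLUMNS, "score table")
    _fail_rows(~df["day"].isin([1, 2]), "day must be 1 or 2")
    for col in ("d_score", "i_score"):
        _fail_rows(~df[col].between(0, 16), f"{col} must be within 0..16")
    _fail_rows(
        df["di_sum"] != df["d_score"] + df["i_score"], "di_sum must equal d + i"
    )
    _fail_rows(
        (df["day"] == 2) & df["t_score"].notna(),
        "t_score is only defined on day 1",
    )
    tvals = df["t_score"].dropna()
    if not tvals.between(1, 16).all():
        raise SchemaError("t_score must lie within 1..16")
    _fail_rows(df.duplicated(subset=["subject_id", "day"]), "duplicate (subject, day)")
    return df


def write_score_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_score_table(df)
    df.to_csv(path, index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"subject_id": "string", "dyad_id": "string", "gender": "string"}
    )
    return validate_score_table(df)


def write_transcript_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, TRANSCRIPT_COLUMNS, "transcript table")
    df.to_csv(path, index=False)


def read_transcript_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"dyad_id": "string", "speaker": "string"})
    _require_columns(df, TRANSCRIPT_COLUMNS, "transcript table")
    return df


def write_manifest(manifest: Mapping[str, object], path: str | Path) -> None:
    """Write a run manifest as sorted key = value text lines."""
    lines = [f"{key} = {manifest[key]}" for key in sorted(manifest)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_manifest(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(" = ")
        out[key] = value
    return out
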