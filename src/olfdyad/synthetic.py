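"""Generate a full synthetic two-day dyadic olfactory study.

The generator emulates the structure of the clinical-battery paradigm: a
day-1 cohort tested individually (threshold staircase, 16-trial 3AFC
discrimination, 16-trial 4AFC identification, with confidence ratings),
quartile-based dyadic matching on day-1 D+I, and a day-2 session in which
each of 20 dyads repeats both forced-choice tasks, deciding privately before
a joint answer produced by a configurable aggregation rule.  Conversation is
emulated at the level of per-trial word and confidence-lexicon counts with
dyad-level and trial-level variance components.

Calibration of the defaults (see docs/methods.md): individual abilities are
drawn from Gaussians truncated at zero whose means put mean accuracy near
0.80 in both tasks, which under independent observers puts the conflict rate
near the one-third of trials characteristic of this paradigm; the retest
correlation is higher for discrimination than identification; word counts
rise on conflict trials and fall in identification; confidence-lexicon
counts follow a log-linear Poisson model; and on conflict trials the member
whose answer prevails is the more talkative one with probability
``expit(talkative_wins_logodds)``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from olfdyad import io, scoring, staircase
from olfdyad.dyad_models import (
    DyadRule,
    ObserverParams,
    simulate_session,
    simulate_trials,
)

__all__ = [
    "CohortConfig",
    "LanguageGenConfig",
    "Cohort",
    "EXPECTED_CONFLICT_BAND",
    "generate_cohort",
    "generate_study_dataset",
]

# Band (proportion of trials) the default abilities are calibrated to put the
# overall conflict rate in; centered on the one-third rate typical of the
# paradigm.
EXPECTED_CONFLICT_BAND = (0.25, 0.45)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and individual-ability structure."""

    n_day1: int = 53
    n_return: int = 40
    n_trials_per_task: int = 16
    d_ability_mean: float = 1.75
    d_ability_sd: float = 0.55
    i_ability_mean: float = 2.0
    i_ability_sd: float = 0.6
    rho_d: float = 0.8  # day-1 -> day-2 retest correlation, discrimination
    rho_i: float = 0.6  # identification (less reliable)
    meta_noise: float = 0.5
    threshold_mean: float = 8.5
    threshold_sd: float = 2.5
    threshold_slope: float = 1.5
    age_mean: float = 24.4
    age_sd: float = 4.1
    p_male: float = 16 / 53
    age_slope_identification: float = 0.053  # ability units per year of age
    gap_mean_days: float = 40.6
    gap_sd_days: float = 23.3

    def __post_init__(self) -> None:
        if self.n_return > self.n_day1:
            raise ValueError("n_return cannot exceed n_day1")
        for rho in (self.rho_d, self.rho_i):
            if not -1.0 <= rho <= 1.0:
                raise ValueError("retest correlations must lie in [-1, 1]")


@dataclass(frozen=True)
class LanguageGenConfig:
    """Conversation-count model for the day-2 discussions."""

    base_words: float = 25.0  # expected dyad words, non-conflict discrimination
    dyad_talkativeness_sd: float = 0.3  # lognormal sigma, between-dyad
    trial_word_sd: float = 0.25  # lognormal sigma, within-dyad
    conflict_words: float = 47.9  # extra words on conflict trials
    identification_words: float = -11.47  # word change in identification
    talkative_wins_logodds: float = -0.59
    talkative_coupling: bool = True
    lexicon_base_rate: float = 0.6  # expected lexicon hits, non-conflict discrimination
    lexicon_conflict_effect: float = 1.26  # log scale
    lexicon_identification_effect: float = -0.35  # log scale
    lexicon_dyad_sd: float = 0.15  # lognormal sigma on the dyad rate

    def __post_init__(self) -> None:
        for name in ("dyad_talkativeness_sd", "trial_word_sd", "lexicon_dyad_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Cohort:
    """Day-1 score table plus the latent abilities the scores realize."""

    scores: pd.DataFrame  # day-1 rows
    trials: pd.DataFrame  # day-1 individual trial rows
    latents: pd.DataFrame  # per-subject latent abilities for both days


def _trunc_gauss(rng: np.random.Generator, mean, sd: float, size: int) -> np.ndarray:
    return np.maximum(np.asarray(mean) + sd * rng.standard_normal(size), 0.0)


def generate_cohort(
    config: CohortConfig = CohortConfig(),
    seed: int | np.random.Generator = 0,
) -> Cohort:
    """Simulate the day-1 cohort through the actual test procedures."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_day1
    subject_ids = [f"s{i + 1:02d}" for i in range(n)]
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 45).round(1)
    gender = np.where(rng.random(n) < config.p_male, "male", "female")

    z_d = rng.standard_normal(n)
    z_i = rng.standard_normal(n)
    age_shift = config.age_slope_identification * (age - config.age_mean)
    ability_d1 = _trunc_gauss(rng, config.d_ability_mean + config.d_ability_sd * z_d, 0.0, n)
    ability_i1 = _trunc_gauss(
        rng, config.i_ability_mean + config.i_ability_sd * z_i + age_shift, 0.0, n
    )
    eps_d = rng.standard_normal(n)
    eps_i = rng.standard_normal(n)
    z_d2 = config.rho_d * z_d + np.sqrt(1 - config.rho_d**2) * eps_d
    z_i2 = config.rho_i * z_i + np.sqrt(1 - config.rho_i**2) * eps_i
    ability_d2 = _trunc_gauss(rng, config.d_ability_mean + config.d_ability_sd * z_d2, 0.0, n)
    ability_i2 = _trunc_gauss(
        rng, config.i_ability_mean + config.i_ability_sd * z_i2 + age_shift, 0.0, n
    )

    # Threshold latent, moderately correlated with discrimination ability.
    theta = np.clip(
        config.threshold_mean
        + config.threshold_sd * (0.5 * z_d + np.sqrt(0.75) * rng.standard_normal(n)),
        2.0,
        15.0,
    )

    trial_rows: list[pd.DataFrame] = []
    d_scores = np.zeros(n, dtype=int)
    i_scores = np.zeros(n, dtype=int)
    t_scores = np.full(n, np.nan)
    for idx, sid in enumerate(subject_ids):
        responder = _psychometric(theta[idx], config.threshold_slope)
        result = staircase.run_threshold_test(responder, rng)
        if result.t_score is not None:
            t_scores[idx] = result.t_score
        for task, ability in (
            ("discrimination", ability_d1[idx]),
            ("identification", ability_i1[idx]),
        ):
            block = _individual_block(
                sid, task, ability, config, rng, study_day=1
            )
            trial_rows.append(block)
            if task == "discrimination":
                d_scores[idx] = block["correct_a"].sum()
            else:
                i_scores[idx] = block["correct_a"].sum()

    scores_df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "day": 1,
            "t_score": t_scores,
            "d_score": d_scores,
            "i_score": i_scores,
            "di_sum": d_scores + i_scores,
            "age": age,
            "gender": gender,
            "dyad_id": pd.Series([pd.NA] * n, dtype="string"),
            "similarity_group": pd.Series([pd.NA] * n, dtype="string"),
        }
    )
    latents = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "ability_d1": ability_d1,
            "ability_i1": ability_i1,
            "ability_d2": ability_d2,
            "ability_i2": ability_i2,
            "theta": theta,
        }
    ).set_index("subject_id")
    return Cohort(scores=scores_df, trials=pd.concat(trial_rows, ignore_index=True), latents=latents)


def _psychometric(theta: float, slope: float):
    """3AFC threshold psychometric: strong (low-numbered) levels are easy."""

    def p_correct(level: int) -> float:
        return 1 / 3 + (2 / 3) * norm.cdf((theta - level) / slope)

    return p_correct


def _individual_block(
    subject_id: str,
    task: str,
    ability: float,
    config: CohortConfig,
    rng: np.random.Generator,
    study_day: int,
) -> pd.DataFrame:
    m = {"discrimination": 3, "identification": 4}[task]
    params = ObserverParams(ability=ability, meta_noise=config.meta_noise)
    arrays = simulate_trials(params, m, config.n_trials_per_task, rng)
    n = config.n_trials_per_task
    return pd.DataFrame(
        {
            "study_day": study_day,
            "dyad_id": pd.Series([pd.NA] * n, dtype="string"),
            "subject_a": pd.Series([subject_id] * n, dtype="string"),
            "subject_b": pd.Series([pd.NA] * n, dtype="string"),
            "task": task,
            "trial_index": np.arange(1, n + 1),
            "answer_a": arrays["choice"] + 1,
            "answer_b": np.nan,
            "correct_answer": arrays["target_index"] + 1,
            "correct_a": arrays["correct"],
            "correct_b": pd.Series([pd.NA] * n, dtype="boolean"),
            "confidence_a": arrays["confidence"],
            "confidence_b": np.nan,
            "joint_answer": np.nan,
            "joint_correct": pd.Series([pd.NA] * n, dtype="boolean"),
            "conflict": pd.Series([pd.NA] * n, dtype="boolean"),
            "words_a": np.nan,
            "words_b": np.nan,
            "lexicon_count": np.nan,
        }
    )


def generate_study_dataset(
    cohort_config: CohortConfig = CohortConfig(),
    language_config: LanguageGenConfig = LanguageGenConfig(),
    rule: DyadRule = DyadRule.DEFER_TO_HIGHER_CONFIDENCE,
    seed: int = 0,
) -> dict[str, object]:
    """Generate the full study: cohort, matching, dyadic sessions, language.

    Returns ``{"trials", "scores", "transcripts", "manifest"}``; all tables
    satisfy the :mod:`olfdyad.io` schemas and the whole dataset is a
    deterministic function of ``seed``.
    """
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(cohort_config, rng)

    subject_scores = [
        scoring.SubjectScore(
            subject_id=row.subject_id,
            day=1,
            d_score=int(row.d_score),
            i_score=int(row.i_score),
        )
        for row in cohort.scores.itertuples()
    ]
    dyads = scoring.match_dyads(subject_scores, rng)

    n_dyads = cohort_config.n_return // 2
    high = [d for d in dyads if d.similarity_group == "high_similarity"]
    low = [d for d in dyads if d.similarity_group == "low_similarity"]
    n_high = min(len(high), (n_dyads + 1) // 2)
    n_low = min(len(low), n_dyads - n_high)
    chosen = list(rng.choice(len(high), size=n_high, replace=False))
    returning_dyads = [high[i] for i in chosen]
    chosen = list(rng.choice(len(low), size=n_low, replace=False))
    returning_dyads += [low[i] for i in chosen]
    returning_dyads.sort(key=lambda d: d.dyad_id)

    trial_blocks: list[pd.DataFrame] = [cohort.trials]
    transcript_rows: list[pd.DataFrame] = []
    day2_scores: list[dict[str, object]] = []
    assignment: dict[str, tuple[str, str]] = {}

    for dyad in returning_dyads:
        sid_a, sid_b = dyad.members
        assignment[sid_a] = (dyad.dyad_id, dyad.similarity_group)
        assignment[sid_b] = (dyad.dyad_id, dyad.similarity_group)
        d2: dict[str, int] = {}
        i2: dict[str, int] = {}
        for task, col in (("discrimination", "ability_d2"), ("identification", "ability_i2")):
            params_a = ObserverParams(
                ability=float(cohort.latents.loc[sid_a, col]),
                meta_noise=cohort_config.meta_noise,
            )
            params_b = ObserverParams(
                ability=float(cohort.latents.loc[sid_b, col]),
                meta_noise=cohort_config.meta_noise,
            )
            session = simulate_session(
                params_a, params_b, rule, cohort_config.n_trials_per_task, task, rng
            )
            session = _attach_language(session, task, language_config, rng)
            session.insert(0, "study_day", 2)
            session.insert(1, "dyad_id", pd.Series([dyad.dyad_id] * len(session), dtype="string"))
            session.insert(2, "subject_a", pd.Series([sid_a] * len(session), dtype="string"))
            session.insert(3, "subject_b", pd.Series([sid_b] * len(session), dtype="string"))
            trial_blocks.append(session[io.TRIAL_COLUMNS])
            transcript_rows.append(_transcript_block(session, dyad.dyad_id, task, rng))
            store = d2 if task == "discrimination" else i2
            store[sid_a] = int(session["correct_a"].sum())
            store[sid_b] = int(session["correct_b"].sum())
        for sid in dyad.members:
            base = cohort.scores.loc[cohort.scores["subject_id"] == sid].iloc[0]
            day2_scores.append(
                {
                    "subject_id": sid,
                    "day": 2,
                    "t_score": np.nan,
                    "d_score": d2[sid],
                    "i_score": i2[sid],
                    "di_sum": d2[sid] + i2[sid],
                    "age": base["age"],
                    "gender": base["gender"],
                    "dyad_id": dyad.dyad_id,
                    "similarity_group": dyad.similarity_group,
                }
            )

    scores = cohort.scores.copy()
    for sid, (dyad_id, group) in assignment.items():
        mask = scores["subject_id"] == sid
        scores.loc[mask, "dyad_id"] = dyad_id
        scores.loc[mask, "similarity_group"] = group
    scores = pd.concat([scores, pd.DataFrame(day2_scores)], ignore_index=True)
    trials = pd.concat(trial_blocks, ignore_index=True)
    io.validate_trial_table(trials)
    io.validate_score_table(scores)

    gap_days = max(1.0, rng.normal(cohort_config.gap_mean_days, cohort_config.gap_sd_days))
    manifest: dict[str, object] = {
        "seed": seed,
        "rule": rule.value,
        "n_dyads": len(returning_dyads),
        "session_gap_days": round(float(gap_days), 1),
        "ability_model": "gaussian latent ability truncated at 0",
    }
    manifest.update({f"cohort.{k}": v for k, v in asdict(cohort_config).items()})
    manifest.update({f"language.{k}": v for k, v in asdict(language_config).items()})
    return {
        "trials": trials,
        "scores": scores,
        "transcripts": pd.concat(transcript_rows, ignore_index=True),
        "manifest": manifest,
    }


def _attach_language(
    session: pd.DataFrame,
    task: str,
    cfg: LanguageGenConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw per-trial word and lexicon counts; couple talkativeness to wins."""
    n = len(session)
    ident = 1.0 if task == "identification" else 0.0
    conflict = session["conflict"].to_numpy().astype(float)

    dyad_mult = rng.lognormal(-cfg.dyad_talkativeness_sd**2 / 2, cfg.dyad_talkativeness_sd)
    trial_mult = rng.lognormal(-cfg.trial_word_sd**2 / 2, cfg.trial_word_sd, size=n)
    lam_total = (
        cfg.base_words + cfg.conflict_words * conflict + cfg.identification_words * ident
    )
    lam_total = np.maximum(lam_total, 2.0) * dyad_mult * trial_mult
    words_a = rng.poisson(lam_total / 2.0).astype(float)
    words_b = rng.poisson(lam_total / 2.0).astype(float)

    if cfg.talkative_coupling:
        p_more_wins = expit(cfg.talkative_wins_logodds)
        for i in range(n):
            if not session["conflict"].iat[i]:
                continue
            joint = session["joint_answer"].iat[i]
            if joint == session["answer_a"].iat[i]:
                winner = "a"
            elif joint == session["answer_b"].iat[i]:
                winner = "b"
            else:
                continue
            if words_a[i] == words_b[i]:
                continue
            more = "a" if words_a[i] > words_b[i] else "b"
            want_more_wins = rng.random() < p_more_wins
            if (more == winner) != want_more_wins:
                words_a[i], words_b[i] = words_b[i], words_a[i]

    lex_mult = rng.lognormal(-cfg.lexicon_dyad_sd**2 / 2, cfg.lexicon_dyad_sd)
    lex_rate = (
        cfg.lexicon_base_rate
        * np.exp(cfg.lexicon_conflict_effect * conflict + cfg.lexicon_identification_effect * ident)
        * lex_mult
    )
    session = session.copy()
    session["words_a"] = words_a
    session["words_b"] = words_b
    session["lexicon_count"] = rng.poisson(lex_rate).astype(float)
    return session


def _transcript_block(
    session: pd.DataFrame, dyad_id: str, task: str, rng: np.random.Generator
) -> pd.DataFrame:
    lex_a = rng.binomial(session["lexicon_count"].astype(int), 0.5)
    rows = []
    for speaker, words, lex in (
        ("member_1", session["words_a"], lex_a),
        ("member_2", session["words_b"], session["lexicon_count"].astype(int) - lex_a),
    ):
        rows.append(
            pd.DataFrame(
                {
                    "dyad_id": dyad_id,
                    "task": task,
                    "trial_index": session["trial_index"].to_numpy(),
                    "speaker": speaker,
                    "word_count": np.asarray(words, dtype=int),
                    "lexicon_count": np.asarray(lex, dtype=int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
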