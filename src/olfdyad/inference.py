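"""Statistical stage: accuracy-by-confidence profiles, clustered logistic and
Poisson models, OLS regressions, paired baselines, and BIC-based Bayes
factors — the full analysis sequence for a two-day dyadic olfactory study.

Conventions: estimates on log-odds / log-rate scales are reported together
with their exponentiated form (odds ratio / rate ratio); all intervals are
two-sided 95%; the multiple-comparison correction for task-split follow-up
models is Holm's method and corrected p-values are labeled "[corrected]".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from olfdyad import language, scoring
from olfdyad._mixed import MixedGLMResult, fit_mixed_glm

__all__ = [
    "FitResult",
    "ModelComparison",
    "AnalysisReport",
    "accuracy_by_confidence",
    "fit_binary_clustered",
    "fit_count_clustered",
    "fit_linear",
    "bayes_factor_bic",
    "prob_from_logodds",
    "holm_correct",
    "build_dyad_table",
    "run_full_analysis",
]

_Z95 = float(stats.norm.ppf(0.975))

ESTIMATE_COLUMNS = [
    "term", "estimate", "se", "statistic", "df", "p",
    "ci_low", "ci_high", "exponentiated",
]


@dataclass
class FitResult:
    """A fitted model: its estimate table plus fit metadata.

    ``table`` has one row per term with estimate, SE, test statistic,
    degrees of freedom (t-based models only), p-value, 95% CI and, for
    log/logit links, the exponentiated estimate.
    """

    table: pd.DataFrame
    description: str
    loglike: float | None = None
    bic: float | None = None
    nobs: int | None = None
    extra: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        rows = self.table[self.table["term"] == name]
        if rows.empty:
            raise KeyError(f"no term {name!r} in {self.description}")
        return rows.iloc[0]


@dataclass(frozen=True)
class ModelComparison:
    """BIC-approximation Bayes factor favoring the simpler of two nested fits."""

    bic_simple: float
    bic_complex: float

    @property
    def bf01(self) -> float:
        return float(np.exp((self.bic_complex - self.bic_simple) / 2.0))


def prob_from_logodds(logodds: float) -> float:
    """Inverse-logit: the probability corresponding to a log-odds value."""
    return float(special.expit(logodds))


def holm_correct(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def accuracy_by_confidence(
    trials: pd.DataFrame,
    confidence_col: str = "confidence_a",
    correct_col: str = "correct_a",
    subject_col: str = "subject_a",
) -> pd.DataFrame:
    """Proportion correct at each confidence level, per subject and overall.

    Returns per-(subject, level) rows plus aggregate rows (subject = "all")
    averaging the per-subject proportions at each occupied level.
    """
    for col in (confidence_col, correct_col, subject_col):
        if col not in trials.columns:
            raise ValueError(f"trials table lacks column {col!r}")
    df = trials.dropna(subset=[confidence_col, correct_col])
    per_subject = (
        df.groupby([subject_col, confidence_col], observed=True)[correct_col]
        .agg(["mean", "size"])
        .reset_index()
        .rename(
            columns={
                subject_col: "subject",
                confidence_col: "confidence",
                "mean": "accuracy",
                "size": "n_trials",
            }
        )
    )
    overall = (
        per_subject.groupby("confidence", observed=True)
        .agg(accuracy=("accuracy", "mean"), n_trials=("n_trials", "sum"))
        .reset_index()
    )
    overall.insert(0, "subject", "all")
    return pd.concat([per_subject, overall], ignore_index=True)


def _mixed_table(res: MixedGLMResult, exponentiate: bool) -> pd.DataFrame:
    z = res.params / res.se
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "term": list(res.exog_names),
            "estimate": res.params,
            "se": res.se,
            "statistic": z,
            "df": np.nan,
            "p": p,
            "ci_low": res.params - _Z95 * res.se,
            "ci_high": res.params + _Z95 * res.se,
            "exponentiated": np.exp(res.params) if exponentiate else np.nan,
        }
    )
    return table[ESTIMATE_COLUMNS]


def _fit_clustered(
    data: pd.DataFrame,
    formula: str,
    cluster: str,
    family: str,
    re_sd: float | None,
    description: str,
) -> FitResult:
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    keep = y.index
    groups = data.loc[keep, cluster].to_numpy()
    res = fit_mixed_glm(
        y.to_numpy().ravel(),
        X.to_numpy(),
        groups,
        family=family,
        exog_names=tuple(X.columns),
        re_sd=re_sd,
    )
    return FitResult(
        table=_mixed_table(res, exponentiate=True),
        description=description,
        loglike=res.loglike,
        bic=res.bic,
        nobs=res.nobs,
        extra={
            "re_sd": res.re_sd,
            "n_clusters": res.n_clusters,
            "family": family,
            "penalized": res.penalized,
            "converged": res.converged,
        },
    )


def fit_binary_clustered(
    data: pd.DataFrame,
    formula: str,
    cluster: str,
    re_sd: float | None = None,
    description: str | None = None,
) -> FitResult:
    """Random-intercept logistic regression (odds ratios, Wald 95% CIs).

    ``re_sd`` fixes the random-intercept sd; 0.0 reduces to plain logistic
    regression.  Complete separation is flagged (``extra['penalized']``) and
    handled by a weak ridge refit.
    """
    if data[cluster].nunique() < 2 and re_sd is None:
        raise ValueError("need at least 2 clusters")
    return _fit_clustered(
        data, formula, cluster, "binomial", re_sd,
        description or f"logistic: {formula} | RI({cluster})",
    )


def fit_count_clustered(
    data: pd.DataFrame,
    formula: str,
    cluster: str,
    re_sd: float | None = None,
    description: str | None = None,
) -> FitResult:
    """Random-intercept Poisson regression (rate ratios, Wald 95% CIs)."""
    outcome = formula.split("~")[0].strip()
    vals = data[outcome].dropna()
    if (vals < 0).any() or (vals != vals.round()).any():
        raise ValueError("count outcome must be nonnegative integers")
    if (vals == 0).all():
        raise ValueError("degenerate all-zero count outcome")
    return _fit_clustered(
        data, formula, cluster, "poisson", re_sd,
        description or f"poisson: {formula} | RI({cluster})",
    )


def fit_linear(data: pd.DataFrame, formula: str, description: str | None = None) -> FitResult:
    """OLS with two-sided t tests and 95% CIs; df = residual df."""
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(f"rank-deficient design for {formula!r}")
    res = model.fit()
    if res.df_resid <= 0:
        raise ValueError("more terms than observations")
    conf = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "statistic": res.tvalues.to_numpy(),
            "df": float(res.df_resid),
            "p": res.pvalues.to_numpy(),
            "ci_low": conf[0].to_numpy(),
            "ci_high": conf[1].to_numpy(),
            "exponentiated": np.nan,
        }
    )
    return FitResult(
        table=table[ESTIMATE_COLUMNS].reset_index(drop=True),
        description=description or f"ols: {formula}",
        loglike=float(res.llf),
        bic=float(res.bic),
        nobs=int(res.nobs),
        extra={"r_squared": float(res.rsquared)},
    )


def bayes_factor_bic(model_simple: FitResult, model_complex: FitResult) -> ModelComparison:
    """BF01 = exp((BIC_complex − BIC_simple)/2) for nested fits on the same rows."""
    if model_simple.bic is None or model_complex.bic is None:
        raise ValueError("both models need a BIC")
    if model_simple.nobs != model_complex.nobs:
        raise ValueError("models were fitted to different data rows")
    return ModelComparison(bic_simple=model_simple.bic, bic_complex=model_complex.bic)


# ---------------------------------------------------------------------------
# Dataset assembly and the full report
# ---------------------------------------------------------------------------

def build_dyad_table(trials: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Per-(dyad, task) summary: joint score, member baselines, similarity,
    collective benefit, and conflict statistics.

    Day-2 individual scores are recomputed from the session's private
    answers; day-1 scores come from the score table.
    """
    day2 = trials[trials["study_day"] == 2]
    if day2.empty:
        raise ValueError("no day-2 dyadic trials")
    day1_scores = scores[scores["day"] == 1].set_index("subject_id")
    group_map: dict[str, object] = {}
    if "similarity_group" in scores.columns:
        assigned = scores.dropna(subset=["dyad_id", "similarity_group"])
        group_map = dict(zip(assigned["dyad_id"], assigned["similarity_group"]))
    rows = []
    for (dyad_id, task), block in day2.groupby(["dyad_id", "task"], observed=True):
        subj_a = block["subject_a"].iloc[0]
        subj_b = block["subject_b"].iloc[0]
        score_col = {"discrimination": "d_score", "identification": "i_score"}[task]
        s_a2 = int(block["correct_a"].sum())
        s_b2 = int(block["correct_b"].sum())
        s_dyad = int(block["joint_correct"].sum())
        s_a1 = float(day1_scores.loc[subj_a, score_col])
        s_b1 = float(day1_scores.loc[subj_b, score_col])
        summary = scoring.summarize_conflicts(
            block[["answer_a", "answer_b", "correct_answer", "joint_answer"]]
            .itertuples(index=False),
            dyad_id=dyad_id,
            task=task,
        )
        rows.append(
            {
                "dyad_id": dyad_id,
                "task": task,
                "similarity_group": group_map.get(dyad_id),
                "n_trials": summary.n_trials,
                "s_dyad": s_dyad,
                "s_best_day2": max(s_a2, s_b2),
                "s_mean_day2": (s_a2 + s_b2) / 2.0,
                "ratio_day1": scoring.similarity_ratio(s_a1, s_b1).ratio,
                "ratio_day2": scoring.similarity_ratio(s_a2, s_b2).ratio
                if max(s_a2, s_b2) > 0
                else np.nan,
                "cb": scoring.collective_benefit(s_dyad, s_a2, s_b2).cb
                if max(s_a2, s_b2) > 0
                else np.nan,
                "n_conflicts": summary.n_conflicts,
                "pct_conflicts": summary.pct_conflicts,
                "n_resolvable": summary.n_resolvable,
                "n_resolved": summary.n_resolved,
                "n_both_wrong": summary.n_both_wrong,
                "resolution_rate": summary.resolution_rate
                if summary.resolution_rate is not None
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _fit_words_lmm(lmm_data: pd.DataFrame):
    """Gaussian LMM for trial word counts, robust to fragile REML retries."""
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = smf.mixedlm(
        "words_total ~ conflict + identification", lmm_data,
        groups=lmm_data["dyad_id"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for kwargs in (
            {"reml": True, "method": "lbfgs"},
            {"reml": False, "method": "lbfgs"},
            {"reml": False, "method": "powell"},
        ):
            try:
                return model.fit(**kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
    raise RuntimeError("word-count mixed model failed to fit")


def _conflict_trials(trials: pd.DataFrame) -> pd.DataFrame:
    day2 = trials[trials["study_day"] == 2].copy()
    day2["words_total"] = day2["words_a"] + day2["words_b"]
    return day2


@dataclass
class AnalysisReport:
    """Ordered collection of every fitted model and summary in the pipeline."""

    sections: dict[str, object]

    def __getitem__(self, key: str) -> object:
        return self.sections[key]

    def render(self) -> str:
        lines = ["Dyadic olfactory decision-making: full analysis report", "=" * 54]
        for name, obj in self.sections.items():
            lines.append("")
            lines.append(f"[{name}]")
            if isinstance(obj, FitResult):
                lines.append(obj.description)
                lines.append(obj.table.to_string(index=False, float_format="%.4f"))
            elif isinstance(obj, scoring.PairedComparison):
                lines.append(
                    f"mean diff = {obj.mean_diff:.4f}, t({obj.df}) = {obj.t:.3f}, "
                    f"p = {obj.p:.4g}, 95% CI [{obj.ci_low:.3f}, {obj.ci_high:.3f}]"
                )
            elif isinstance(obj, ModelComparison):
                lines.append(
                    f"BIC simple = {obj.bic_simple:.2f}, BIC complex = "
                    f"{obj.bic_complex:.2f}, BF01 = {obj.bf01:.3f}"
                )
            elif isinstance(obj, pd.DataFrame):
                lines.append(obj.to_string(index=False, float_format="%.4f"))
            elif isinstance(obj, Mapping):
                for k, v in obj.items():
                    lines.append(f"{k} = {v}")
            else:
                lines.append(str(obj))
        return "\n".join(lines)


def run_full_analysis(dataset: Mapping[str, pd.DataFrame]) -> AnalysisReport:
    """Run the complete analysis sequence on a study dataset.

    ``dataset`` must contain ``trials`` and ``scores`` tables (the formats
    produced by :mod:`olfdyad.synthetic` and validated by :mod:`olfdyad.io`).
    Sections, in order: demographics, metacognition, collective-vs-individual
    baselines, similarity->benefit, conflict summaries and regressions,
    word-count models, talkative-wins, confidence-lexicon models, and the
    Bayes-factor model comparison.
    """
    for key in ("trials", "scores"):
        if key not in dataset:
            raise KeyError(f"dataset is missing the {key!r} table")
    trials = dataset["trials"]
    scores = dataset["scores"]
    sections: dict[str, object] = {}

    # --- demographics: day-1 subtest scores on age and gender -------------
    day1 = scores[scores["day"] == 1]
    for label, col in (("threshold", "t_score"), ("discrimination", "d_score"),
                       ("identification", "i_score")):
        sections[f"demographics_{label}"] = fit_linear(
            day1.dropna(subset=[col, "age", "gender"]),
            f"{col} ~ age + gender",
            description=f"ols: day-1 {label} score ~ age + gender",
        )

    # --- metacognition: accuracy tracks confidence (individual trials) ----
    day1_trials = trials[trials["study_day"] == 1]
    for task in ("discrimination", "identification"):
        block = day1_trials[day1_trials["task"] == task]
        sections[f"metacognition_profile_{task}"] = accuracy_by_confidence(block)
        sections[f"metacognition_{task}"] = fit_binary_clustered(
            block.assign(correct_a=block["correct_a"].astype(int)),
            "correct_a ~ confidence_a",
            cluster="subject_a",
            description=f"logistic: {task} accuracy ~ confidence | RI(subject)",
        )

    # --- collective vs individual baselines --------------------------------
    dyads = build_dyad_table(trials, scores)
    for task in ("discrimination", "identification"):
        block = dyads[dyads["task"] == task]
        baselines = scoring.compare_dyad_baselines(
            block["s_dyad"], block["s_best_day2"], block["s_mean_day2"]
        )
        sections[f"dyad_vs_best_{task}"] = baselines["dyad_vs_best"]
        sections[f"dyad_vs_average_{task}"] = baselines["dyad_vs_average"]

    # --- similarity ratio -> collective benefit ----------------------------
    for task in ("discrimination", "identification"):
        block = dyads[dyads["task"] == task].dropna(subset=["cb"])
        for basis in ("day1", "day2"):
            sections[f"similarity_benefit_{task}_{basis}"] = fit_linear(
                block.dropna(subset=[f"ratio_{basis}"]),
                f"cb ~ ratio_{basis}",
                description=f"ols: {task} collective benefit ~ {basis} similarity ratio",
            )

    # --- conflicts ----------------------------------------------------------
    sections["conflict_summary"] = (
        dyads.groupby("task", observed=True)
        .agg(
            mean_conflicts=("n_conflicts", "mean"),
            sd_conflicts=("n_conflicts", "std"),
            pct_conflicts=("pct_conflicts", "mean"),
            mean_resolution=("resolution_rate", "mean"),
            sd_resolution=("resolution_rate", "std"),
        )
        .reset_index()
    )
    wide = dyads.pivot(index="dyad_id", columns="task", values="n_conflicts").dropna()
    sections["conflict_count_task_comparison"] = scoring.paired_comparison(
        wide["discrimination"], wide["identification"], "conflicts_discrimination_vs_identification"
    )
    for task in ("discrimination", "identification"):
        block = dyads[dyads["task"] == task]
        sections[f"similarity_conflicts_{task}"] = fit_linear(
            block, "n_conflicts ~ ratio_day1",
            description=f"ols: {task} conflict count ~ day-1 similarity ratio",
        )
        sections[f"similarity_resolution_{task}"] = fit_linear(
            block.dropna(subset=["resolution_rate"]), "resolution_rate ~ ratio_day1",
            description=f"ols: {task} resolution rate ~ day-1 similarity ratio",
        )

    # --- word counts --------------------------------------------------------
    day2 = _conflict_trials(trials)
    lmm_data = day2.assign(
        conflict=day2["conflict"].astype(int),
        identification=(day2["task"] == "identification").astype(int),
    )
    mixed = _fit_words_lmm(lmm_data)
    conf = mixed.conf_int(alpha=0.05)
    fe = [t for t in mixed.params.index if t != "Group Var"]
    sections["word_count_lmm"] = FitResult(
        table=pd.DataFrame(
            {
                "term": fe,
                "estimate": mixed.params[fe].to_numpy(),
                "se": mixed.bse[fe].to_numpy(),
                "statistic": mixed.tvalues[fe].to_numpy(),
                "df": float(mixed.df_resid),
                "p": mixed.pvalues[fe].to_numpy(),
                "ci_low": conf.loc[fe, 0].to_numpy(),
                "ci_high": conf.loc[fe, 1].to_numpy(),
                "exponentiated": np.nan,
            }
        )[ESTIMATE_COLUMNS],
        description="lmm: dyad words per trial ~ conflict + task | RI(dyad)",
        loglike=float(mixed.llf),
        nobs=int(mixed.nobs),
    )

    resolvable = day2[
        day2["conflict"] & (day2["correct_a"] != day2["correct_b"])
    ].assign(success=lambda d: d["joint_correct"].astype(int))
    sections["resolution_words"] = fit_binary_clustered(
        resolvable, "success ~ words_total", cluster="dyad_id",
        description="logistic: conflict resolution ~ total words | RI(dyad)",
    )
    task_fits: dict[str, FitResult] = {}
    for task in ("discrimination", "identification"):
        block = resolvable[resolvable["task"] == task]
        task_fits[task] = fit_binary_clustered(
            block, "success ~ words_total", cluster="dyad_id",
            description=f"logistic: {task} conflict resolution ~ total words | RI(dyad)",
        )
    raw_p = [task_fits[t].term("words_total")["p"] for t in task_fits]
    for (task, fit), p_corr in zip(task_fits.items(), holm_correct(raw_p)):
        idx = fit.table.index[fit.table["term"] == "words_total"][0]
        fit.table.loc[idx, "p"] = p_corr
        fit.table.loc[idx, "term"] = "words_total [corrected]"
        sections[f"resolution_words_{task}"] = fit

    # --- within/between/imbalance word-use decomposition -------------------
    ident_conf = resolvable[resolvable["task"] == "identification"]
    if not ident_conf.empty:
        comp = language.word_use_components(
            ident_conf[["dyad_id", "trial_index", "words_a", "words_b"]]
        )
        comp_data = ident_conf.merge(comp, on=["dyad_id", "trial_index"])
        sections["word_use_components"] = fit_binary_clustered(
            comp_data, "success ~ within_dev + between + imbalance", cluster="dyad_id",
            description="logistic: identification resolution ~ word-use components | RI(dyad)",
        )

    # --- talkative-wins ----------------------------------------------------
    talk = day2[(day2["task"] == "identification") & day2["conflict"]].copy()
    outcomes = [
        language.talkative_outcome(r.words_a, r.words_b, r.answer_a, r.answer_b, r.joint_answer)
        for r in talk.itertuples()
    ]
    talk["outcome"] = [o.value for o in outcomes]
    usable = talk[talk["outcome"] != language.TalkativeOutcome.TIE_OR_EXCLUDED.value]
    usable = usable.assign(
        more_talkative_won=(
            usable["outcome"] == language.TalkativeOutcome.MORE_TALKATIVE_WON.value
        ).astype(int)
    )
    fit_talk = fit_binary_clustered(
        usable, "more_talkative_won ~ 1", cluster="dyad_id",
        description="logistic: P(more talkative wins the conflict) | RI(dyad)",
    )
    fit_talk.extra["win_probability"] = prob_from_logodds(
        fit_talk.term("Intercept")["estimate"]
    )
    sections["talkative_wins"] = fit_talk

    # --- confidence lexicon -------------------------------------------------
    lex_data = day2.assign(
        conflict=day2["conflict"].astype(int),
        identification=(day2["task"] == "identification").astype(int),
    )
    sections["lexicon_poisson"] = fit_count_clustered(
        lex_data, "lexicon_count ~ conflict + identification", cluster="dyad_id",
        description="poisson: confidence-word count ~ conflict + task | RI(dyad)",
    )
    sections["lexicon_poisson_interaction"] = fit_count_clustered(
        lex_data, "lexicon_count ~ conflict * identification", cluster="dyad_id",
        description="poisson: confidence-word count ~ conflict * task | RI(dyad)",
    )
    res_lex = resolvable.assign(
        identification=(resolvable["task"] == "identification").astype(int)
    )
    simple = fit_binary_clustered(
        res_lex, "success ~ lexicon_count", cluster="dyad_id",
        description="logistic: conflict resolution ~ confidence-word count | RI(dyad)",
    )
    complex_ = fit_binary_clustered(
        res_lex, "success ~ lexicon_count * identification", cluster="dyad_id",
        description="logistic: conflict resolution ~ confidence words * task | RI(dyad)",
    )
    sections["resolution_lexicon"] = simple
    sections["resolution_lexicon_interaction"] = complex_
    sections["lexicon_model_comparison"] = bayes_factor_bic(simple, complex_)

    sections["dyad_table"] = dyads
    return AnalysisReport(sections=sections)
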