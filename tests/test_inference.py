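"""Model-fitting stage: GLMM correctness, OLS, Bayes factors, full report."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from olfdyad import inference, synthetic
from olfdyad._mixed import fit_mixed_glm
from olfdyad.dyad_models import DyadRule


def _clustered_logistic(rng, n_clusters=20, n_per=16, beta=(-0.3, 0.9), sd=0.8):
    g = np.repeat(np.arange(n_clusters), n_per)
    u = rng.normal(0, sd, n_clusters)
    x = rng.normal(size=g.size)
    eta = beta[0] + beta[1] * x + u[g]
    y = (rng.random(g.size) < expit(eta)).astype(int)
    return pd.DataFrame({"y": y, "x": x, "g": g})


class TestMixedGLM:
    def test_sigma_zero_equals_plain_glm(self, rng):
        df = _clustered_logistic(rng, sd=0.0)
        X = sm.add_constant(df["x"]).to_numpy()
        ours = fit_mixed_glm(df["y"].to_numpy(), X, df["g"].to_numpy(),
                             "binomial", re_sd=0.0)
        glm = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit()
        assert np.allclose(ours.params, glm.params, atol=1e-6)
        y_pois = rng.poisson(np.exp(0.4 + 0.5 * df["x"]))
        ours_p = fit_mixed_glm(y_pois, X, df["g"].to_numpy(), "poisson", re_sd=0.0)
        glm_p = sm.GLM(y_pois, X, family=sm.families.Poisson()).fit()
        assert np.allclose(ours_p.params, glm_p.params, atol=1e-6)

    def test_agrees_with_lme4_adaptive_quadrature(self, rng, tmp_path):
        """Independent oracle: glmer with nAGQ=25 on the same small dataset."""
        df = _clustered_logistic(rng)
        df_pois = df.assign(y=rng.poisson(np.exp(0.5 + 0.4 * df["x"]
                                                 + 0.5 * rng.normal(0, 1, 20)[df["g"]])))
        df.to_csv(tmp_path / "bin.csv", index=False)
        df_pois.to_csv(tmp_path / "pois.csv", index=False)
        rscript = tmp_path / "oracle.R"
        rscript.write_text(
            """
            suppressMessages(library(lme4))
            b <- read.csv(file.path("%s", "bin.csv"))
            mb <- glmer(y ~ x + (1|g), data=b, family=binomial, nAGQ=25)
            p <- read.csv(file.path("%s", "pois.csv"))
            mp <- glmer(y ~ x + (1|g), data=p, family=poisson, nAGQ=25)
            out <- list(bin=c(fixef(mb), sqrt(unlist(VarCorr(mb))), as.numeric(logLik(mb))),
                        pois=c(fixef(mp), sqrt(unlist(VarCorr(mp))), as.numeric(logLik(mp))))
            cat(jsonlite::toJSON(out, digits=10))
            """ % (tmp_path, tmp_path)
        )
        res = subprocess.run(["Rscript", str(rscript)], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        oracle = json.loads(res.stdout)
        X = sm.add_constant(df["x"]).to_numpy()
        ours_b = fit_mixed_glm(df["y"].to_numpy(), X, df["g"].to_numpy(), "binomial")
        np.testing.assert_allclose(ours_b.params, oracle["bin"][:2], atol=5e-3)
        assert abs(ours_b.re_sd - oracle["bin"][2]) < 5e-3
        assert abs(ours_b.loglike - oracle["bin"][3]) < 1e-2
        ours_p = fit_mixed_glm(df_pois["y"].to_numpy(), X, df["g"].to_numpy(), "poisson")
        np.testing.assert_allclose(ours_p.params, oracle["pois"][:2], atol=1e-2)
        assert abs(ours_p.re_sd - oracle["pois"][2]) < 1e-2

    def test_nominal_ci_coverage_under_null(self):
        """Wald 95% CIs for a null slope cover 0 at ~nominal rate."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            df = _clustered_logistic(rng, n_clusters=20, n_per=8, beta=(0.2, 0.0), sd=0.6)
            fit = inference.fit_binary_clustered(df, "y ~ x", cluster="g")
            row = fit.term("x")
            hits += row["ci_low"] <= 0.0 <= row["ci_high"]
        from scipy.stats import binomtest

        assert binomtest(hits, n_seeds, 0.95).pvalue > 0.01

    def test_separation_flagged_and_penalized(self):
        df = pd.DataFrame(
            {
                "y": [0] * 10 + [1] * 10,
                "x": [0.0] * 10 + [1.0] * 10,
                "g": list(range(5)) * 4,
            }
        )
        fit = inference.fit_binary_clustered(df, "y ~ x", cluster="g")
        assert fit.extra["penalized"]
        assert np.isfinite(fit.term("x")["estimate"])

    def test_count_outcome_validation(self):
        df = pd.DataFrame({"y": [0.5, 1.2], "x": [0, 1], "g": [0, 1]})
        with pytest.raises(ValueError):
            inference.fit_count_clustered(df, "y ~ x", cluster="g")
        df_zero = pd.DataFrame({"y": [0, 0, 0, 0], "x": [0, 1, 0, 1], "g": [0, 0, 1, 1]})
        with pytest.raises(ValueError):
            inference.fit_count_clustered(df_zero, "y ~ x", cluster="g")


class TestLinearFits:
    def test_exact_line(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 * df["x"]
        fit = inference.fit_linear(df, "y ~ x")
        assert fit.term("x")["estimate"] == pytest.approx(2.0)
        assert fit.term("x")["se"] == pytest.approx(0.0, abs=1e-10)

    def test_residual_df(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20)})
        df["y"] = 1 + df["x"] + rng.normal(size=20)
        fit = inference.fit_linear(df, "y ~ x")
        assert fit.term("x")["df"] == 18

    def test_slope_recovery_within_ci(self):
        covered = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"r": rng.uniform(0.2, 1.0, 20)})
            df["cb"] = 0.8 + 0.7 * df["r"] + rng.normal(0, 0.15, 20)
            row = inference.fit_linear(df, "cb ~ r").term("r")
            covered += row["ci_low"] <= 0.7 <= row["ci_high"]
        assert covered >= 32  # ~95% nominal over 40 draws

    def test_rank_deficient_rejected(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=12)})
        df["x2"] = 2 * df["x"]
        df["y"] = df["x"] + rng.normal(size=12)
        with pytest.raises(ValueError):
            inference.fit_linear(df, "y ~ x + x2")


class TestAccuracyByConfidence:
    def _trials(self, rng, n=2000, or_per_level=1.0, base=0.5):
        conf = rng.integers(1, 5, size=n)
        eta = np.log(base / (1 - base)) + np.log(or_per_level) * (conf - 2.5)
        correct = rng.random(n) < expit(eta)
        return pd.DataFrame(
            {
                "subject_a": rng.integers(0, 20, size=n).astype(str),
                "confidence_a": conf,
                "correct_a": correct,
            }
        )

    def test_all_correct(self, rng):
        df = self._trials(rng, n=200)
        df["correct_a"] = True
        table = inference.accuracy_by_confidence(df)
        assert (table["accuracy"] == 1.0).all()

    def test_flat_profile_when_uninformative(self, rng):
        df = self._trials(rng, n=6000, or_per_level=1.0, base=0.6)
        table = inference.accuracy_by_confidence(df)
        overall = table[table["subject"] == "all"]
        se = np.sqrt(0.6 * 0.4 / (6000 / 4))
        assert (np.abs(overall["accuracy"] - 0.6) < 4 * se).all()

    def test_or_recovery(self, rng):
        df = self._trials(rng, n=8000, or_per_level=2.0)
        fit = inference.fit_binary_clustered(
            df.assign(correct_a=df["correct_a"].astype(int)),
            "correct_a ~ confidence_a", cluster="subject_a",
        )
        row = fit.term("confidence_a")
        assert row["ci_low"] <= np.log(2.0) <= row["ci_high"]

    def test_missing_column(self):
        with pytest.raises(ValueError):
            inference.accuracy_by_confidence(pd.DataFrame({"confidence_a": [1]}))


class TestBayesFactor:
    def _fit(self, bic, nobs=100):
        return inference.FitResult(table=pd.DataFrame(), description="stub",
                                   bic=bic, nobs=nobs)

    def test_equal_bics(self):
        assert inference.bayes_factor_bic(self._fit(10.0), self._fit(10.0)).bf01 == 1.0

    def test_two_point_difference(self):
        cmp_ = inference.bayes_factor_bic(self._fit(10.0), self._fit(12.0))
        assert cmp_.bf01 == pytest.approx(np.e)

    def test_alignment_error(self):
        with pytest.raises(ValueError):
            inference.bayes_factor_bic(self._fit(10.0, 100), self._fit(10.0, 90))


class TestHolm:
    def test_adjusts_upward(self):
        adj = inference.holm_correct([0.01, 0.04])
        assert adj[0] == pytest.approx(0.02)
        assert adj[1] == pytest.approx(0.04)


class TestFullAnalysis:
    @pytest.fixture(scope="class")
    def report(self, default_dataset):
        return inference.run_full_analysis(default_dataset)

    def test_all_sections_present_in_order(self, report):
        keys = list(report.sections)
        for expected in (
            "demographics_threshold", "metacognition_discrimination",
            "dyad_vs_best_discrimination", "dyad_vs_average_identification",
            "similarity_benefit_discrimination_day1", "conflict_summary",
            "similarity_conflicts_identification", "word_count_lmm",
            "resolution_words", "word_use_components", "talkative_wins",
            "lexicon_poisson", "lexicon_model_comparison",
        ):
            assert expected in keys
        assert keys.index("demographics_threshold") < keys.index("talkative_wins")

    def test_corrected_label_applied(self, report):
        terms = list(report["resolution_words_identification"].table["term"])
        assert any("[corrected]" in t for t in terms)

    def test_word_count_conflict_effect_positive(self, report):
        assert report["word_count_lmm"].term("conflict")["estimate"] > 20

    def test_render_mentions_every_section(self, report):
        text = report.render()
        for key in report.sections:
            assert f"[{key}]" in text

    def test_missing_table_named(self, default_dataset):
        with pytest.raises(KeyError, match="scores"):
            inference.run_full_analysis({"trials": default_dataset["trials"]})

    def test_voting_dataset_matches_average_baseline(self):
        dataset = synthetic.generate_study_dataset(
            rule=DyadRule.COIN_FLIP_VOTING, seed=23
        )
        report = inference.run_full_analysis(dataset)
        for task in ("discrimination", "identification"):
            cmp_ = report[f"dyad_vs_average_{task}"]
            # voting predicts zero difference; allow 3x the paired-test SE
            se = (cmp_.ci_high - cmp_.ci_low) / (2 * 2.093)  # t_{.975,19}
            assert abs(cmp_.mean_diff) < 3 * se + 1e-9
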