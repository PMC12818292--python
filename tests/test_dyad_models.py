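"""Observer model accuracy, aggregation rules, and the analytic benchmarks."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from olfdyad.dyad_models import (
    DyadRule,
    ObserverParams,
    combine_dyad_decision,
    combine_dyad_decisions,
    simulate_individual_trial,
    simulate_session,
    simulate_trials,
    wcs_oracle,
)


def nafc_accuracy(ability: float, m: int) -> float:
    """Independent oracle: P(correct) for argmax of target N(a,1) vs m-1 N(0,1)."""
    f = lambda e: norm.pdf(e - ability) * norm.cdf(e) ** (m - 1)
    return quad(f, -10, 12 + ability)[0]


class TestIndividualObserver:
    @pytest.mark.parametrize("m, chance", [(3, 1 / 3), (4, 1 / 4)])
    def test_zero_ability_is_chance(self, m, chance, rng):
        n = 10_000
        arrays = simulate_trials(ObserverParams(ability=0.0), m, n, rng)
        se = math.sqrt(chance * (1 - chance) / n)
        assert abs(arrays["correct"].mean() - chance) < 3 * se

    def test_ability_two_matches_quadrature_oracle(self, rng):
        n = 20_000
        expected = nafc_accuracy(2.0, 3)
        arrays = simulate_trials(ObserverParams(ability=2.0), 3, n, rng)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(arrays["correct"].mean() - expected) < 3 * se

    def test_choice_is_argmax(self, rng):
        trial = simulate_individual_trial(ObserverParams(ability=1.0), 4, rng)
        assert trial.choice == int(np.argmax(trial.evidence))
        assert trial.correct == (trial.choice == trial.target_index)
        assert 1 <= trial.confidence <= 4

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ObserverParams(ability=-0.1)
        with pytest.raises(ValueError):
            ObserverParams(ability=1.0, meta_noise=-1)
        with pytest.raises(ValueError):
            ObserverParams(ability=1.0, n_conf_levels=4, conf_bin_edges=(1.0, 0.5, 2.0))


class TestAggregation:
    def test_agreement_wins_under_any_rule(self, rng):
        params = ObserverParams(ability=3.0)
        for rule in DyadRule:
            t = rng.integers(0, 3, size=50)
            a = simulate_trials(params, 3, 50, rng, target_index=t)
            b = {**a}  # identical answers
            out = combine_dyad_decisions(a, b, rule, rng)
            assert np.array_equal(out["joint_choice"], a["choice"])
            assert not out["conflict"].any()

    def test_defer_rule_follows_higher_confidence(self, rng):
        a = {
            "evidence": np.array([[2.0, 0.0, 0.0]]),
            "target_index": np.array([0]),
            "choice": np.array([0]),
            "correct": np.array([True]),
            "confidence": np.array([3]),
        }
        b = {**a, "choice": np.array([1]), "correct": np.array([False]),
             "confidence": np.array([1])}
        out = combine_dyad_decisions(a, b, DyadRule.DEFER_TO_HIGHER_CONFIDENCE, rng)
        assert out["joint_choice"][0] == 0
        assert out["conflict"][0]

    def test_coin_flip_splits_evenly(self, rng):
        n = 4000
        a = {
            "evidence": np.zeros((n, 3)),
            "target_index": np.zeros(n, dtype=int),
            "choice": np.zeros(n, dtype=int),
            "correct": np.ones(n, dtype=bool),
            "confidence": np.ones(n, dtype=int),
        }
        b = {**a, "choice": np.ones(n, dtype=int), "correct": np.zeros(n, dtype=bool)}
        out = combine_dyad_decisions(a, b, DyadRule.COIN_FLIP_VOTING, rng)
        share_a = (out["joint_choice"] == 0).mean()
        assert abs(share_a - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_task_mismatch_rejected(self, rng):
        t1 = simulate_individual_trial(ObserverParams(ability=1.0), 3, rng)
        t2 = simulate_individual_trial(ObserverParams(ability=1.0), 4, rng)
        with pytest.raises(ValueError):
            combine_dyad_decision(t1, t2, DyadRule.COIN_FLIP_VOTING, rng)


class TestVotingIdentity:
    def test_analytic_identity(self):
        # P(both correct) + 1/2 P(exactly one correct) = (p1 + p2)/2
        # for any answer correlation: expand with joint probabilities
        for p11, p10, p01 in [(0.5, 0.2, 0.1), (0.3, 0.3, 0.2), (0.81, 0.09, 0.09)]:
            p1 = p11 + p10
            p2 = p11 + p01
            dyad = p11 + 0.5 * (p10 + p01)
            assert dyad == pytest.approx((p1 + p2) / 2)

    def test_simulation_identity(self, rng):
        n = 100_000
        pa = ObserverParams(ability=1.8)
        pb = ObserverParams(ability=0.6)
        t = rng.integers(0, 3, size=n)
        a = simulate_trials(pa, 3, n, rng, target_index=t)
        b = simulate_trials(pb, 3, n, rng, target_index=t)
        out = combine_dyad_decisions(a, b, DyadRule.COIN_FLIP_VOTING, rng)
        expected = (a["correct"].mean() + b["correct"].mean()) / 2
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(out["joint_correct"].mean() - expected) < 3 * se


class TestConfidenceSharing:
    def test_defer_beats_best_and_pooling_beats_defer(self, rng):
        n = 100_000
        params = ObserverParams(ability=1.5, meta_noise=0.0)
        t = rng.integers(0, 3, size=n)
        a = simulate_trials(params, 3, n, rng, target_index=t)
        b = simulate_trials(params, 3, n, rng, target_index=t)
        best = max(a["correct"].mean(), b["correct"].mean())
        defer = combine_dyad_decisions(a, b, DyadRule.DEFER_TO_HIGHER_CONFIDENCE, rng)
        pool = combine_dyad_decisions(a, b, DyadRule.EVIDENCE_SUM, rng)
        acc_defer = defer["joint_correct"].mean()
        acc_pool = pool["joint_correct"].mean()
        mc = 3 * math.sqrt(0.25 / n)
        assert acc_defer > best + mc
        assert acc_pool >= acc_defer - mc

    def test_noisy_metacognition_degrades_to_voting(self, rng):
        n = 60_000
        pa = ObserverParams(ability=1.8, meta_noise=60.0)
        pb = ObserverParams(ability=0.6, meta_noise=60.0)
        t = rng.integers(0, 3, size=n)
        a = simulate_trials(pa, 3, n, rng, target_index=t)
        b = simulate_trials(pb, 3, n, rng, target_index=t)
        defer = combine_dyad_decisions(a, b, DyadRule.DEFER_TO_HIGHER_CONFIDENCE, rng)
        voting_pred = (a["correct"].mean() + b["correct"].mean()) / 2
        assert abs(defer["joint_correct"].mean() - voting_pred) < 4 * math.sqrt(0.25 / n)


class TestWcsOracle:
    def test_equal_members(self):
        s_dyad, cb = wcs_oracle(1.3, 1.3)
        assert s_dyad == pytest.approx(1.3 * math.sqrt(2))
        assert cb == pytest.approx(math.sqrt(2))

    def test_benefit_boundary_at_sqrt2_minus_1(self):
        r = math.sqrt(2) - 1
        _, cb = wcs_oracle(r * 2.0, 2.0)
        assert cb == pytest.approx(1.0)
        _, cb_low = wcs_oracle(0.5 * 2.0, 2.0)
        assert cb_low == pytest.approx(1.5 / math.sqrt(2))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            wcs_oracle(0.0, 1.0)
        with pytest.raises(ValueError):
            wcs_oracle(2.0, 1.0)

    def test_2afc_pooling_matches_closed_form(self, rng):
        n = 200_000
        s_low, s_high = 0.9, 1.8
        t = rng.integers(0, 2, size=n)
        a = simulate_trials(ObserverParams(ability=s_low), 2, n, rng, target_index=t)
        b = simulate_trials(ObserverParams(ability=s_high), 2, n, rng, target_index=t)
        pool = combine_dyad_decisions(a, b, DyadRule.EVIDENCE_SUM, rng)
        acc = pool["joint_correct"].mean()
        # sensitivity from 2AFC accuracy via the inverse-normal transform
        s_est = norm.ppf(acc) * math.sqrt(2)
        s_pred, _ = wcs_oracle(s_low, s_high)
        se_acc = math.sqrt(acc * (1 - acc) / n)
        se_s = se_acc * math.sqrt(2) / norm.pdf(norm.ppf(acc))
        assert abs(s_est - s_pred) < 3 * se_s


class TestSimulateSession:
    def test_deterministic_given_seed(self):
        pa = ObserverParams(ability=1.5, meta_noise=0.5)
        pb = ObserverParams(ability=1.0, meta_noise=0.5)
        s1 = simulate_session(pa, pb, DyadRule.DEFER_TO_HIGHER_CONFIDENCE, 16,
                              "identification", seed=11)
        s2 = simulate_session(pa, pb, DyadRule.DEFER_TO_HIGHER_CONFIDENCE, 16,
                              "identification", seed=11)
        assert s1.to_csv() == s2.to_csv()

    def test_conflict_flag_matches_answers(self):
        s = simulate_session(
            ObserverParams(ability=1.0), ObserverParams(ability=1.0),
            DyadRule.COIN_FLIP_VOTING, 16, "discrimination", seed=3
        )
        assert (s["conflict"] == (s["answer_a"] != s["answer_b"])).all()

    @pytest.mark.parametrize("task, expected", [("discrimination", 2 / 3),
                                                ("identification", 3 / 4)])
    def test_guessing_conflict_probability(self, task, expected):
        # independent guessing: P(conflict) = 1 - sum_k p_k^2 = 1 - 1/m
        zero = ObserverParams(ability=0.0)
        n = 6000
        s = simulate_session(zero, zero, DyadRule.COIN_FLIP_VOTING, n, task, seed=5)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(s["conflict"].mean() - expected) < 3 * se

    def test_expert_dyads_rarely_conflict(self):
        expert = ObserverParams(ability=8.0)
        s = simulate_session(expert, expert, DyadRule.COIN_FLIP_VOTING, 500,
                             "discrimination", seed=1)
        assert s["conflict"].mean() < 0.01

    def test_similarity_benefit_slope_positive_across_seeds(self):
        # qualitative form of the headline result: under confidence deferral
        # the OLS slope of collective benefit on similarity ratio is positive;
        # all-positive across 10 seeds is a sign test at p = 2^-10 < 0.01
        import pandas as pd
        import statsmodels.formula.api as smf

        signs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rows = []
            for _ in range(40):
                r = rng.uniform(0.05, 1.0)
                pa = ObserverParams(ability=2.0 * r, meta_noise=0.5)
                pb = ObserverParams(ability=2.0, meta_noise=0.5)
                ses = simulate_session(pa, pb, DyadRule.DEFER_TO_HIGHER_CONFIDENCE,
                                       16, "discrimination", rng)
                sa, sb = ses["correct_a"].sum(), ses["correct_b"].sum()
                if max(sa, sb) == 0:
                    continue
                rows.append({"ratio": min(sa, sb) / max(sa, sb),
                             "cb": ses["joint_correct"].sum() / max(sa, sb)})
            fit = smf.ols("cb ~ ratio", pd.DataFrame(rows)).fit()
            signs.append(fit.params["ratio"] > 0)
        assert all(signs)
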