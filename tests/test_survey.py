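"""Tests for the synthetic survey generator, list-experiment estimator,
design-effect screen, knowledge scoring and model selection/averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from lwfgsim import (
    ANSWER_KEY,
    CandidateModelSummary,
    SurveyConfig,
    aicc_top_set,
    akaike_weights,
    design_effect_check,
    generate_respondents,
    generate_uct_responses,
    knowledge_score,
    knowledge_scores,
    natural_model_average,
    uct_prevalence,
)


class TestRespondentGenerator:
    def test_empty_collection(self):
        assert len(generate_respondents(0, seed=1)) == 0

    def test_seed_determinism(self):
        a = generate_respondents(166, seed=7)
        b = generate_respondents(166, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_licence_fraction_within_exact_binomial_interval(self):
        df = generate_respondents(166, seed=8)
        licensed = int((df.licence != "none").sum())
        ci = binomtest(licensed, 166).proportion_ci(0.95)
        assert ci.low <= 0.42 <= ci.high

    def test_goose_and_duck_most_common_licence(self):
        df = generate_respondents(2_000, seed=9)
        counts = df.loc[df.licence != "none", "licence"].value_counts()
        assert counts.idxmax() == "goose_and_duck"

    def test_site_labels_within_configured_range(self):
        df = generate_respondents(500, seed=10)
        assert df.site_id.between(1, 46).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SurveyConfig(licence_probs={"none": 0.5, "single": 0.1,
                                        "goose_and_duck": 0.1})


class TestUCTGenerator:
    def test_count_bounds(self):
        prof = generate_respondents(800, seed=11)
        uct = generate_uct_responses(prof, seed=12)
        ctrl = uct[uct.group == "control"]
        trt = uct[uct.group == "treatment"]
        for q in ("q_past_year", "q_autumn_winter", "q_spring_summer", "q_cash"):
            assert ctrl[q].between(0, 4).all()
            assert trt[q].between(0, 5).all()

    def test_assignment_ratio(self):
        prof = generate_respondents(189, seed=13)
        uct = generate_uct_responses(prof, seed=14)
        assert (uct.group == "control").sum() == 80
        assert (uct.group == "treatment").sum() == 109

    def test_no_items_no_hunters_gives_zero_counts(self):
        prof = generate_respondents(100, seed=15)
        prof["hunts_geese"] = False
        uct = generate_uct_responses(prof, item_probs=(0, 0, 0, 0), seed=16)
        assert (uct[["q_past_year", "q_autumn_winter"]] == 0).all().all()

    def test_difference_in_means_approaches_prevalence(self):
        prof = generate_respondents(20_000, seed=17)
        uct = generate_uct_responses(prof, sensitive_rules={"q_past_year": True},
                                     seed=18)
        est = uct_prevalence(uct, "q_past_year")
        assert est.theta == pytest.approx(1.0, abs=0.05)


class TestPrevalenceEstimator:
    def test_identical_groups_give_zero(self):
        data = pd.DataFrame({"group": ["control"] * 5 + ["treatment"] * 5,
                             "q_past_year": [1, 2, 1, 2, 1] * 2})
        assert uct_prevalence(data, "q_past_year").theta == pytest.approx(0.0)

    def test_difference_arithmetic(self):
        data = pd.DataFrame({
            "group": ["treatment"] * 109 + ["control"] * 80,
            "q_past_year": [1.5] * 109 + [1.2] * 80,
        })
        assert uct_prevalence(data, "q_past_year").theta == pytest.approx(0.3)

    def test_empty_group_rejected(self):
        data = pd.DataFrame({"group": ["treatment"] * 4, "q_past_year": [1] * 4})
        with pytest.raises(ValueError):
            uct_prevalence(data, "q_past_year")

    @pytest.mark.parametrize("theta", [0.0, 0.1, 0.3])
    def test_estimator_unbiased(self, theta):
        """Mean estimate over 500 synthetic replicates within 2 empirical SE."""
        estimates = []
        for s in range(500):
            rng = np.random.default_rng([21, s])
            prof = generate_respondents(300, seed=[22, s])
            flags = rng.random(len(prof)) < theta
            uct = generate_uct_responses(
                prof, sensitive_rules={"q_past_year": lambda df, f=flags: f},
                seed=[23, s])
            estimates.append(uct_prevalence(uct, "q_past_year").theta)
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - theta) < 2 * se + 1e-9

    def test_formula_se_matches_empirical_se(self):
        thetas, ses = [], []
        for s in range(500):
            prof = generate_respondents(2_000, seed=[31, s])
            rng = np.random.default_rng([32, s])
            flags = rng.random(len(prof)) < 0.25
            uct = generate_uct_responses(
                prof, sensitive_rules={"q_past_year": lambda df, f=flags: f},
                seed=[33, s])
            est = uct_prevalence(uct, "q_past_year")
            thetas.append(est.theta)
            ses.append(est.se)
        assert abs(np.mean(thetas) - 0.25) < 0.01
        assert abs(np.mean(ses) - np.std(thetas, ddof=1)) < 0.1 * np.std(thetas, ddof=1)


class TestDesignEffectCheck:
    def test_null_case_large_p_value(self):
        prof = generate_respondents(600, seed=41)
        uct = generate_uct_responses(prof, seed=42)
        res = design_effect_check(uct, "q_past_year", n_boot=499, seed=43)
        assert res.p_value > 0.05

    def test_power_against_shape_distorting_design_effect(self):
        """Evasive zero-reporting in the treatment group is detected.

        A uniform inflation of a non-sensitive item shifts only the group
        mean and is absorbed into the prevalence estimate, so it is
        invisible to any check built on the difference-in-means null; the
        screen targets violations that distort the count distribution's
        shape, such as a fraction of treatment respondents reporting zero
        for the whole list once the sensitive item appears.
        """
        rejections = 0
        n_sims = 100
        probs = np.array([0.35, 0.10, 0.15, 0.30])
        for s in range(n_sims):
            rng = np.random.default_rng([53, s])
            c = (rng.random((200, 4)) < probs).sum(axis=1)
            t = (rng.random((200, 4)) < probs).sum(axis=1) + (rng.random(200) < 0.3)
            t[rng.random(200) < 0.35] = 0
            uct = pd.DataFrame({"group": ["control"] * 200 + ["treatment"] * 200,
                                "q_past_year": np.concatenate([c, t])})
            res = design_effect_check(uct, "q_past_year", n_boot=199, seed=[54, s])
            rejections += res.p_value <= 0.05
        assert rejections / n_sims > 0.8

    def test_empty_group_rejected(self):
        data = pd.DataFrame({"group": ["treatment"] * 4, "q_past_year": [1] * 4})
        with pytest.raises(ValueError):
            design_effect_check(data, "q_past_year")


class TestKnowledgeScore:
    def test_all_correct(self):
        assert knowledge_score(dict(ANSWER_KEY)) == 5

    def test_all_dont_know(self):
        answers = {sp: "dont_know" for sp in ANSWER_KEY}
        assert knowledge_score(answers) == 0

    def test_partial_credit_counts_matches(self):
        answers = {"lwfg": "protected", "red_breasted_goose": "protected",
                   "mute_swan": "not_protected", "greylag_goose": "not_protected",
                   "goldeneye_duck": "not_protected"}
        # only the mute-swan answer disagrees with the key
        assert knowledge_score(answers) == 4

    def test_unknown_species_rejected(self):
        answers = dict(ANSWER_KEY)
        answers["dodo"] = "protected"
        with pytest.raises(ValueError):
            knowledge_score(answers)

    def test_vectorised_scores_match_scalar(self):
        df = generate_respondents(50, seed=61)
        scores = knowledge_scores(df)
        for i in range(10):
            answers = {sp: df.loc[i, f"know_{sp}"] for sp in ANSWER_KEY}
            assert scores.iloc[i] == knowledge_score(answers)
        assert scores.between(0, 5).all()


def model(name, aicc, **coefs):
    return CandidateModelSummary(name, aicc, coefs)


class TestModelSelection:
    def test_single_candidate_is_its_own_top_set(self):
        m = model("m0", 100.0, x=1.0)
        assert aicc_top_set([m]) == [m]

    def test_delta_rule_application(self):
        ms = [model("a", 100.0, x=1.0), model("b", 103.9, x=2.0),
              model("c", 104.1, x=3.0)]
        assert [m.name for m in aicc_top_set(ms)] == ["a", "b"]

    def test_boundary_tie_excluded(self):
        ms = [model("a", 100.0, x=1.0), model("b", 104.0, x=2.0)]
        assert [m.name for m in aicc_top_set(ms)] == ["a"]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            aicc_top_set([])

    def test_weights_sum_to_one(self):
        w = akaike_weights([100.0, 101.0, 105.0])
        assert w.sum() == pytest.approx(1.0)


class TestNaturalAveraging:
    def test_identical_coefficient_passes_through(self):
        ms = [model("a", 100.0, x=0.7), model("b", 102.0, x=0.7)]
        assert natural_model_average(ms)["x"] == pytest.approx(0.7)

    def test_hand_computed_two_model_average(self):
        # weights exp(0)/Z and exp(-0.5)/Z = 0.6225, 0.3775
        ms = [model("a", 100.0, x=1.0), model("b", 101.0, x=2.0)]
        avg = natural_model_average(ms)
        w2 = np.exp(-0.5) / (1 + np.exp(-0.5))
        assert avg["x"] == pytest.approx(1.0 * (1 - w2) + 2.0 * w2)
        assert avg["x"] == pytest.approx(1.3775, abs=2e-4)

    def test_term_in_single_model_unchanged(self):
        ms = [model("a", 100.0, x=1.0), model("b", 100.5, x=2.0, z=-3.3)]
        assert natural_model_average(ms)["z"] == pytest.approx(-3.3)

    def test_natural_equals_ordinary_average_when_term_everywhere(self):
        ms = [model("a", 100.0, x=1.0), model("b", 101.0, x=2.0),
              model("c", 103.0, x=-1.0)]
        w = akaike_weights([m.aicc for m in ms])
        expected = (w * np.array([1.0, 2.0, -1.0])).sum()
        assert natural_model_average(ms)["x"] == pytest.approx(expected)

    def test_non_finite_aicc_rejected(self):
        with pytest.raises(ValueError):
            model("bad", float("nan"), x=1.0)
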