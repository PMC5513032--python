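import numpy as np
import pytest

from cervical_ce import (
    HealthState as S,
    STRATEGIES,
    build_cascade,
    cascade_completion_probability,
    classify,
    expected_side_effect_cost,
)
from cervical_ce.natural_history import LIVE_STATES


class TestClassify:
    @pytest.mark.parametrize(
        "test,state,expected",
        [
            ("VIA", S.HSIL, 0.61),  # sensitivity for CIN2+
            ("Pap", S.NORMAL, 0.02),  # 1 - specificity
            ("HPV", S.LSIL, 0.45),  # LSIL is below the CIN2+ threshold
            ("HPV", S.DISTANT, 0.81),
            ("VIA+Pap", S.LOCAL, 0.51),
        ],
    )
    def test_positivity_probabilities(self, params, test, state, expected):
        assert classify(test, state, params) == pytest.approx(expected)

    def test_unknown_test_rejected(self, params):
        with pytest.raises(KeyError, match="unknown test"):
            classify("VILI", S.HSIL, params)


class TestCompletion:
    @pytest.mark.parametrize(
        "name,expected",
        [("HPV", 0.68), ("Pap", 0.68), ("VIA+Pap", 0.52), ("VIA", 1.0), ("cryo_all", 1.0)],
    )
    def test_loss_to_follow_up(self, params, name, expected):
        assert cascade_completion_probability(STRATEGIES[name], params) == pytest.approx(
            expected
        )

    def test_single_visit_override(self, params):
        assert (
            cascade_completion_probability(
                STRATEGIES["HPV"].with_single_visit(), params
            )
            == 1.0
        )


class TestSideEffectCost:
    def test_closed_forms(self, params):
        assert expected_side_effect_cost(params, "societal") == pytest.approx(3.2636)
        assert expected_side_effect_cost(params, "clinic") == pytest.approx(2.8504)

    def test_zero_rate(self, params):
        p = params.replace(side_effect_monthly=0.0, ranges={})
        assert expected_side_effect_cost(p, "societal") == 0.0


class TestBuildCascade:
    def test_cryo_all_clinic_baseline_cost(self, params):
        out = build_cascade(STRATEGIES["cryo_all"], params, "clinic")
        expected = 12 + expected_side_effect_cost(params, "clinic")
        for s in LIVE_STATES:
            if s <= S.DISTANT:
                assert out.cost0[s] == pytest.approx(expected)
                assert out.p_treat[s] == 1.0

    def test_via_false_positive_cost(self, params):
        out = build_cascade(STRATEGIES["VIA"], params, "societal")
        mix = 0.8 * 48 + 0.2 * 86
        se = expected_side_effect_cost(params, "societal")
        assert out.p_treat[S.NORMAL] == pytest.approx(0.37)
        assert out.cost0[S.NORMAL] == pytest.approx(18 + 0.37 * (mix + se))

    def test_pap_hsil_treatment_probability(self, params):
        out = build_cascade(STRATEGIES["Pap"], params, "societal")
        assert out.p_treat[S.HSIL] == pytest.approx(0.74 * 0.68)
        # treatment success moves HSIL to Normal with 90% efficacy
        assert out.after[S.HSIL, S.NORMAL] == pytest.approx(0.74 * 0.68 * 0.9)

    def test_pair_strategy_charges_both_screens(self, params):
        out = build_cascade(STRATEGIES["VIA+HPV"], params, "societal")
        assert out.cost0[S.NORMAL] >= 18 + 32

    def test_cancer_states_get_colposcopy_and_staging(self, params):
        out = build_cascade(STRATEGIES["HPV"], params, "societal")
        reach = 0.81 * 0.68
        assert out.p_cancer_workup[S.REGIONAL] == pytest.approx(reach)
        assert out.cost0[S.REGIONAL] == pytest.approx(32 + reach * (160 + 6447))
        assert out.after[S.REGIONAL, S.REGIONAL_TREATED] == pytest.approx(reach)

    def test_perfect_specificity_means_no_false_positive_cost(self, params):
        doc = params.model_dump()
        for t in doc["test_performance"]:
            doc["test_performance"][t]["specificity"] = 1.0
        doc["ranges"] = {}
        from cervical_ce import ParameterSet

        p = ParameterSet.model_validate(doc)
        for name, strat in STRATEGIES.items():
            if name == "cryo_all":
                continue
            out = build_cascade(strat, p, "societal")
            screen_only = sum(
                {"Pap": 39, "VIA": 18, "HPV": 32}[t] for t in strat.tests
            )
            assert out.cost0[S.NORMAL] == pytest.approx(screen_only)
            assert out.cost0[S.LSIL] == pytest.approx(screen_only)

    def test_treatment_probability_monotone_in_sensitivity_and_completion(
        self, params
    ):
        doc = params.model_dump()
        doc["ranges"] = {}
        from cervical_ce import ParameterSet

        last = -1.0
        for sens in (0.2, 0.5, 0.8):
            doc["test_performance"]["HPV"]["sensitivity"] = sens
            p = ParameterSet.model_validate(doc)
            out = build_cascade(STRATEGIES["HPV"], p, "societal")
            assert out.p_treat[S.HSIL] >= last
            last = out.p_treat[S.HSIL]
        last = 2.0
        for ltfu in (0.0, 0.3, 0.6):
            doc["test_performance"]["HPV"]["sensitivity"] = 0.81
            doc["ltfu_2visit"] = ltfu
            p = ParameterSet.model_validate(doc)
            out = build_cascade(STRATEGIES["HPV"], p, "societal")
            assert out.p_treat[S.HSIL] <= last
            last = out.p_treat[S.HSIL]

    def test_after_matrices_are_row_stochastic(self, params):
        for strat in STRATEGIES.values():
            out = build_cascade(strat, params, "societal")
            assert np.allclose(out.after.sum(axis=1), 1.0)
            assert np.all(out.after >= 0)

    def test_unknown_perspective_rejected(self, params):
        with pytest.raises(ValueError, match="perspective"):
            build_cascade(STRATEGIES["VIA"], params, "payer")
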