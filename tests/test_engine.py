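import numpy as np
import pytest

from cervical_ce import (
    STRATEGIES,
    microsimulate,
    run_all,
    run_strategy,
    synthetic_life_table,
)
from cervical_ce.natural_history import N_STATES
from .conftest import constant_q_table, disease_free, zero_costs


@pytest.fixture(scope="module")
def deathless_table():
    return synthetic_life_table(0.0, 0.0, 2.0, 38, 100)


class TestCohortEngine:
    def test_closed_world_life_expectancy(self, params, deathless_table):
        # no disease, no cost, no mortality until the 62-year horizon closes
        p = zero_costs(disease_free(params))
        res = run_strategy("VIA", p, deathless_table, "societal")
        assert res.le_undiscounted == pytest.approx(62.0)
        assert res.cost == 0.0

    def test_discounted_le_matches_annuity_closed_form(self, params):
        # disease-free cohort at constant annual mortality is a geometric
        # annuity: sum_t s^t v^t / 12 with s the monthly survival
        q = 0.02
        p = zero_costs(disease_free(params, smr=1.0))
        lt = constant_q_table(q)
        res = run_strategy("cryo_all", p, lt, "societal")
        s = (1 - q) ** (1 / 12)
        v = 1 / 1.0025
        t = np.arange((100 - 38) * 12)
        expected = np.sum((s * v) ** t) / 12
        assert res.le_discounted == pytest.approx(expected, rel=1e-9)
        expected_undisc = np.sum(s**t) / 12
        assert res.le_undiscounted == pytest.approx(expected_undisc, rel=1e-9)

    def test_mass_conservation_every_cycle(self, params, life_table):
        res = run_strategy("HPV", params, life_table, "societal", keep_trace=True)
        assert res.trace is not None
        assert np.allclose(res.trace.sum(axis=1), 1.0, atol=1e-12)
        assert res.trace.shape[1] == N_STATES

    def test_discount_monotonicity(self, params, life_table):
        res_base = run_strategy("VIA", params, life_table, "societal")
        hi = params.replace(discount_monthly=0.005)
        res_hi = run_strategy("VIA", hi, life_table, "societal")
        assert res_hi.cost < res_base.cost
        assert res_hi.le_discounted < res_base.le_discounted
        assert res_hi.le_undiscounted == pytest.approx(res_base.le_undiscounted)

    def test_societal_cost_dominates_clinic(self, params, life_table):
        for name in STRATEGIES:
            soc = run_strategy(name, params, life_table, "societal")
            cli = run_strategy(name, params, life_table, "clinic")
            assert soc.cost >= cli.cost

    def test_higher_sensitivity_never_lowers_le(self, params, life_table):
        doc = params.model_dump()
        doc["ranges"] = {}
        from cervical_ce import ParameterSet

        les = []
        for sens in (0.3, 0.6, 0.9):
            doc["test_performance"]["Pap"]["sensitivity"] = sens
            p = ParameterSet.model_validate(doc)
            les.append(run_strategy("Pap", p, life_table).le_discounted)
        assert les == sorted(les)

    def test_higher_ltfu_never_raises_le(self, params, life_table):
        les = []
        for ltfu in (0.0, 0.32, 0.6):
            p = params.replace(ltfu_2visit=ltfu, ranges={})
            les.append(run_strategy("HPV", p, life_table).le_discounted)
        assert les == sorted(les, reverse=True)

    def test_zeroed_costs_leave_le_unchanged(self, params, life_table):
        base = run_strategy("Pap", params, life_table)
        zeroed = run_strategy("Pap", zero_costs(params), life_table)
        assert zeroed.cost == 0.0
        assert zeroed.le_discounted == pytest.approx(base.le_discounted)

    def test_run_all_shape_and_ordering(self, params, life_table):
        df = run_all(params, life_table)
        assert len(df) == len(STRATEGIES)
        assert list(df.columns) == [
            "strategy",
            "cost_societal",
            "le_discounted",
            "le_undiscounted",
            "cost_clinic",
        ]
        assert df["cost_societal"].is_monotonic_increasing
        assert (df["le_discounted"] <= df["le_undiscounted"]).all()

    def test_life_table_must_cover_start_age(self, params):
        lt = constant_q_table(0.01, age_min=50)
        with pytest.raises(ValueError, match="start age"):
            run_strategy("VIA", params, lt)


class TestMicrosimulation:
    def test_degenerate_deterministic_individual_matches_cohort(
        self, params, deathless_table
    ):
        # all event probabilities 0 or 1: a single sampled woman reproduces
        # the cohort result exactly
        doc = disease_free(params, side_effect_monthly=0.0).model_dump()
        doc["test_performance"]["Pap"]["specificity"] = 1.0
        from cervical_ce import ParameterSet

        p = ParameterSet.model_validate(doc)
        cohort = run_strategy("Pap", p, deathless_table, "societal")
        micro = microsimulate(
            "Pap", p, deathless_table, "societal", n_individuals=1, seed=7
        )
        assert micro.cost == pytest.approx(cohort.cost)
        assert micro.le_discounted == pytest.approx(cohort.le_discounted)

    def test_same_seed_reproduces(self, params, life_table):
        a = microsimulate("VIA", params, life_table, n_individuals=500, seed=11)
        b = microsimulate("VIA", params, life_table, n_individuals=500, seed=11)
        assert (a.cost, a.le_discounted) == (b.cost, b.le_discounted)

    def test_agrees_with_cohort_within_monte_carlo_error(self, params, life_table):
        cohort = run_strategy("cryo_all", params, life_table, "societal")
        micro = microsimulate(
            "cryo_all", params, life_table, "societal", n_individuals=20_000, seed=3
        )
        assert abs(micro.cost - cohort.cost) < 3 * micro.cost_se
        assert abs(micro.le_discounted - cohort.le_discounted) < 3 * micro.le_se
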