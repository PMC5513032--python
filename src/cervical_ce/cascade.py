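"""Screening/treatment cascade: strategies, test classification, LTFU,
treatment assignment, and expected month-0 costs per true health state.

Seven strategies are modeled: preventative cryotherapy for all women
without screening (single visit), VIA screen-and-treat (single visit), Pap
or HPV screening (two visits: screen, then results + treatment), and the
three test pairs (three visits: screen, confirmation, treatment).  Joint
sensitivity/specificity is used for pairs.  All loss to follow-up occurs
before the final treatment visit: lost women pay every screening visit but
receive no treatment, no benefit and no side-effect exposure.

Screen-positive completers with HSIL (or falsely positive Normal/LSIL)
receive ablative lesion treatment, 80% cryotherapy / 20% LEEP, with one
month of side-effect risk; treatment succeeds (HSIL returns to Normal) with
probability ``treatment_effectiveness``.  Screen-positive completers in an
invasive-cancer state undergo colposcopy (staging gateway) plus the
stage-specific cancer-care cost and enter the corresponding treated state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .natural_history import (
    N_STATES,
    CANCER_STATES,
    HealthState,
    LIVE_STATES,
    TRUE_POSITIVE_STATES,
)
from .parameters import ParameterSet

__all__ = [
    "Strategy",
    "STRATEGIES",
    "CascadeOutcome",
    "classify",
    "cascade_completion_probability",
    "expected_side_effect_cost",
    "build_cascade",
]

_SCREEN_COST_KEY = {"Pap": "pap", "VIA": "via", "HPV": "hpv"}


@dataclass(frozen=True)
class Strategy:
    """A screening/treatment policy.

    ``tests`` are the component screen names (empty for cryo_all); the
    combined classification of a pair uses the pair's own joint
    sensitivity/specificity entry (e.g. ``"VIA+HPV"``).
    """

    name: str
    tests: tuple[str, ...]
    n_visits: int
    single_visit_override: bool = False

    def __post_init__(self):
        if self.name == "cryo_all":
            if self.tests or self.n_visits != 1:
                raise ValueError("cryo_all has no tests and a single visit")
        elif not self.tests:
            raise ValueError("screening strategies need at least one test")
        if self.n_visits not in (1, 2, 3):
            raise ValueError("n_visits must be 1, 2 or 3")

    @property
    def combined_test(self) -> str:
        return "+".join(self.tests)

    def with_single_visit(self) -> "Strategy":
        return Strategy(self.name, self.tests, self.n_visits, True)


STRATEGIES: dict[str, Strategy] = {
    "cryo_all": Strategy("cryo_all", (), 1),
    "VIA": Strategy("VIA", ("VIA",), 1),
    "Pap": Strategy("Pap", ("Pap",), 2),
    "HPV": Strategy("HPV", ("HPV",), 2),
    "VIA+HPV": Strategy("VIA+HPV", ("VIA", "HPV"), 3),
    "VIA+Pap": Strategy("VIA+Pap", ("VIA", "Pap"), 3),
    "HPV+Pap": Strategy("HPV+Pap", ("HPV", "Pap"), 3),
}


def classify(test_name: str, true_state: HealthState, params: ParameterSet) -> float:
    """Probability the test calls ``true_state`` positive.

    True positivity is CIN2+ (HSIL or invasive cancer): those states return
    the test's sensitivity, Normal/LSIL return one minus its specificity.
    """
    try:
        perf = params.test_performance[test_name]
    except KeyError:
        raise KeyError(f"unknown test {test_name!r}") from None
    if true_state in TRUE_POSITIVE_STATES:
        return perf.sensitivity
    if true_state in (HealthState.NORMAL, HealthState.LSIL):
        return 1.0 - perf.specificity
    return 0.0


def cascade_completion_probability(strategy: Strategy, params: ParameterSet) -> float:
    """Probability a screen-positive woman reaches the treatment visit."""
    if strategy.single_visit_override or strategy.n_visits == 1:
        return 1.0
    if strategy.n_visits == 2:
        return 1.0 - params.ltfu_2visit
    return 1.0 - params.ltfu_3visit


def expected_side_effect_cost(params: ParameterSet, perspective: str) -> float:
    """Expected cost of one month of treatment side-effect exposure."""
    costs = params.unit_costs[perspective].side_effects
    p_major = params.p_side_effect_major
    return params.side_effect_monthly * (
        p_major * costs.major + (1.0 - p_major) * costs.minor
    )


@dataclass(frozen=True)
class CascadeOutcome:
    """Expected month-0 consequences of one strategy, per true state.

    ``cost0[s]`` is the expected cascade cost for a woman whose true state
    is ``s`` (screening visits for everyone; treatment, side-effect and
    cancer-workup costs weighted by their probabilities).  ``after`` is the
    row-stochastic state-reassignment matrix applied to the cohort at month
    0 (successful lesion treatment moves HSIL to Normal; staged cancers
    move to their treated state).
    """

    strategy: Strategy
    perspective: str
    p_treat: np.ndarray
    p_cancer_workup: np.ndarray
    cost0: np.ndarray
    after: np.ndarray


def build_cascade(
    strategy: Strategy, params: ParameterSet, perspective: str
) -> CascadeOutcome:
    if perspective not in params.unit_costs:
        raise ValueError(f"unknown perspective {perspective!r}")
    costs = params.unit_costs[perspective]
    se_cost = expected_side_effect_cost(params, perspective)
    p_cryo = params.p_cryo_given_treatment
    lesion_tx_cost = (
        p_cryo * costs.treatment.cryotherapy + (1.0 - p_cryo) * costs.treatment.leep
    )
    eff = params.treatment_effectiveness
    stage_cost = {
        HealthState.LOCAL: costs.cancer_care.local,
        HealthState.REGIONAL: costs.cancer_care.regional,
        HealthState.DISTANT: costs.cancer_care.distant,
    }
    treated_of = {
        HealthState.LOCAL: HealthState.LOCAL_TREATED,
        HealthState.REGIONAL: HealthState.REGIONAL_TREATED,
        HealthState.DISTANT: HealthState.DISTANT_TREATED,
    }

    p_treat = np.zeros(N_STATES)
    p_workup = np.zeros(N_STATES)
    cost0 = np.zeros(N_STATES)
    after = np.eye(N_STATES)

    if strategy.name == "cryo_all":
        # treat every live woman; no screen, no triage of cancers
        for s in LIVE_STATES:
            p_treat[s] = 1.0
            cost0[s] = costs.treatment.cryotherapy + se_cost
        after[HealthState.HSIL, HealthState.HSIL] = 1.0 - eff
        after[HealthState.HSIL, HealthState.NORMAL] = eff
        return CascadeOutcome(strategy, perspective, p_treat, p_workup, cost0, after)

    screen_cost = sum(
        getattr(costs.screening, _SCREEN_COST_KEY[t]) for t in strategy.tests
    )
    completion = cascade_completion_probability(strategy, params)
    test = strategy.combined_test

    for s in LIVE_STATES:
        if s in (HealthState.LOCAL_TREATED, HealthState.REGIONAL_TREATED,
                 HealthState.DISTANT_TREATED):
            continue  # unoccupied at month 0
        p_pos = classify(test, s, params)
        reach_treatment = p_pos * completion
        cost0[s] = screen_cost
        if s in CANCER_STATES:
            p_workup[s] = reach_treatment
            cost0[s] += reach_treatment * (
                costs.treatment.colposcopy + stage_cost[s]
            )
            after[s, s] = 1.0 - reach_treatment
            after[s, treated_of[s]] = reach_treatment
        else:
            p_treat[s] = reach_treatment
            cost0[s] += reach_treatment * (lesion_tx_cost + se_cost)
            if s == HealthState.HSIL:
                after[s, s] = 1.0 - reach_treatment * eff
                after[s, HealthState.NORMAL] = reach_treatment * eff

    return CascadeOutcome(strategy, perspective, p_treat, p_workup, cost0, after)
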