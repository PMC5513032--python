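"""Markov state space and monthly transition structure.

Eleven health states track squamous intraepithelial lesions (LSIL/HSIL),
invasive cancer by stage (local/regional/distant), the corresponding
treated-cancer states, and two absorbing death states (cancer vs other
causes).  Women whose lesion treatment succeeds, and treated-cancer
patients who cure, return to Normal: progression/regression parameters are
population aggregates with no dependence on disease history, so no separate
post-treatment compartment is carried.

Competing risks within a monthly cycle: background (all-cause, SMR-scaled)
death is applied first; conditional on surviving it, the monthly disease
event probabilities apply directly.  Treated-cancer states keep cancer
mortality and stage progression at ``(1 - treatment_effectiveness)`` times
the untreated value and add a monthly cure probability back to Normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .life_tables import LifeTable, monthly_background_mortality
from .parameters import ParameterSet

__all__ = [
    "HealthState",
    "N_STATES",
    "LIVE_STATES",
    "CANCER_STATES",
    "TREATED_STATES",
    "StateDistribution",
    "initial_state_distribution",
    "build_transition_matrix",
]


class HealthState(IntEnum):
    NORMAL = 0
    LSIL = 1
    HSIL = 2
    LOCAL = 3
    REGIONAL = 4
    DISTANT = 5
    LOCAL_TREATED = 6
    REGIONAL_TREATED = 7
    DISTANT_TREATED = 8
    DEAD_CANCER = 9
    DEAD_OTHER = 10


N_STATES = len(HealthState)
LIVE_STATES = tuple(s for s in HealthState if s < HealthState.DEAD_CANCER)
CANCER_STATES = (HealthState.LOCAL, HealthState.REGIONAL, HealthState.DISTANT)
TREATED_STATES = (
    HealthState.LOCAL_TREATED,
    HealthState.REGIONAL_TREATED,
    HealthState.DISTANT_TREATED,
)
#: States that count as test-positive disease (CIN2+ or worse).
TRUE_POSITIVE_STATES = (HealthState.HSIL,) + CANCER_STATES

_MASS_TOL = 1e-12


@dataclass(frozen=True)
class StateDistribution:
    """Probability mass over the 11 health states (sums to 1)."""

    mass: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", m)
        if m.shape != (N_STATES,):
            raise ValueError(f"mass must have shape ({N_STATES},)")
        if np.any(m < -_MASS_TOL):
            raise ValueError("state masses must be non-negative")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("state masses must sum to 1")

    def live_mass(self) -> float:
        return float(self.mass[list(LIVE_STATES)].sum())

    def __getitem__(self, state: HealthState) -> float:
        return float(self.mass[state])


def initial_state_distribution(params: ParameterSet) -> StateDistribution:
    """Cohort composition at the screening visit.

    A fraction ``prev_disease`` carries HSIL or invasive cancer, split per
    the diseased distribution; the remainder splits Normal/LSIL.  Printed
    split vectors are renormalized here (the CD4<=200 pair prints 1.001).
    """
    m = np.zeros(N_STATES)
    nd = np.array(params.split_nondiseased.as_tuple, dtype=float)
    nd = nd / nd.sum()
    dz = np.array(params.split_diseased.as_tuple, dtype=float)
    dz = dz / dz.sum()
    p = params.prev_disease
    m[HealthState.NORMAL] = (1 - p) * nd[0]
    m[HealthState.LSIL] = (1 - p) * nd[1] + p * dz[0]
    m[HealthState.HSIL] = p * dz[1]
    m[HealthState.LOCAL] = p * dz[2]
    m[HealthState.REGIONAL] = p * dz[3]
    m[HealthState.DISTANT] = p * dz[4]
    return StateDistribution(m)


def build_transition_matrix(
    params: ParameterSet, lt: LifeTable, age_years: float
) -> np.ndarray:
    """Row-stochastic monthly transition matrix at the given age.

    Raises ``ValueError`` if any row's event probabilities exceed 1
    (oversubscribed competing risks).
    """
    q_m = monthly_background_mortality(lt, age_years, params.smr)
    prog = params.progression_monthly
    reg = params.regression_monthly
    mort = params.cancer_mortality_monthly
    fail = 1.0 - params.treatment_effectiveness
    cure = params.cure_monthly

    S = HealthState
    P = np.zeros((N_STATES, N_STATES))

    # conditional-on-surviving-background event blocks, per live state
    events: dict[HealthState, dict[HealthState, float]] = {
        S.NORMAL: {S.LSIL: prog.normal_lsil},
        S.LSIL: {S.HSIL: prog.lsil_hsil, S.NORMAL: reg.lsil_normal},
        S.HSIL: {
            S.LOCAL: prog.hsil_local,
            S.LSIL: reg.hsil_lsil,
            S.NORMAL: reg.hsil_normal,
        },
        S.LOCAL: {S.DEAD_CANCER: mort.local, S.REGIONAL: prog.local_regional},
        S.REGIONAL: {S.DEAD_CANCER: mort.regional, S.DISTANT: prog.regional_distant},
        S.DISTANT: {S.DEAD_CANCER: mort.distant},
        S.LOCAL_TREATED: {
            S.DEAD_CANCER: mort.local * fail,
            S.REGIONAL_TREATED: prog.local_regional * fail,
            S.NORMAL: cure,
        },
        S.REGIONAL_TREATED: {
            S.DEAD_CANCER: mort.regional * fail,
            S.DISTANT_TREATED: prog.regional_distant * fail,
            S.NORMAL: cure,
        },
        S.DISTANT_TREATED: {S.DEAD_CANCER: mort.distant * fail, S.NORMAL: cure},
    }

    for state, moves in events.items():
        total = sum(moves.values())
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"monthly event probabilities for state {state.name} sum to "
                f"{total:.4f} > 1"
            )
        surv = 1.0 - q_m
        P[state, S.DEAD_OTHER] = q_m
        for dest, p in moves.items():
            P[state, dest] += surv * p
        P[state, state] += surv * (1.0 - total)

    P[S.DEAD_CANCER, S.DEAD_CANCER] = 1.0
    P[S.DEAD_OTHER, S.DEAD_OTHER] = 1.0
    return P
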