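"""Deterministic monthly cohort iteration and an individual-level
Monte-Carlo cross-check.

Cycle structure: month 0 opens with the initial state mix and applies the
screening/treatment cascade (costs and state reassignments), then every
month — including month 0 — applies one natural-history transition at the
cohort's current age.  Life-years accrue 1/12 per live person at the start
of each month (no half-cycle correction); costs and life-years at month t
are discounted by ``(1 + discount_monthly)^-t`` (0.25%/month base case).
The run stops when live mass falls below 1e-9 or the cohort reaches the
life table's closing age (100 in the bundled tables).

Symptomatic presentation: untreated regional or distant cancer is detected
and treated with probability 1 in the month it is occupied (stage-specific
cancer-care cost, move to the treated state, palliative accrual in
subsequent months); untreated local cancer goes undetected until it
progresses.  This policy is configurable via :class:`DetectionPolicy`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cascade import STRATEGIES, CascadeOutcome, Strategy, build_cascade, \
    expected_side_effect_cost
from .life_tables import LifeTable
from .natural_history import (
    HealthState,
    N_STATES,
    build_transition_matrix,
    initial_state_distribution,
)
from .parameters import PERSPECTIVES, ParameterSet

__all__ = [
    "DetectionPolicy",
    "StrategyResult",
    "run_strategy",
    "run_all",
    "microsimulate",
]

_LIVE_EPS = 1e-9
_S = HealthState
_LIVE_SLICE = slice(0, _S.DEAD_CANCER)
_TX_STATES = [_S.LOCAL_TREATED, _S.REGIONAL_TREATED, _S.DISTANT_TREATED]
_PALLIATIVE_STATES = [_S.REGIONAL_TREATED, _S.DISTANT_TREATED]


@dataclass(frozen=True)
class DetectionPolicy:
    """Which untreated cancer stages present symptomatically (prob. 1/month)."""

    local: bool = False
    regional: bool = True
    distant: bool = True

    def pairs(self) -> list[tuple[HealthState, HealthState]]:
        out = []
        if self.local:
            out.append((_S.LOCAL, _S.LOCAL_TREATED))
        if self.regional:
            out.append((_S.REGIONAL, _S.REGIONAL_TREATED))
        if self.distant:
            out.append((_S.DISTANT, _S.DISTANT_TREATED))
        return out


@dataclass(frozen=True)
class StrategyResult:
    """Discounted lifetime cost and life expectancy for one strategy run."""

    strategy: str
    perspective: str
    cost: float
    le_discounted: float
    le_undiscounted: float
    cost_se: float | None = None
    le_se: float | None = None
    trace: np.ndarray | None = None  # (T, N_STATES) start-of-month masses


def _stage_costs(params: ParameterSet, perspective: str) -> dict[HealthState, float]:
    cc = params.unit_costs[perspective].cancer_care
    return {_S.LOCAL: cc.local, _S.REGIONAL: cc.regional, _S.DISTANT: cc.distant}


def run_strategy(
    strategy: Strategy | str,
    params: ParameterSet,
    life_table: LifeTable,
    perspective: str = "societal",
    detection: DetectionPolicy = DetectionPolicy(),
    keep_trace: bool = False,
) -> StrategyResult:
    """Deterministic cohort run of one strategy under one cost perspective."""
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    if life_table.age_min > params.start_age or life_table.age_max < params.start_age:
        raise ValueError("life table does not cover the start age")

    cascade = build_cascade(strategy, params, perspective)
    stage_cost = _stage_costs(params, perspective)
    se_cost = expected_side_effect_cost(params, perspective)
    palliative = params.unit_costs[perspective].cancer_care.palliative_monthly
    v = 1.0 / (1.0 + params.discount_monthly)
    detect_pairs = detection.pairs()

    d = initial_state_distribution(params).mass.copy()
    t_max = (life_table.age_max - params.start_age) * 12
    matrices: dict[int, np.ndarray] = {}

    cost = 0.0
    ly_disc = 0.0
    ly_undisc = 0.0
    trace = [] if keep_trace else None

    for t in range(t_max):
        live = float(d[_LIVE_SLICE].sum())
        if live < _LIVE_EPS:
            break
        if trace is not None:
            trace.append(d.copy())
        disc = v**t
        ly_disc += disc * live / 12.0
        ly_undisc += live / 12.0
        # occupancy costs for women in treated-cancer states this month
        cost += disc * (
            palliative * float(d[_PALLIATIVE_STATES].sum())
            + se_cost * float(d[_TX_STATES].sum())
        )
        if t == 0:
            cost += disc * float(d @ cascade.cost0)
            d = d @ cascade.after
            # prevalent symptomatic cancers (e.g. cryo_all arm, LTFU women)
            for src, dst in detect_pairs:
                cost += disc * stage_cost[src] * float(d[src])
                d[dst] += d[src]
                d[src] = 0.0
        age = int(params.start_age + t // 12)
        P = matrices.get(age)
        if P is None:
            P = matrices[age] = build_transition_matrix(params, life_table, age)
        d = d @ P
        # symptomatic detection of newly entered untreated stages
        for src, dst in detect_pairs:
            cost += disc * stage_cost[src] * float(d[src])
            d[dst] += d[src]
            d[src] = 0.0

    return StrategyResult(
        strategy=strategy.name,
        perspective=perspective,
        cost=cost,
        le_discounted=ly_disc,
        le_undiscounted=ly_undisc,
        trace=np.array(trace) if trace is not None else None,
    )


def run_all(
    params: ParameterSet,
    life_table: LifeTable,
    strategies: Iterable[Strategy | str] | None = None,
    perspectives: Sequence[str] = PERSPECTIVES,
    detection: DetectionPolicy = DetectionPolicy(),
) -> pd.DataFrame:
    """All strategies x perspectives; one row per strategy, sorted by
    societal lifetime cost ascending (life expectancy is perspective-free)."""
    if strategies is None:
        strategies = list(STRATEGIES.values())
    rows = []
    for strat in strategies:
        row: dict[str, object] = {}
        for persp in perspectives:
            res = run_strategy(strat, params, life_table, persp, detection)
            row["strategy"] = res.strategy
            row[f"cost_{persp}"] = res.cost
            row["le_discounted"] = res.le_discounted
            row["le_undiscounted"] = res.le_undiscounted
        rows.append(row)
    df = pd.DataFrame(rows)
    sort_key = "cost_societal" if "cost_societal" in df.columns else df.columns[1]
    return df.sort_values(sort_key, ignore_index=True)


# ---------------------------------------------------------------------------
# individual-level Monte-Carlo oracle


def microsimulate(
    strategy: Strategy | str,
    params: ParameterSet,
    life_table: LifeTable,
    perspective: str = "societal",
    n_individuals: int = 10_000,
    seed: int = 0,
    detection: DetectionPolicy = DetectionPolicy(),
) -> StrategyResult:
    """Sample ``n_individuals`` trajectories through the identical cascade
    and transition logic; returns means with Monte-Carlo standard errors.

    Side-effect events, treatment modality (cryotherapy vs LEEP) and every
    transition are drawn individually, so means converge to the cohort
    model's expectations.
    """
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    rng = np.random.default_rng(seed)
    n = int(n_individuals)
    if n < 1:
        raise ValueError("n_individuals must be >= 1")

    costs_u = params.unit_costs[perspective]
    stage_cost = _stage_costs(params, perspective)
    palliative = costs_u.cancer_care.palliative_monthly
    v = 1.0 / (1.0 + params.discount_monthly)
    cascade = build_cascade(strategy, params, perspective)
    detect_pairs = detection.pairs()

    init = initial_state_distribution(params).mass
    state = rng.choice(N_STATES, size=n, p=init / init.sum()).astype(np.int64)
    cost = np.zeros(n)
    ly_disc = np.zeros(n)
    ly_undisc = np.zeros(n)

    def draw_side_effect_costs(idx: np.ndarray) -> None:
        """One month of side-effect risk for individuals ``idx`` (cost added
        undiscounted; caller scales)."""
        if idx.size == 0:
            return
        hit = idx[rng.random(idx.size) < params.side_effect_monthly]
        if hit.size == 0:
            return
        major = rng.random(hit.size) < params.p_side_effect_major
        _se_scratch[hit] = np.where(
            major, costs_u.side_effects.major, costs_u.side_effects.minor
        )

    _se_scratch = np.zeros(n)

    t_max = (life_table.age_max - params.start_age) * 12
    matrices: dict[int, np.ndarray] = {}

    for t in range(t_max):
        alive = state < _S.DEAD_CANCER
        if not alive.any():
            break
        disc = v**t
        ly_disc[alive] += disc / 12.0
        ly_undisc[alive] += 1.0 / 12.0
        # occupancy costs in treated-cancer states
        in_tx = (state >= _S.LOCAL_TREATED) & (state <= _S.DISTANT_TREATED)
        in_pall = (state == _S.REGIONAL_TREATED) | (state == _S.DISTANT_TREATED)
        cost[in_pall] += disc * palliative
        _se_scratch[:] = 0.0
        draw_side_effect_costs(np.flatnonzero(in_tx))
        cost += disc * _se_scratch

        if t == 0:
            state, month0_cost = _sample_cascade(
                strategy, params, cascade, costs_u, state, rng
            )
            cost += disc * month0_cost
            for src, dst in detect_pairs:
                sel = state == src
                cost[sel] += disc * stage_cost[src]
                state[sel] = dst

        age = int(params.start_age + t // 12)
        P = matrices.get(age)
        if P is None:
            P = matrices[age] = build_transition_matrix(params, life_table, age)
            matrices[age + 1000] = np.cumsum(P, axis=1)  # cached cumulative rows
        cumP = matrices[age + 1000]
        idx = np.flatnonzero(alive)
        u = rng.random(idx.size)
        rows = cumP[state[idx]]
        state[idx] = (u[:, None] < rows).argmax(axis=1)
        for src, dst in detect_pairs:
            sel = state == src
            cost[sel] += disc * stage_cost[src]
            state[sel] = dst

    return StrategyResult(
        strategy=strategy.name,
        perspective=perspective,
        cost=float(cost.mean()),
        le_discounted=float(ly_disc.mean()),
        le_undiscounted=float(ly_undisc.mean()),
        cost_se=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        le_se=float(ly_disc.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    )


def _sample_cascade(
    strategy: Strategy,
    params: ParameterSet,
    cascade: CascadeOutcome,
    costs_u,
    state: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample month-0 cascade events per individual; returns (new_state, cost)."""
    from .cascade import _SCREEN_COST_KEY, cascade_completion_probability, classify

    n = state.size
    month0 = np.zeros(n)
    new_state = state.copy()
    eff = params.treatment_effectiveness
    p_cryo = params.p_cryo_given_treatment

    def lesion_treatment_costs(idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        cryo = rng.random(idx.size) < p_cryo
        month0[idx] += np.where(
            cryo, costs_u.treatment.cryotherapy, costs_u.treatment.leep
        )
        hit = idx[rng.random(idx.size) < params.side_effect_monthly]
        if hit.size:
            major = rng.random(hit.size) < params.p_side_effect_major
            month0[hit] += np.where(
                major, costs_u.side_effects.major, costs_u.side_effects.minor
            )

    if strategy.name == "cryo_all":
        month0 += costs_u.treatment.cryotherapy
        hit = np.flatnonzero(rng.random(n) < params.side_effect_monthly)
        if hit.size:
            major = rng.random(hit.size) < params.p_side_effect_major
            month0[hit] += np.where(
                major, costs_u.side_effects.major, costs_u.side_effects.minor
            )
        hsil = np.flatnonzero(state == _S.HSIL)
        success = hsil[rng.random(hsil.size) < eff]
        new_state[success] = _S.NORMAL
        return new_state, month0

    month0 += sum(
        getattr(costs_u.screening, _SCREEN_COST_KEY[t]) for t in strategy.tests
    )
    completion = cascade_completion_probability(strategy, params)
    p_pos = np.array(
        [classify(strategy.combined_test, _S(s), params) for s in range(N_STATES)]
    )
    reach = (rng.random(n) < p_pos[state]) & (rng.random(n) < completion)

    lesion = reach & (state <= _S.HSIL)
    lesion_treatment_costs(np.flatnonzero(lesion))
    hsil_treated = np.flatnonzero(lesion & (state == _S.HSIL))
    success = hsil_treated[rng.random(hsil_treated.size) < eff]
    new_state[success] = _S.NORMAL

    for src in (_S.LOCAL, _S.REGIONAL, _S.DISTANT):
        sel = reach & (state == src)
        month0[sel] += costs_u.treatment.colposcopy + _stage_costs(
            params, cascade.perspective
        )[src]
        new_state[sel] = {
            _S.LOCAL: _S.LOCAL_TREATED,
            _S.REGIONAL: _S.REGIONAL_TREATED,
            _S.DISTANT: _S.DISTANT_TREATED,
        }[src]
    return new_state, month0
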