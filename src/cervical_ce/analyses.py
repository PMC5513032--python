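"""Analytic products over the cohort engine: the base-case/CD4 scenario
table, one-way (tornado) sensitivity analyses of the two incremental cost
comparisons, the single-visit conversion scenario for Pap and HPV, and the
loss-to-follow-up threshold at which a two-visit HPV programme costs the
same as single-visit VIA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cascade import STRATEGIES
from .engine import DetectionPolicy, run_strategy
from .life_tables import LifeTable
from .parameters import ParameterSet, apply_scenario, enumerate_oneway

__all__ = [
    "TornadoEntry",
    "base_case_and_scenarios",
    "tornado",
    "single_visit_scenario",
    "ltfu_threshold",
]

COMPARISONS = {
    "VIA_minus_cryo": ("VIA", "cryo_all"),
    "HPV_minus_VIA": ("HPV", "VIA"),
}


@dataclass(frozen=True)
class TornadoEntry:
    """Incremental cost of one comparison at a parameter's min and max."""

    parameter_name: str
    delta_low: float
    delta_high: float
    comparison: str

    @property
    def span(self) -> float:
        return abs(self.delta_high - self.delta_low)


def base_case_and_scenarios(
    params: ParameterSet,
    life_table: LifeTable,
    detection: DetectionPolicy = DetectionPolicy(),
) -> pd.DataFrame:
    """Lifetime costs (both perspectives) and life expectancy for all seven
    strategies under the base case and the two CD4 scenarios.

    Rows are ordered by societal cost ascending within each scenario.
    """
    frames = []
    for scenario in ("base", "cd4_low", "cd4_high"):
        p = apply_scenario(params, scenario)
        rows = []
        for name in STRATEGIES:
            soc = run_strategy(name, p, life_table, "societal", detection)
            cli = run_strategy(name, p, life_table, "clinic", detection)
            rows.append(
                {
                    "scenario": scenario,
                    "strategy": name,
                    "cost_societal": soc.cost,
                    "cost_clinic": cli.cost,
                    "le_discounted": soc.le_discounted,
                    "le_undiscounted": soc.le_undiscounted,
                }
            )
        frames.append(
            pd.DataFrame(rows).sort_values("cost_societal", ignore_index=True)
        )
    return pd.concat(frames, ignore_index=True)


def _incremental_cost(
    comparison: str,
    params: ParameterSet,
    life_table: LifeTable,
    perspective: str,
    detection: DetectionPolicy,
) -> float:
    a, b = COMPARISONS[comparison]
    ca = run_strategy(a, params, life_table, perspective, detection).cost
    cb = run_strategy(b, params, life_table, perspective, detection).cost
    return ca - cb


def tornado(
    comparison: str,
    params: ParameterSet,
    life_table: LifeTable,
    perspective: str = "societal",
    detection: DetectionPolicy = DetectionPolicy(),
) -> tuple[float, list[TornadoEntry]]:
    """One-way sensitivity of an incremental cost over every ranged parameter.

    Returns the base-case incremental cost and the entries sorted by bar
    width (|delta_high - delta_low|) descending, ties broken by table row
    order for determinism.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    base_delta = _incremental_cost(comparison, params, life_table, perspective, detection)
    entries = []
    for order, (name, low, high) in enumerate(enumerate_oneway(params)):
        d_lo = _incremental_cost(comparison, low, life_table, perspective, detection)
        d_hi = _incremental_cost(comparison, high, life_table, perspective, detection)
        entries.append((order, TornadoEntry(name, d_lo, d_hi, comparison)))
    entries.sort(key=lambda pair: (-pair[1].span, pair[0]))
    return base_delta, [e for _, e in entries]


def single_visit_scenario(
    params: ParameterSet,
    life_table: LifeTable,
    perspective: str = "societal",
    detection: DetectionPolicy = DetectionPolicy(),
) -> pd.DataFrame:
    """Rerun Pap and HPV with screening and treatment compressed into one
    visit (no loss to follow-up), alongside their multi-visit base values."""
    rows = []
    for name in ("Pap", "HPV"):
        strat = STRATEGIES[name]
        base = run_strategy(strat, params, life_table, perspective, detection)
        single = run_strategy(
            strat.with_single_visit(), params, life_table, perspective, detection
        )
        rows.append(
            {
                "strategy": name,
                "cost_multivisit": base.cost,
                "cost_single_visit": single.cost,
                "le_multivisit": base.le_discounted,
                "le_single_visit": single.le_discounted,
            }
        )
    return pd.DataFrame(rows)


def ltfu_threshold(
    params: ParameterSet,
    life_table: LifeTable,
    perspective: str = "societal",
    detection: DetectionPolicy = DetectionPolicy(),
    cost_tol: float = 0.01,
) -> float:
    """Two-visit LTFU at which HPV's lifetime cost equals single-visit VIA's.

    Only ``ltfu_2visit`` (HPV's cascade completion) is varied; VIA is a
    single-visit strategy and does not depend on it.  Solved by Brent root
    finding on [0, base LTFU] to within ``cost_tol`` dollars; raises
    ``ValueError`` if the cost difference does not change sign there.
    """
    via_cost = run_strategy("VIA", params, life_table, perspective, detection).cost

    def diff(ltfu: float) -> float:
        p = params.replace(ltfu_2visit=float(ltfu))
        return run_strategy("HPV", p, life_table, perspective, detection).cost - via_cost

    lo, hi = 0.0, params.ltfu_2visit
    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            "no threshold in range: HPV-VIA cost difference does not change "
            f"sign on [0, {hi}] (f(0)={f_lo:.2f}, f({hi})={f_hi:.2f})"
        )
    root = brentq(diff, lo, hi, xtol=1e-6)
    if abs(diff(root)) > cost_tol:
        raise RuntimeError("root finder did not reach cost tolerance")
    return float(root)
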