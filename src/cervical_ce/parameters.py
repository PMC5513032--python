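"""Model parameters: loading, validation, CD4 scenarios, one-way ranges.

The parameter document is a flat YAML file with one key per model quantity:
monthly transition probabilities of the cervical-lesion/cancer natural
history, screening-test performance, loss to follow-up by visit count, the
standardized mortality ratio for treated HIV-infected women, and unit costs
(2014 USD) under societal and clinic perspectives.  The bundled files
``base_case.yaml``, ``cd4_low.yaml`` and ``cd4_high.yaml`` hold the base
case (CD4 200-500 cells/mL) and the two CD4 scenario parameter sets.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "TestPerformance",
    "CostSet",
    "ParameterSet",
    "OneWayEntry",
    "load_parameters",
    "dump_parameters",
    "bundled_parameter_path",
    "apply_scenario",
    "enumerate_oneway",
    "PERSPECTIVES",
    "SCENARIOS",
]

PERSPECTIVES = ("societal", "clinic")
SCENARIOS = ("base", "cd4_low", "cd4_high")

#: Tolerance on printed probability vectors that should sum to one.  The
#: CD4<=200 scenario prints 0.832/0.169 (sum 1.001); values are stored as
#: printed and renormalized where the vector is consumed.
_SIMPLEX_TOL = 2e-3

Probability = Field(ge=0.0, le=1.0)


class TestPerformance(BaseModel):
    """Sensitivity/specificity of one screening test against CIN2+."""

    model_config = ConfigDict(frozen=True)

    sensitivity: float = Probability
    specificity: float = Probability


class _ScreeningCosts(BaseModel):
    model_config = ConfigDict(frozen=True)
    pap: float = Field(ge=0)
    via: float = Field(ge=0)
    hpv: float = Field(ge=0)


class _TreatmentCosts(BaseModel):
    model_config = ConfigDict(frozen=True)
    cryotherapy: float = Field(ge=0)
    colposcopy: float = Field(ge=0)
    leep: float = Field(ge=0)


class _SideEffectCosts(BaseModel):
    model_config = ConfigDict(frozen=True)
    major: float = Field(ge=0)
    minor: float = Field(ge=0)


class _CancerCareCosts(BaseModel):
    model_config = ConfigDict(frozen=True)
    local: float = Field(ge=0)
    regional: float = Field(ge=0)
    distant: float = Field(ge=0)
    palliative_monthly: float = Field(ge=0)


class CostSet(BaseModel):
    """Unit costs (2014 USD) for one accounting perspective."""

    model_config = ConfigDict(frozen=True)

    screening: _ScreeningCosts
    treatment: _TreatmentCosts
    side_effects: _SideEffectCosts
    cancer_care: _CancerCareCosts


class _SplitDiseased(BaseModel):
    model_config = ConfigDict(frozen=True)
    lsil: float = Probability
    hsil: float = Probability
    local: float = Probability
    regional: float = Probability
    distant: float = Probability

    @property
    def as_tuple(self) -> tuple[float, ...]:
        return (self.lsil, self.hsil, self.local, self.regional, self.distant)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "_SplitDiseased":
        if abs(sum(self.as_tuple) - 1.0) > _SIMPLEX_TOL:
            raise ValueError("split_diseased must sum to 1")
        return self


class _SplitNondiseased(BaseModel):
    model_config = ConfigDict(frozen=True)
    normal: float = Probability
    lsil: float = Probability

    @property
    def as_tuple(self) -> tuple[float, float]:
        return (self.normal, self.lsil)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "_SplitNondiseased":
        if abs(self.normal + self.lsil - 1.0) > _SIMPLEX_TOL:
            raise ValueError("split_nondiseased must sum to 1")
        return self


class _CancerMortality(BaseModel):
    model_config = ConfigDict(frozen=True)
    local: float = Probability
    regional: float = Probability
    distant: float = Probability


class _Progression(BaseModel):
    model_config = ConfigDict(frozen=True)
    normal_lsil: float = Probability
    lsil_hsil: float = Probability
    hsil_local: float = Probability
    local_regional: float = Probability
    regional_distant: float = Probability


class _Regression(BaseModel):
    model_config = ConfigDict(frozen=True)
    lsil_normal: float = Probability
    hsil_lsil: float = Probability
    hsil_normal: float = Probability


class ParameterSet(BaseModel):
    """Complete, validated parameter set for one model run.

    ``ranges`` maps dotted parameter paths to (min, max) for the one-way
    sensitivity analysis, in table row order.  ``scenarios`` holds the CD4
    overrides as partial documents keyed ``cd4_low`` / ``cd4_high``.
    """

    model_config = ConfigDict(frozen=True)

    start_age: int = Field(ge=15, le=99)
    prev_disease: float = Probability
    split_diseased: _SplitDiseased
    split_nondiseased: _SplitNondiseased
    ltfu_2visit: float = Probability
    ltfu_3visit: float = Probability
    smr: float = Field(gt=0)
    cancer_mortality_monthly: _CancerMortality
    progression_monthly: _Progression
    regression_monthly: _Regression
    treatment_effectiveness: float = Probability
    cure_monthly: float = Probability
    side_effect_monthly: float = Probability
    p_side_effect_major: float = Probability
    p_cryo_given_treatment: float = Probability
    discount_monthly: float = Field(ge=0)
    test_performance: dict[str, TestPerformance]
    unit_costs: dict[str, CostSet]
    ranges: dict[str, tuple[float, float]] = Field(default_factory=dict)
    scenarios: dict[str, dict] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ParameterSet":
        for p in PERSPECTIVES:
            if p not in self.unit_costs:
                raise ValueError(f"unit_costs missing perspective {p!r}")
        soc, cli = self.unit_costs["societal"], self.unit_costs["clinic"]
        for block in ("screening", "treatment", "side_effects", "cancer_care"):
            s_block = getattr(soc, block)
            c_block = getattr(cli, block)
            for item in type(s_block).model_fields:
                if getattr(s_block, item) < getattr(c_block, item) - 1e-9:
                    raise ValueError(
                        f"societal cost {block}.{item} below clinic cost"
                    )
        for name, (lo, hi) in self.ranges.items():
            if name.startswith("cost."):
                base = _get_path(self.unit_costs["societal"], name[len("cost."):])
            else:
                base = _get_path(self, name)
            if not (lo - 1e-9 <= base <= hi + 1e-9):
                raise ValueError(f"range for {name!r} does not bracket base value")
        return self

    # -- convenience -------------------------------------------------------
    def replace(self, **updates) -> "ParameterSet":
        """Return a copy with top-level fields replaced."""
        doc = self.model_dump()
        doc.update(updates)
        return ParameterSet.model_validate(doc)


class OneWayEntry(NamedTuple):
    name: str
    low: ParameterSet
    high: ParameterSet


# ---------------------------------------------------------------------------
# dotted-path access on plain dict documents

def _get_path(obj, path: str):
    node = obj
    for part in path.split("."):
        node = node[part] if isinstance(node, Mapping) else getattr(node, part)
    return node


def _set_path(doc: dict, path: str, value) -> None:
    parts = path.split(".")
    node = doc
    for part in parts[:-1]:
        node = node[part]
    node[parts[-1]] = value


# ---------------------------------------------------------------------------
# loading / dumping

def bundled_parameter_path(name: str = "base_case") -> Path:
    """Path to a bundled parameter file (``base_case``, ``cd4_low``, ``cd4_high``)."""
    ref = resources.files("cervical_ce").joinpath("data", f"{name}.yaml")
    return Path(str(ref))


def load_parameters(source: str | Path | Mapping | None = None) -> ParameterSet:
    """Load and validate a parameter document.

    ``source`` may be a path to a YAML file, an already-parsed mapping, or
    ``None`` for the bundled base case.
    """
    if source is None:
        source = bundled_parameter_path("base_case")
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    return ParameterSet.model_validate(doc)


def dump_parameters(params: ParameterSet, path: str | Path | None = None) -> str:
    """Serialize a ParameterSet back to the YAML document format."""
    doc = params.model_dump(mode="json")
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# CD4 scenarios

def apply_scenario(params: ParameterSet, scenario: str) -> ParameterSet:
    """Return a copy of ``params`` with one CD4 scenario's overrides applied.

    ``base`` returns an identical copy.  Cells the scenario table leaves
    blank keep the base-case value.  Never mutates its input.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if scenario == "base":
        return params.model_copy(deep=True)
    overrides = params.scenarios.get(scenario)
    if overrides is None:
        raise ValueError(f"parameter set carries no overrides for {scenario!r}")
    doc = params.model_dump()
    for path, value in _flatten(overrides):
        _set_path(doc, path, value)
        # one-way ranges describe the base case; an overridden cell's range
        # no longer brackets its value and is not enumerated under a scenario
        doc["ranges"].pop(path, None)
    return ParameterSet.model_validate(doc)


def _flatten(tree: Mapping, prefix: str = "") -> Iterator[tuple[str, object]]:
    for key, val in tree.items():
        path = f"{prefix}{key}"
        if isinstance(val, Mapping):
            yield from _flatten(val, prefix=f"{path}.")
        else:
            yield path, val


# ---------------------------------------------------------------------------
# one-way sensitivity enumeration

def _perturbed(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """A copy of ``params`` with one ranged parameter set to ``value``.

    Simplex components are renormalized so their vector still sums to one:
    the complement of the varied component is scaled proportionally
    (``split_nondiseased`` is a pair, so its other entry is set to 1-value).
    Cost entries vary jointly across perspectives: the clinic value is scaled
    by the same ratio to its base as the societal value.
    """
    doc = params.model_dump()
    if name.startswith("split_nondiseased."):
        comp = name.split(".")[1]
        other = "lsil" if comp == "normal" else "normal"
        doc["split_nondiseased"][comp] = value
        doc["split_nondiseased"][other] = 1.0 - value
    elif name.startswith("split_diseased."):
        comp = name.split(".")[1]
        vec = doc["split_diseased"]
        rest = [k for k in vec if k != comp]
        rest_sum = sum(vec[k] for k in rest)
        target_rest = 1.0 - value
        scale = target_rest / rest_sum if rest_sum > 0 else 0.0
        for k in rest:
            vec[k] = vec[k] * scale
        if rest_sum == 0 and target_rest > 0:
            # degenerate base (all mass in the varied component): park the
            # remainder in hsil unless hsil itself is varied
            sink = "hsil" if comp != "hsil" else "lsil"
            vec[sink] = target_rest
        vec[comp] = value
    elif name.startswith("cost."):
        path = name[len("cost."):]
        base_soc = _get_path(doc["unit_costs"]["societal"], path)
        base_cli = _get_path(doc["unit_costs"]["clinic"], path)
        ratio = value / base_soc if base_soc > 0 else 1.0
        _set_path(doc["unit_costs"]["societal"], path, value)
        _set_path(doc["unit_costs"]["clinic"], path, base_cli * ratio)
    elif name == "start_age":
        doc["start_age"] = int(round(value))
    else:
        _set_path(doc, name, value)
    _prune_stale_ranges(doc)
    return ParameterSet.model_validate(doc)


def _prune_stale_ranges(doc: dict) -> None:
    """Drop range entries no longer bracketing their value (e.g. simplex
    complements rescaled by a one-way perturbation of a sibling)."""
    for rname in list(doc.get("ranges", {})):
        lo, hi = doc["ranges"][rname]
        if rname.startswith("cost."):
            cur = _get_path(doc["unit_costs"]["societal"], rname[len("cost."):])
        else:
            cur = _get_path(doc, rname)
        if not (lo - 1e-9 <= cur <= hi + 1e-9):
            del doc["ranges"][rname]


def enumerate_oneway(params: ParameterSet) -> list[OneWayEntry]:
    """One (name, low ParameterSet, high ParameterSet) per ranged parameter.

    Entries appear in the order of ``params.ranges`` (table row order); each
    low/high set differs from ``params`` in exactly that parameter (costs
    move jointly across perspectives; simplex complements rebalance).
    """
    out = []
    for name, (lo, hi) in params.ranges.items():
        out.append(OneWayEntry(name, _perturbed(params, name, lo), _perturbed(params, name, hi)))
    return out
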