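import numpy as np
import pytest

from cervical_ce import LifeTable, kenya_female_2011_synthetic, load_parameters


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def life_table():
    return kenya_female_2011_synthetic()


def constant_q_table(q: float, age_min: int = 38, age_max: int = 100) -> LifeTable:
    """Life table with the same annual death probability at every age."""
    ages = np.arange(age_min, age_max + 1)
    qs = np.full(ages.size, q, dtype=float)
    qs[-1] = 1.0
    return LifeTable(ages, qs)


def disease_free(params, **extra):
    """Parameters with no prevalent disease and no disease dynamics, so the
    cohort reduces to a pure life-table population."""
    updates = dict(
        prev_disease=0.0,
        progression_monthly={
            "normal_lsil": 0.0,
            "lsil_hsil": 0.0,
            "hsil_local": 0.0,
            "local_regional": 0.0,
            "regional_distant": 0.0,
        },
        ranges={},
    )
    updates.update(extra)
    return params.replace(**updates)


def zero_costs(params):
    """Parameters with every unit cost set to zero (health side untouched)."""
    doc = params.model_dump()
    for persp in doc["unit_costs"]:
        for block in doc["unit_costs"][persp].values():
            for item in block:
                block[item] = 0.0
    doc["ranges"] = {k: v for k, v in doc["ranges"].items() if not k.startswith("cost.")}
    from cervical_ce import ParameterSet

    return ParameterSet.model_validate(doc)
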