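"""Age-specific background mortality for the cohort model.

A :class:`LifeTable` maps integer age to the annual probability of death
``q(age)`` for HIV-negative females; the standardized mortality ratio (SMR)
for treated HIV-infected women is applied on the hazard scale when annual
probabilities are converted to monthly cycle probabilities.

The reference schedule the model was built around is the WHO age-specific
all-cause mortality table for Kenyan females in 2011.  That table is not
redistributed here; :func:`read_life_table` ingests any two-column CSV
export of it (see ``data/life_table_format.md``), and
:func:`kenya_female_2011_synthetic` provides a deterministic Gompertz-Makeham
stand-in calibrated to the same era's summary indicators for testing and
offline runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "read_life_table",
    "synthetic_life_table",
    "kenya_female_2011_synthetic",
    "monthly_background_mortality",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``q_annual`` indexed by integer ``ages``.

    Ages are strictly increasing and the final age closes the table with
    ``q = 1`` so no cohort mass survives past it.
    """

    ages: np.ndarray
    q_annual: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)
        if ages.ndim != 1 or ages.shape != q.shape or ages.size < 2:
            raise ValueError("ages and q_annual must be matching 1-d arrays")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("annual death probabilities must lie in [0, 1]")
        if q[-1] != 1.0:
            raise ValueError("life table must close with q = 1 at the final age")

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def q(self, age_years: float) -> float:
        """Annual death probability at ``floor(age_years)``.

        Raises ``ValueError`` for ages outside the table.
        """
        age = int(np.floor(age_years))
        if age < self.age_min or age > self.age_max:
            raise ValueError(
                f"age {age} outside life table range [{self.age_min}, {self.age_max}]"
            )
        idx = np.searchsorted(self.ages, age)
        if idx >= self.ages.size or self.ages[idx] != age:
            raise ValueError(f"age {age} missing from life table")
        return float(self.q_annual[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q_annual": self.q_annual})


def read_life_table(
    source: str | Path,
    age_col: str = "age",
    q_col: str = "q_annual",
) -> LifeTable:
    """Read a life table from a headered CSV with age and annual-q columns."""
    df = pd.read_csv(source)
    for col in (age_col, q_col):
        if col not in df.columns:
            raise ValueError(f"life table CSV lacks column {col!r}")
    return LifeTable(df[age_col].to_numpy(), df[q_col].to_numpy())


def synthetic_life_table(
    makeham_a: float,
    makeham_b: float,
    makeham_c: float,
    age_min: int,
    age_max: int,
) -> LifeTable:
    """Deterministic Gompertz-Makeham life table.

    The annual hazard at age ``x`` is ``a + b * c**x`` (Makeham constant
    plus exponential senescence), so ``q(x) = 1 - exp(-(a + b*c**x))``,
    clamped to [0, 1]; the table closes with ``q(age_max) = 1``.
    """
    if makeham_a < 0 or makeham_b < 0:
        raise ValueError("Makeham a and b must be non-negative")
    if makeham_c <= 1:
        raise ValueError("Gompertz growth c must exceed 1")
    if age_min >= age_max:
        raise ValueError("age_min must be below age_max")
    ages = np.arange(age_min, age_max + 1)
    hazard = makeham_a + makeham_b * np.power(makeham_c, ages.astype(float))
    q = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    q[-1] = 1.0
    return LifeTable(ages, q)


def kenya_female_2011_synthetic() -> LifeTable:
    """Synthetic stand-in for the WHO Kenya 2011 female life table.

    Gompertz-Makeham schedule over ages 15-100 with a flat young-adult
    hazard component (a = 0.004/yr) reflecting the HIV-era excess in adult
    female mortality, and senescence b = 3e-5, c = 1.10.  Calibrated to the
    era's summary indicators (probability of death between 15 and 60 of
    roughly 0.24), not to any model output.  Synthetic: use a real WHO
    export via :func:`read_life_table` for country-accurate absolute
    numbers.
    """
    return synthetic_life_table(0.004, 3e-5, 1.10, 15, 100)


def monthly_background_mortality(lt: LifeTable, age_years: float, smr: float) -> float:
    """Monthly background death probability at ``age_years`` under an SMR.

    The SMR multiplies the hazard (log-survival), keeping the result a
    probability for any SMR:  ``q_m = 1 - (1 - q_annual)**(smr / 12)``.
    """
    if smr <= 0:
        raise ValueError("smr must be positive")
    q_a = lt.q(age_years)
    if q_a >= 1.0:
        return 1.0
    return 1.0 - (1.0 - q_a) ** (smr / 12.0)
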