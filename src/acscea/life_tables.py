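"""Background mortality: life tables, rate/probability conversions, hazards.

Age-specific background mortality enters the model as annual mortality
rates (per person-year).  Rates convert to one-cycle probabilities via
``p = 1 - exp(-r t)``.  Hazard ratios act multiplicatively on the rate
scale *before* conversion; relative risks act on the probability scale
*after* conversion (clamped to 1).

National life tables are read from a two-column CSV.  When none is
supplied, a synthetic table is generated from a Gompertz-Makeham hazard
``r(a) = alpha * exp(beta_g * (a - age_min)) + gamma_m``, calibrated so the
remaining life expectancy at age 62 is plausible for the modelled
population (about 18-22 years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class LifeTableError(ValueError):
    """Malformed life table or out-of-domain query."""


def rate_to_prob(r: float, t: float = 1.0) -> float:
    """Probability of an event within ``t`` years at constant rate ``r``."""
    if r < 0:
        raise LifeTableError(f"rate must be >= 0 (got {r})")
    if t <= 0:
        raise LifeTableError(f"time must be > 0 (got {t})")
    return -math.expm1(-r * t)


def prob_to_rate(p: float, t: float = 1.0) -> float:
    """Constant annual rate implied by probability ``p`` over ``t`` years."""
    if not 0.0 <= p < 1.0:
        raise LifeTableError(f"probability must be in [0,1) (got {p})")
    if t <= 0:
        raise LifeTableError(f"time must be > 0 (got {t})")
    return -math.log1p(-p) / t

def adjust_rate_by_hr(r: float, hr: float) -> float:
    """Apply a hazard ratio on the rate scale."""
    if r < 0:
        raise LifeTableError(f"rate must be >= 0 (got {r})")
    if hr <= 0:
        raise LifeTableError(f"hazard ratio must be > 0 (got {hr})")
    return r * hr


def apply_rr(p: float, rr: float) -> float:
    """Apply a relative risk on the probability scale, clamped to 1."""
    if not 0.0 <= p <= 1.0:
        raise LifeTableError(f"probability must be in [0,1] (got {p})")
    if rr <= 0:
        raise LifeTableError(f"relative risk must be > 0 (got {rr})")
    return min(p * rr, 1.0)


@dataclass(frozen=True)
class MakehamParams:
    """Gompertz-Makeham hazard parameters (all per year)."""

    # Defaults calibrated so that remaining life expectancy at age 62 is
    # ~20 years (plausible for a sex-combined national table at that age).
    alpha: float = 0.0128  # Gompertz level at the table's first age
    beta_g: float = 0.085  # Gompertz slope per year of age
    gamma_m: float = 0.001 # age-independent Makeham background

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise LifeTableError("alpha must be > 0")
        if self.beta_g < 0:
            raise LifeTableError("beta_g must be >= 0")
        if self.gamma_m < 0:
            raise LifeTableError("gamma_m must be >= 0")


DEFAULT_MAKEHAM = MakehamParams()


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual background mortality rates.

    Ages are contiguous integer years.  Queries above the last tabulated
    age hold the final rate constant (a conservative tail for the < 1% of
    cohort mass that can survive past the table); queries below the first
    age are rejected.
    """

    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if ages.ndim != 1 or rates.shape != ages.shape or ages.size == 0:
            raise LifeTableError("ages and rates must be equal-length 1-D")
        if ages.size > 1 and not np.all(np.diff(ages) == 1):
            raise LifeTableError(
                "ages must be contiguous with step 1 (non-contiguous tables "
                "are rejected rather than interpolated)")
        if np.any(rates < 0):
            raise LifeTableError("mortality rates must be >= 0")

    def rate_at(self, age: int) -> float:
        if age < self.ages[0]:
            raise LifeTableError(
                f"age {age} below table start {self.ages[0]}")
        idx = min(int(age) - int(self.ages[0]), self.ages.size - 1)
        return float(self.rates[idx])

    def death_prob(self, age: int) -> float:
        return rate_to_prob(self.rate_at(age), 1.0)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        required = {"age", "mortality_rate"}
        if not required <= set(df.columns):
            raise LifeTableError(
                f"life-table CSV must have columns {sorted(required)}")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["mortality_rate"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "mortality_rate": self.rates}).to_csv(
            path, index=False)


def background_death_prob(lt: LifeTable, age: int, hr_excess: float = 1.0,
                          rr_any: float = 1.0) -> float:
    """Annual background death probability at ``age`` after adjustment.

    The excess-mortality hazard ratio multiplies the life-table rate; the
    result converts to a probability, to which the all-cause relative risk
    (1 for the comparator arm) applies.
    """
    r = adjust_rate_by_hr(lt.rate_at(age), hr_excess)
    return apply_rr(rate_to_prob(r, 1.0), rr_any)


def gen_synthetic_life_table(params: MakehamParams = DEFAULT_MAKEHAM,
                             age_min: int = 62,
                             age_max: int = 100) -> LifeTable:
    """Deterministic Gompertz-Makeham life table over ``[age_min, age_max]``."""
    if age_min >= age_max:
        raise LifeTableError("age_min must be < age_max")
    ages = np.arange(age_min, age_max + 1)
    rates = params.alpha * np.exp(params.beta_g * (ages - age_min)) + params.gamma_m
    return LifeTable(ages, rates)


def life_expectancy(lt: LifeTable, age: int) -> float:
    """Undiscounted remaining life expectancy at ``age`` (years).

    Survivorship is built from annual death probabilities and summed with
    trapezoidal (mid-year) credit, truncating at the table's last age.
    """
    if age < lt.ages[0] or age > lt.ages[-1]:
        raise LifeTableError(f"age {age} outside table range")
    surv = 1.0
    total = 0.0
    for a in range(int(age), int(lt.ages[-1])):
        nxt = surv * (1.0 - lt.death_prob(a))
        total += 0.5 * (surv + nxt)
        surv = nxt
    return total
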