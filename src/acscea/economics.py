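"""Discounted costs, life-years, QALYs, and incremental cost-effectiveness.

Costs and outcomes are discounted at the configured annual rates with
mid-cycle timing by default, applied to half-cycle-corrected state-time.
Under this convention the lifetime drug cost is exactly the annual price
times discounted life-years, the identity the reporting tables rely on.

Cost bookkeeping:

* drug costs accrue to all living state-time (statin in both arms,
  ezetimibe only in the add-on arm);
* ACS management costs accrue to the no-event state (first-year price in
  cycle 1, maintenance price thereafter);
* event costs use a one-cycle tunnel: the first-year price attaches to the
  new-event inflow in its inflow cycle, the maintenance price to residence
  time after the entry cycle;
* direct non-medical costs accrue once to the full cohort in cycle 1 and
  then per living state-time; they count only under the societal
  perspective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .engine import (DEATH, MI, NO_EVENT, STROKE, ArmLabel, CohortTrace,
                     half_cycle_occupancy, run_cohort)
from .life_tables import LifeTable
from .params import AnalysisSettings, ModelParameters, ParameterValidationError

PERSPECTIVES = ("societal", "provider")

_DNM_CATEGORIES = ("dnm_y1", "dnm_y2plus")


class EconomicsError(ValueError):
    pass


@dataclass(frozen=True)
class CostLedger:
    """Discounted lifetime cost (THB) by category for one strategy."""

    drug_statin: float = 0.0
    drug_ez: float = 0.0
    acs_y1: float = 0.0
    acs_y2plus: float = 0.0
    mi_y1: float = 0.0
    mi_y2plus: float = 0.0
    stroke_y1: float = 0.0
    stroke_y2plus: float = 0.0
    dnm_y1: float = 0.0
    dnm_y2plus: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise EconomicsError(f"negative cost category {f.name}")

    @property
    def direct_medical(self) -> float:
        return (self.drug_statin + self.drug_ez + self.acs_y1 + self.acs_y2plus
                + self.mi_y1 + self.mi_y2plus + self.stroke_y1
                + self.stroke_y2plus)

    @property
    def direct_non_medical(self) -> float:
        return self.dnm_y1 + self.dnm_y2plus

    @property
    def societal_total(self) -> float:
        return self.direct_medical + self.direct_non_medical

    def total(self, perspective: str) -> float:
        if perspective == "societal":
            return self.societal_total
        if perspective == "provider":
            return self.direct_medical
        raise EconomicsError(f"unknown perspective {perspective!r}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted ledger, life-years and QALYs for one strategy."""

    arm: ArmLabel
    ledger: CostLedger
    life_years: float
    qalys: float


@dataclass(frozen=True)
class IcerResult:
    """Incremental comparison of the add-on arm against the comparator."""

    perspective: str
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    flag: str | None            # None | dominant | dominated | zero-effect
    cost_effective_at_wtp: bool
    wtp: float


def discount_factor(cycle: int, rate: float, timing: str = "mid") -> float:
    """Discount factor for cycle ``cycle`` (1-based).

    Mid-cycle timing discounts to the middle of the cycle (exponent
    ``cycle - 0.5``); end-of-cycle timing uses exponent ``cycle``.
    """
    if cycle < 1:
        raise EconomicsError(f"cycle must be >= 1 (got {cycle})")
    if rate < 0:
        raise EconomicsError(f"discount rate must be >= 0 (got {rate})")
    offset = 0.5 if timing == "mid" else 0.0
    return (1.0 + rate) ** -(cycle - offset)


def _discount_vector(n: int, rate: float, timing: str) -> np.ndarray:
    cycles = np.arange(1, n + 1, dtype=float)
    offset = 0.5 if timing == "mid" else 0.0
    return (1.0 + rate) ** -(cycles - offset)


def accumulate_costs(trace: CohortTrace,
                     params: ModelParameters,
                     settings: AnalysisSettings,
                     arm: ArmLabel) -> CostLedger:
    """Discounted cost ledger for one arm's cohort trace."""
    w = half_cycle_occupancy(trace, settings.half_cycle)
    n = trace.n_cycles
    df = _discount_vector(n, settings.discount_rate_costs,
                          settings.discount_timing)
    living = w[:, (NO_EVENT, MI, STROKE)].sum(axis=1)
    v = params.value

    disc_ly = float(living @ df)
    drug_statin = v("cost_statin_annual") * disc_ly
    drug_ez = (v("cost_ez_annual") * disc_ly
               if arm is ArmLabel.EZETIMIBE_PLUS_STATIN else 0.0)

    acs_time = living if settings.acs_cost_states == "all_living" \
        else w[:, NO_EVENT]
    acs_y1 = v("cost_acs_y1") * acs_time[0] * df[0]
    acs_y2plus = v("cost_acs_y2plus") * float(acs_time[1:] @ df[1:])

    # one-cycle tunnel: first-year price on inflow, maintenance afterwards;
    # entrants contribute half a cycle of occupancy in their entry cycle
    # under the half-cycle correction, a full cycle without it
    entry_share = 0.5 if settings.half_cycle else 1.0
    mi_maint = np.maximum(w[:, MI] - entry_share * trace.new_mi, 0.0)
    stroke_maint = np.maximum(w[:, STROKE] - entry_share * trace.new_stroke, 0.0)
    mi_y1 = v("cost_mi_y1") * float(trace.new_mi @ df)
    mi_y2plus = v("cost_mi_y2plus") * float(mi_maint @ df)
    stroke_y1 = v("cost_stroke_y1") * float(trace.new_stroke @ df)
    stroke_y2plus = v("cost_stroke_y2plus") * float(stroke_maint @ df)

    dnm_y1 = v("cost_dnm_y1") * 1.0 * df[0]
    dnm_y2plus = v("cost_dnm_y2plus") * float(living[1:] @ df[1:])

    return CostLedger(
        drug_statin=drug_statin, drug_ez=drug_ez,
        acs_y1=acs_y1, acs_y2plus=acs_y2plus,
        mi_y1=mi_y1, mi_y2plus=mi_y2plus,
        stroke_y1=stroke_y1, stroke_y2plus=stroke_y2plus,
        dnm_y1=dnm_y1, dnm_y2plus=dnm_y2plus,
    )


def state_utilities(params: ModelParameters) -> np.ndarray:
    """Per-state annual utilities: post-event states carry decrements."""
    u = params.value("u_acs")
    u_mi = u - params.value("dec_mi")
    u_stroke = u - params.value("dec_stroke")
    if u_mi < 0 or u_stroke < 0:
        raise ParameterValidationError(
            "post-event utility is negative (decrement exceeds u_acs)")
    return np.array([u, u_mi, u_stroke, 0.0])


def accumulate_qalys(trace: CohortTrace,
                     params: ModelParameters,
                     settings: AnalysisSettings) -> tuple[float, float]:
    """Discounted (life_years, qalys) for one cohort trace."""
    w = half_cycle_occupancy(trace, settings.half_cycle)
    df = _discount_vector(trace.n_cycles, settings.discount_rate_outcomes,
                          settings.discount_timing)
    living = w[:, (NO_EVENT, MI, STROKE)].sum(axis=1)
    life_years = float(living @ df)
    qalys = float((w @ state_utilities(params)) @ df)
    return life_years, qalys


def evaluate_arm(params: ModelParameters,
                 settings: AnalysisSettings,
                 lt: LifeTable,
                 arm: ArmLabel) -> ArmOutcome:
    """Run one strategy end-to-end: trace, ledger, life-years, QALYs."""
    trace = run_cohort(params, settings, lt, arm)
    ledger = accumulate_costs(trace, params, settings, arm)
    life_years, qalys = accumulate_qalys(trace, params, settings)
    return ArmOutcome(arm=arm, ledger=ledger, life_years=life_years,
                      qalys=qalys)


def compute_icer(ref: ArmOutcome, alt: ArmOutcome,
                 settings: AnalysisSettings,
                 perspective: str | None = None) -> IcerResult:
    """Incremental cost-effectiveness of ``alt`` versus ``ref``."""
    perspective = perspective or settings.perspective
    d_cost = alt.ledger.total(perspective) - ref.ledger.total(perspective)
    d_ly = alt.life_years - ref.life_years
    d_qaly = alt.qalys - ref.qalys

    flag = None
    icer_q = icer_ly = None
    if d_qaly == 0.0:
        flag = "zero-effect"
    elif d_qaly > 0 and d_cost < 0:
        flag = "dominant"
    elif d_qaly < 0 and d_cost > 0:
        flag = "dominated"
    if d_qaly != 0.0:
        icer_q = d_cost / d_qaly
    if d_ly != 0.0:
        icer_ly = d_cost / d_ly

    if flag == "dominant":
        ce = True
    elif flag in ("dominated", "zero-effect"):
        ce = False
    else:
        ce = icer_q is not None and d_qaly > 0 and icer_q <= settings.wtp
    return IcerResult(perspective=perspective, delta_cost=d_cost,
                      delta_ly=d_ly, delta_qaly=d_qaly,
                      icer_per_qaly=icer_q, icer_per_ly=icer_ly,
                      flag=flag, cost_effective_at_wtp=ce, wtp=settings.wtp)


def to_usd(thb: float, settings: AnalysisSettings) -> float:
    """Convert THB to USD at the fixed reporting exchange rate."""
    return thb / settings.exchange_rate_thb_per_usd


@dataclass(frozen=True)
class StrategyComparison:
    """Both arms evaluated under common settings, with ICERs per perspective."""

    comparator: ArmOutcome
    intervention: ArmOutcome
    icers: dict[str, IcerResult]


def compare_strategies(params: ModelParameters,
                       settings: AnalysisSettings,
                       lt: LifeTable) -> StrategyComparison:
    """Base-case evaluation of both strategies and ICERs for both
    perspectives."""
    ref = evaluate_arm(params, settings, lt, ArmLabel.STATIN_ALONE)
    alt = evaluate_arm(params, settings, lt, ArmLabel.EZETIMIBE_PLUS_STATIN)
    icers = {p: compute_icer(ref, alt, settings, p) for p in PERSPECTIVES}
    return StrategyComparison(comparator=ref, intervention=alt, icers=icers)
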