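"""Cohort Markov engine: transition matrices and the annual cohort trace.

Four mutually exclusive states — no further event, non-fatal MI, non-fatal
stroke, death — with annual cycles.  The cohort enters in the no-event
state; within a cycle it may stay, suffer a first MI or stroke, or die.
Post-event states are absorbing up to death (no MI/stroke crossover, no
recurrent events).

Mortality layering: the no-event state carries life-table background
mortality scaled by the post-ACS excess hazard ratio (and, in the
ezetimibe arm, the all-cause relative risk).  Post-event states carry an
annual case-fatality probability for every cycle of residence, combined
with unscaled background mortality under a configurable rule (``max`` by
default, so post-event mortality never drops below general-population
mortality and is never double counted).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import LifeTable, background_death_prob, rate_to_prob
from .params import AnalysisSettings, ModelParameters

STATES = ("no_event", "mi", "stroke", "death")
NO_EVENT, MI, STROKE, DEATH = range(4)

_ROW_SUM_TOL = 1e-12


class ArmLabel(enum.Enum):
    """The two modelled strategies."""

    STATIN_ALONE = "statin_alone"
    EZETIMIBE_PLUS_STATIN = "ezetimibe_plus_statin"


class InfeasibleParametersError(ValueError):
    """A state's outgoing probabilities exceed 1."""


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy plus new-event incidence.

    ``occupancy[t]`` is the distribution over states at the end of cycle
    ``t`` (row 0 is the starting distribution); ``new_mi[t-1]`` /
    ``new_stroke[t-1]`` are the inflows into the event states during cycle
    ``t``; ``ages[t-1]`` is the age at the start of cycle ``t``.
    """

    occupancy: np.ndarray
    new_mi: np.ndarray
    new_stroke: np.ndarray
    ages: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        """Living cohort share at each recorded time point."""
        return self.occupancy[:, :DEATH].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cycles
        return pd.DataFrame({
            "cycle": np.arange(n + 1),
            "age": np.concatenate([self.ages, [self.ages[-1] + 1]]),
            "no_event": self.occupancy[:, NO_EVENT],
            "mi": self.occupancy[:, MI],
            "stroke": self.occupancy[:, STROKE],
            "death": self.occupancy[:, DEATH],
            "new_mi": np.concatenate([[0.0], self.new_mi]),
            "new_stroke": np.concatenate([[0.0], self.new_stroke]),
        })


def _event_probs(params: ModelParameters, arm: ArmLabel) -> tuple[float, float]:
    if arm is ArmLabel.EZETIMIBE_PLUS_STATIN:
        return params.value("p_mi_ez"), params.value("p_stroke_ez")
    return params.value("p_mi_statin"), params.value("p_stroke_statin")


def _combine_mortality(p_event: float, p_background: float, rule: str) -> float:
    if rule == "event_only":
        return p_event
    if rule == "competing":
        return 1.0 - (1.0 - p_event) * (1.0 - p_background)
    return max(p_event, p_background)


def build_transition_matrix(params: ModelParameters,
                            settings: AnalysisSettings,
                            lt: LifeTable,
                            arm: ArmLabel,
                            age: int) -> np.ndarray:
    """One-cycle 4x4 transition matrix for ``arm`` at ``age``.

    Rows/columns follow :data:`STATES`.  Every row sums to 1; the death
    row is absorbing; MI<->stroke crossover entries are structurally 0.
    """
    ez = arm is ArmLabel.EZETIMIBE_PLUS_STATIN
    p_mi, p_stroke = _event_probs(params, arm)
    hr = math.exp(params.value("log_hr_excess"))
    rr_any = params.value("rr_death_any") if ez else 1.0
    p_death_noev = background_death_prob(lt, age, hr, rr_any)

    out = p_mi + p_stroke + p_death_noev
    if out > 1.0 + _ROW_SUM_TOL:
        raise InfeasibleParametersError(
            f"no_event row: outgoing probabilities sum to {out:.6f} > 1 "
            f"at age {age} ({arm.value})")

    p_bg = lt.death_prob(age)  # unscaled background for post-event states
    rule = settings.post_event_mortality
    p_death_mi = _combine_mortality(
        params.value("p_death_mi") * (params.value("rr_death_mi") if ez else 1.0),
        p_bg, rule)
    p_death_stroke = _combine_mortality(
        params.value("p_death_stroke")
        * (params.value("rr_death_stroke") if ez else 1.0),
        p_bg, rule)
    for name, p in (("mi", p_death_mi), ("stroke", p_death_stroke)):
        if p > 1.0 + _ROW_SUM_TOL:
            raise InfeasibleParametersError(
                f"{name} row: death probability {p:.6f} > 1 at age {age}")

    m = np.zeros((4, 4))
    m[NO_EVENT] = (max(1.0 - out, 0.0), p_mi, p_stroke, p_death_noev)
    m[MI] = (0.0, max(1.0 - p_death_mi, 0.0), 0.0, min(p_death_mi, 1.0))
    m[STROKE] = (0.0, 0.0, max(1.0 - p_death_stroke, 0.0),
                 min(p_death_stroke, 1.0))
    m[DEATH, DEATH] = 1.0
    return m


def run_cohort(params: ModelParameters,
               settings: AnalysisSettings,
               lt: LifeTable,
               arm: ArmLabel) -> CohortTrace:
    """Run the closed cohort from ``start_age`` to ``max_age``."""
    n = settings.n_cycles
    occ = np.zeros((n + 1, 4))
    occ[0, NO_EVENT] = 1.0
    new_mi = np.zeros(n)
    new_stroke = np.zeros(n)
    ages = settings.start_age + np.arange(n)

    for t in range(1, n + 1):
        age = int(ages[t - 1])
        m = build_transition_matrix(params, settings, lt, arm, age)
        prev = occ[t - 1]
        occ[t] = prev @ m
        new_mi[t - 1] = prev[NO_EVENT] * m[NO_EVENT, MI]
        new_stroke[t - 1] = prev[NO_EVENT] * m[NO_EVENT, STROKE]

    return CohortTrace(occ, new_mi, new_stroke, ages)


def half_cycle_occupancy(trace: CohortTrace,
                         half_cycle: bool = True) -> np.ndarray:
    """State-time (years) attributed to each cycle, per state.

    With the half-cycle correction, time in a living state during cycle
    ``t`` is the trapezoid ``(occ[t-1] + occ[t]) / 2``; without it, the
    end-of-cycle occupancy is used.  Death accrues no time.
    """
    occ = trace.occupancy
    if half_cycle:
        w = 0.5 * (occ[:-1] + occ[1:])
    else:
        w = occ[1:].copy()
    w[:, DEATH] = 0.0
    return w
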