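"""One-way and probabilistic sensitivity analysis.

One-way sensitivity (tornado): each input is pushed to the ends of its
range while everything else stays at base, the deterministic model is
re-run, and parameters are ranked by the absolute spread of the resulting
ICER.

Probabilistic sensitivity analysis: every parameter is drawn independently
from its fitted distribution (beta / gamma / log-normal), both strategies
are evaluated on the common draw, and the per-iteration incremental cost
and QALY pairs feed the cost-effectiveness plane (quadrant shares) and the
acceptability curve.  Draw order follows the sorted canonical parameter
names, so seeded runs are reproducible and stable under config layout
changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import compare_strategies, compute_icer, evaluate_arm
from .engine import ArmLabel, InfeasibleParametersError
from .life_tables import LifeTable
from .params import (AnalysisSettings, DistributionFit, ModelParameters,
                     fit_distribution, owsa_range)

logger = logging.getLogger(__name__)

DEFAULT_WTP_GRID = np.arange(0, 400_001, 10_000, dtype=float)

_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter.

    ``flag`` marks entries whose ICER is not a well-defined positive-regime
    ratio at one of the bounds: ``infeasible-model`` when the bound breaks
    the transition matrix, ``dominance`` when the incremental QALYs turn
    non-positive (the ratio would be misleading).  Flagged entries keep
    their NaN endpoint and sink to the bottom of the ranking rather than
    being dropped.
    """

    parameter: str
    low_input: float
    high_input: float
    icer_at_low: float
    icer_at_high: float
    pct_change_low: float
    pct_change_high: float
    flag: str | None = None

    @property
    def infeasible(self) -> bool:
        return self.flag is not None

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PsaDraws:
    """Per-iteration incremental results under a fixed perspective."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    perspective: str
    rng_seed: int
    resampled: int = 0
    parameter_draws: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return self.delta_cost.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, self.n + 1),
            "delta_cost_thb": self.delta_cost,
            "delta_qaly": self.delta_qaly,
        })


@dataclass(frozen=True)
class CeacCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    wtp: np.ndarray
    prob_cost_effective: np.ndarray

    def at(self, wtp: float) -> float:
        idx = np.nonzero(np.isclose(self.wtp, wtp))[0]
        if idx.size == 0:
            raise KeyError(f"wtp {wtp} not on the grid")
        return float(self.prob_cost_effective[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp_thb": self.wtp,
                             "prob_ce": self.prob_cost_effective})


def _icer_value(params: ModelParameters, settings: AnalysisSettings,
                lt: LifeTable, perspective: str) -> tuple[float, str | None]:
    """(ICER, flag): NaN + ``dominance`` when incremental QALYs are <= 0."""
    ref = evaluate_arm(params, settings, lt, ArmLabel.STATIN_ALONE)
    alt = evaluate_arm(params, settings, lt, ArmLabel.EZETIMIBE_PLUS_STATIN)
    res = compute_icer(ref, alt, settings, perspective)
    if res.delta_qaly <= 0:
        return np.nan, "dominance"
    return res.icer_per_qaly, None


def run_owsa(params: ModelParameters,
             settings: AnalysisSettings,
             lt: LifeTable,
             perspective: str | None = None) -> list[TornadoEntry]:
    """One-way sensitivity over every parameter, sorted by spread descending.

    A bound that renders the model infeasible flags the entry (NaN ICER at
    that bound) instead of dropping it.
    """
    perspective = perspective or settings.perspective
    icer_base, base_flag = _icer_value(params, settings, lt, perspective)
    if base_flag is not None:
        raise ValueError("base case has non-positive incremental QALYs; "
                         "tornado percentages are undefined")
    entries = []
    for spec in params:
        low, high = owsa_range(spec)
        icers = []
        flag = None
        for bound in (low, high):
            try:
                val, f = _icer_value(params.with_value(spec.name, bound),
                                     settings, lt, perspective)
                icers.append(val)
                flag = flag or f
            except (InfeasibleParametersError, ValueError):
                icers.append(np.nan)
                flag = "infeasible-model"
        pct = [100.0 * (x - icer_base) / icer_base for x in icers]
        entries.append(TornadoEntry(
            parameter=spec.name, low_input=low, high_input=high,
            icer_at_low=icers[0], icer_at_high=icers[1],
            pct_change_low=pct[0], pct_change_high=pct[1], flag=flag))
    # flagged entries sink to the end; well-defined ones rank by spread
    feasible = [e for e in entries if e.flag is None]
    flagged = [e for e in entries if e.flag is not None]
    feasible.sort(key=lambda e: e.spread, reverse=True)
    return feasible + flagged


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter,
        "low_input": e.low_input,
        "high_input": e.high_input,
        "icer_low": e.icer_at_low,
        "icer_high": e.icer_at_high,
        "pct_low": e.pct_change_low,
        "pct_high": e.pct_change_high,
        "spread": e.spread,
        "flag": e.flag or "",
    } for e in entries])


def fit_all(params: ModelParameters) -> dict[str, DistributionFit]:
    return {spec.name: fit_distribution(spec) for spec in params}


def sample_parameter_set(params: ModelParameters,
                         rng: np.random.Generator,
                         fits: dict[str, DistributionFit] | None = None
                         ) -> ModelParameters:
    """One independent joint draw of all non-fixed parameters.

    Probabilities and utilities are clamped into their unit-interval domain
    (with a logged warning) in the rare tail where a fitted distribution
    strays; fixed parameters pass through untouched.
    """
    fits = fits if fits is not None else fit_all(params)
    values: dict[str, float] = {}
    for name in sorted(params.names):  # canonical draw order
        spec = params[name]
        draw = float(fits[name].sample(rng))
        if spec.role in ("probability", "utility") and not 0.0 <= draw < 1.0:
            clamped = min(max(draw, 0.0), np.nextafter(1.0, 0.0))
            logger.warning("clamped %s draw %.6g to %.6g", name, draw, clamped)
            draw = clamped
        values[name] = draw
    return params.with_values(values)


def run_psa(params: ModelParameters,
            settings: AnalysisSettings,
            lt: LifeTable,
            perspective: str | None = None,
            seed: int | None = None,
            iterations: int | None = None,
            keep_parameter_draws: bool = False) -> PsaDraws:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Both strategies are evaluated on the same sampled parameter set within
    each iteration.  Draws that make the model infeasible (outgoing
    probabilities above 1) are re-sampled and counted.
    """
    perspective = perspective or settings.perspective
    seed = settings.rng_seed if seed is None else seed
    n = settings.psa_iterations if iterations is None else iterations
    rng = np.random.default_rng(seed)
    fits = fit_all(params)

    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    rows = [] if keep_parameter_draws else None
    resampled = 0
    for i in range(n):
        for _ in range(_MAX_RESAMPLE):
            drawn = sample_parameter_set(params, rng, fits)
            try:
                ref = evaluate_arm(drawn, settings, lt, ArmLabel.STATIN_ALONE)
                alt = evaluate_arm(drawn, settings, lt,
                                   ArmLabel.EZETIMIBE_PLUS_STATIN)
            except (InfeasibleParametersError, ValueError):
                resampled += 1
                continue
            break
        else:
            raise InfeasibleParametersError(
                "PSA: could not draw a feasible parameter set")
        d_cost[i] = (alt.ledger.total(perspective)
                     - ref.ledger.total(perspective))
        d_qaly[i] = alt.qalys - ref.qalys
        if rows is not None:
            rows.append({s.name: s.base for s in drawn})
    if resampled:
        logger.info("PSA re-sampled %d infeasible draw(s)", resampled)
    return PsaDraws(delta_cost=d_cost, delta_qaly=d_qaly,
                    perspective=perspective, rng_seed=seed,
                    resampled=resampled,
                    parameter_draws=pd.DataFrame(rows) if rows else None)


def quadrant_shares(draws: PsaDraws) -> dict[str, float]:
    """Cost-effectiveness-plane quadrant shares.

    Half-open convention: a delta of exactly 0 counts as positive, so the
    four shares partition the draws and sum to 1.
    """
    if draws.n == 0:
        raise ValueError("no draws")
    qpos = draws.delta_qaly >= 0
    cpos = draws.delta_cost >= 0
    n = draws.n
    return {
        "NE": float(np.sum(qpos & cpos)) / n,
        "NW": float(np.sum(~qpos & cpos)) / n,
        "SE": float(np.sum(qpos & ~cpos)) / n,
        "SW": float(np.sum(~qpos & ~cpos)) / n,
    }


def ceac(draws: PsaDraws,
         wtp_grid: np.ndarray | None = None) -> CeacCurve:
    """Acceptability curve: share of draws with positive net monetary
    benefit ``wtp * dQALY - dCost`` at each grid point (strict inequality,
    so an exactly zero benefit counts as not cost-effective)."""
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid,
                                                               dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("wtp grid must be 1-D strictly ascending")
    nmb = grid[:, None] * draws.delta_qaly[None, :] - draws.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CeacCurve(wtp=grid, prob_cost_effective=prob)
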