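# Methods

## The decision problem

`acscea` implements a cost-utility comparison of two lipid-lowering
strategies for secondary prevention after acute coronary syndrome (ACS) in
patients who cannot tolerate high-intensity statins:

* **comparator** — moderate-intensity statin alone (simvastatin 40 mg/day);
* **intervention** — ezetimibe 10 mg/day added to the same statin.

The health economy is Thailand's: costs are 2024 Thai baht (THB), the
willingness-to-pay (WTP) ceiling is 160,000 THB/QALY, and results are
reported from both the societal perspective (direct medical + direct
non-medical costs) and the healthcare-provider perspective (direct medical
only). Indirect/productivity costs are excluded by design.

## Model structure

A closed-cohort Markov model with four mutually exclusive states —
*no further event*, *non-fatal MI*, *non-fatal stroke*, *death* — and an
annual cycle. The cohort enters at age 62 in the no-event state and runs to
age 100 (38 cycles), by which point under the default mortality more than
99% of the cohort has died; the residual living mass still earns its final
half-cycle credit. Post-event states are absorbing up to death: no
MI↔stroke crossover, no recurrent events, no concurrent MI+stroke, no
discontinuation or adverse-event states.

### Transition probabilities

Annual first-event probabilities are arm-specific constants (trial-derived
average annual risks; no age interaction is modelled):

| input | comparator | ezetimibe arm |
|---|---|---|
| MI | 0.016900 | 0.014779 |
| stroke | 0.005415 | 0.004653 |

Mortality is layered as follows. Hazard ratios act multiplicatively on the
**rate** scale before conversion to probabilities with `p = 1 − exp(−rt)`;
relative risks act on the **probability** scale afterwards (clamped at 1).

* **No-event state** — life-table background rate × the post-ACS excess
  hazard ratio `exp(0.693) ≈ 2.0`, converted to a probability; in the
  ezetimibe arm the all-cause relative risk 0.99 then applies.
* **Post-event states** — an annual case-fatality probability (0.090263
  after MI, 0.071593 after stroke; × 0.84 / 0.90 in the ezetimibe arm)
  applies in *every* cycle of residence, combined with *unscaled*
  background mortality under a configurable rule (`post_event_mortality`):
  * `max` (default): `max(event-specific, background)` — post-event
    mortality never falls below general-population mortality, with no
    double counting;
  * `event_only`: the case-fatality probability alone;
  * `competing`: `1 − (1−p_event)(1−p_background)`.

  The excess hazard ratio is *not* applied in post-event states: its input
  is defined specifically for the no-event state, and the case-fatality
  inputs already embed post-event excess risk.

Every generated matrix is row-stochastic to 1e-12 with an absorbing death
row; a parameter set whose outgoing probabilities exceed 1 raises an
infeasibility error naming the offending row rather than renormalising
silently.

## Background mortality

The model reads any national life table as a CSV of age-indexed annual
mortality rates (`age,mortality_rate`, contiguous integer ages; gaps are
rejected rather than interpolated, ages past the table end hold the final
rate). When no table is supplied, a synthetic Gompertz–Makeham table is
generated:

    r(a) = alpha * exp(beta_g * (a - 62)) + gamma_m

with defaults `alpha = 0.0128`, `beta_g = 0.085`, `gamma_m = 0.001`.
`alpha` was calibrated (slope and Makeham term held at conventional
old-age values) so that undiscounted remaining life expectancy at 62 is
≈ 20 years, a plausible sex-combined national value at that age. The
synthetic table emulates only the *level and age-gradient* of background
mortality; it does not reproduce any particular national table's shape, so
absolute life-years, incremental QALYs and probabilistic quadrant shares
computed under it are indicative rather than reproductions — results that
hinge on the exact national mortality schedule should be read accordingly
(the base-case ICERs turn out to be far less table-sensitive than the LY/QALY
levels, because both arms share the same background mortality).

## Valuation

* **Discounting** — 3%/year for both costs and outcomes. Discounting is
  mid-cycle by default (`discount_timing: mid`, factor `1.03^−(t−0.5)`),
  applied to half-cycle-corrected state-time, so lifetime drug cost equals
  annual price × discounted life-years exactly — the identity the reported
  ledger satisfies. End-of-cycle timing is available in config.
* **Half-cycle correction** — living state-time in cycle *t* is the
  trapezoid `(occ[t−1] + occ[t])/2`; death accrues no time. Disabling it
  (`half_cycle: false`) switches to end-of-cycle occupancy.
* **Costs** (all annual THB): drug costs (statin 292 = 0.80/day × 365;
  ezetimibe 1,730 = 4.74/day × 365) accrue to all living state-time; ACS
  management costs (65,507 first year; 39,617 thereafter) accrue to the
  no-event state only by default (`acs_cost_states`), keeping the reported
  categories disjoint from the post-event maintenance costs; event costs
  use a one-cycle tunnel — the first-year price (MI 148,366; stroke
  73,440) attaches to the new-event inflow in its inflow cycle, and the
  maintenance price (15,924; 11,634) to residence state-time with the
  entrants' first half-cycle excluded (half a year of an entrant's entry
  cycle is their first year, already covered by the one-time payment);
  direct non-medical costs (3,730 first year, once, to the full cohort;
  5,394/year of living time thereafter) count only in the societal total.
* **Utilities** — no-event 0.82; post-MI 0.82 − 0.41635 = 0.40365;
  post-stroke 0.82 − 0.2259 = 0.5941; death 0. A decrement exceeding the
  baseline utility is a validation error. QALYs are discounted half-cycle
  state-time weighted by these utilities.
* **ICER** — incremental cost over incremental QALYs (and per LY),
  intervention minus comparator. Dominance flags replace the ratio where it
  is undefined or misleading: `dominant` (cheaper and more effective),
  `dominated` (costlier and less effective), `zero-effect` (ΔQALY = 0).
  USD columns are derived at the fixed 35.2952 THB/USD reporting rate and
  are never an input.

## Parameter uncertainty

Each input carries a 95% interval and a distribution family. The interval
maps to a standard error as `SE = (high − low)/3.92`; distributions are
fitted by method of moments:

* **beta** (probabilities, baseline utility): `ν = base(1−base)/SE² − 1`,
  `α = base·ν`, `β = (1−base)·ν` — fitted mean = base to 1e-9;
* **gamma** (costs, utility decrements): `shape = (base/SE)²`,
  `scale = SE²/base` — fitted mean = base;
* **log-normal** (relative risks): `meanlog = ln(base)`,
  `sdlog = (ln high − ln low)/3.92` — median-preserving;
* the excess-mortality input is stored as ln(HR) = 0.693 with its interval
  (0.62–0.76) already on the log scale; the HR is log-normal with
  `meanlog = 0.693`, and draws are returned as ln(HR).

**One-way sensitivity** re-runs the deterministic model at each
parameter's bounds (the stated interval; ±10% for probabilities/utilities
or ±20% for costs when a config row has no interval) and ranks by absolute
ICER spread. A bound that turns incremental QALYs non-positive makes the
ratio meaningless; such entries are flagged (`dominance`), keep a NaN
endpoint, and sink below the ranked entries instead of being dropped — as
does a bound that breaks matrix feasibility (`infeasible-model`).

**Probabilistic sensitivity analysis** draws every non-fixed parameter
independently (1,000 iterations by default), evaluates both arms on the
common draw, and records (Δcost, ΔQALY). Draw order follows sorted
parameter names, so seeded runs are bit-reproducible and stable under
config re-ordering. Probabilities/utilities are clamped into [0, 1) with a
logged warning in the rare tail; draws that break feasibility are
re-sampled and counted. Quadrant shares use a half-open convention (a
delta of exactly 0 counts as positive) so the four shares always sum to 1.
The CEAC reports, on a 0–400,000 THB grid in 10,000 steps (160,000 always
on-grid), the share of draws with strictly positive net monetary benefit
`λ·ΔQALY − Δcost`; an exactly-zero benefit counts as *not* cost-effective.
Sampling is independent across all parameters, including the two arms'
event probabilities — matching the one-distribution-per-parameter design —
which makes the PSA spread of ΔQALY wider than arm-linked sampling would;
`psa_link_arms` is reserved in config for a correlated-draw variant.

## Validation

Internal validity: every transition matrix row sums to 1 within 1e-12 at
every age and arm (`acscea validate` emits a machine-readable report).
Cross-checks in the test suite include closed-form oracles (constant
mortality q = 0.5 gives 1.5 trapezoidal state-years; geometric cohort
decay), exact equivalence between the engine's undiscounted life-years and
the life table's trapezoidal life expectancy when events and excess
mortality are switched off, and PSA mean–base-case agreement within three
Monte-Carlo standard errors.

## Problem sizes and determinism

The default analysis is 38 annual cycles per arm; one-way sensitivity is
2 model runs × 23 parameters; the PSA default is 1,000 iterations (both
arms per iteration) and completes in seconds. All stochastic paths take an
explicit seed; identical seeds give bit-identical draws, scatter files and
CEAC values.

## Known limitations

* No recurrent events, crossover, or treatment discontinuation — these are
  structural exclusions, shared with the source four-state design.
* The single annual post-event case-fatality input cannot distinguish
  first-cycle case fatality from long-run excess mortality; the
  `post_event_mortality` switch exposes the plausible readings, and `max`
  is the default.
* First-cycle cost attribution conventions differ across published
  implementations of this model family; the conventions here are stated
  above and logged in every run manifest, and first-year cost categories
  should be compared across implementations with that caveat.
* Under the synthetic life table the absolute life-years and QALYs (and
  hence PSA quadrant geometry) differ from what a specific national table
  would give; supply the national table CSV for reproduction-grade runs.
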