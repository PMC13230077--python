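"""Model inputs, configuration parsing, and uncertainty-distribution fitting.

Every model input is a :class:`ParameterSpec` carrying a point estimate, a
95% uncertainty interval, and a sampling-distribution family.  Distributions
are fitted by method of moments from the interval half-width treated as a
normal 95% confidence interval (SE = range / 3.92): beta for probabilities
and utilities, gamma for costs and utility decrements, log-normal for
relative risks and for the hazard ratio of post-ACS excess mortality
(median-preserving on the ratio scale).

Configuration is a YAML document with two blocks, ``parameters.*`` and
``settings.*``; the packaged default reproduces the full base-case input
set.  User configs overlay the default key-by-key.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

Z95 = 1.96  # two-sided normal 95% quantile used to map intervals to SEs

ROLES = frozenset(
    {"probability", "relative_risk", "log_hazard_ratio", "cost", "utility",
     "utility_decrement"}
)
FAMILIES = frozenset({"beta", "gamma", "lognormal", "fixed"})

# Fallback one-way sensitivity spans when a parameter has no interval:
# +/-10% for probabilities and utilities, +/-20% for costs.
_OWSA_FALLBACK_SPAN = {"cost": 0.20}
_OWSA_DEFAULT_SPAN = 0.10


class ConfigurationError(ValueError):
    """A config file is malformed or missing a mandatory key."""


class ParameterValidationError(ValueError):
    """A parameter value violates its role's invariants."""


class InfeasibleMomentsError(ValueError):
    """Interval too wide for a moment-matched distribution on the base value."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model input: point estimate, interval, distribution family, role.

    ``low``/``high`` may be ``None`` when a source gives no interval; the
    one-way sensitivity range then falls back to a fixed proportional span
    and the parameter samples as fixed.
    """

    name: str
    base: float
    low: float | None
    high: float | None
    dist_family: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ParameterValidationError(
                f"{self.name}: unknown role {self.role!r}")
        if self.dist_family not in FAMILIES:
            raise ParameterValidationError(
                f"{self.name}: unknown distribution {self.dist_family!r}")
        if (self.low is None) != (self.high is None):
            raise ParameterValidationError(
                f"{self.name}: interval must give both bounds or neither")
        if self.low is not None and not (self.low <= self.base <= self.high):
            raise ParameterValidationError(
                f"{self.name}: interval must bracket the base value "
                f"({self.low} <= {self.base} <= {self.high} fails)")
        if self.role in ("probability", "utility") and not (0.0 <= self.base <= 1.0):
            kind = "probability" if self.role == "probability" else "utility"
            raise ParameterValidationError(
                f"{self.name}: {kind} out of [0,1] (got {self.base})")
        if self.role == "cost" and self.base < 0:
            raise ParameterValidationError(
                f"{self.name}: cost must be >= 0 (got {self.base})")
        if self.role == "relative_risk" and self.base <= 0:
            raise ParameterValidationError(
                f"{self.name}: relative risk must be > 0 (got {self.base})")

    @property
    def is_fixed(self) -> bool:
        return self.dist_family == "fixed" or (
            self.low is not None and self.low == self.high)

    def interval(self) -> tuple[float, float]:
        """The stated interval, or the fallback proportional span."""
        if self.low is not None:
            return (self.low, self.high)
        span = _OWSA_FALLBACK_SPAN.get(self.role, _OWSA_DEFAULT_SPAN)
        return (self.base * (1 - span), self.base * (1 + span))


@dataclass(frozen=True)
class ModelParameters:
    """The full, ordered input set of the decision model.

    Parameter order is canonical (the order of the serialised config) and
    fixes the Monte-Carlo draw order, so probabilistic results are stable
    under refactoring.
    """

    specs: tuple[ParameterSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ParameterValidationError("duplicate parameter names")

    def __getitem__(self, name: str) -> ParameterSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.specs)

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self.specs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def value(self, name: str) -> float:
        return self[name].base

    def with_value(self, name: str, value: float) -> "ModelParameters":
        """A copy with one base value replaced (bounds widened if needed)."""
        out = []
        for s in self.specs:
            if s.name == name:
                low = None if s.low is None else min(s.low, value)
                high = None if s.high is None else max(s.high, value)
                s = replace(s, base=float(value), low=low, high=high)
            out.append(s)
        return ModelParameters(tuple(out))

    def with_values(self, values: Mapping[str, float]) -> "ModelParameters":
        p = self
        for k, v in values.items():
            p = p.with_value(k, v)
        return p

    def validate_cross(self) -> None:
        """Base-case cross-parameter coherence checks.

        Applied at configuration load only: independently sampled parameter
        sets may legitimately violate these orderings.
        """
        u = self.value("u_acs")
        for dec in ("dec_mi", "dec_stroke"):
            if self.value(dec) > u:
                raise ParameterValidationError(
                    f"{dec}: utility decrement {self.value(dec)} exceeds "
                    f"u_acs {u} (post-event utility would be negative)")
        for ez, ms in (("p_mi_ez", "p_mi_statin"),
                       ("p_stroke_ez", "p_stroke_statin")):
            if self.value(ez) > self.value(ms):
                raise ParameterValidationError(
                    f"{ez}: ezetimibe-arm event probability exceeds the "
                    f"statin-arm value {self.value(ms)}")


@dataclass(frozen=True)
class AnalysisSettings:
    """Run-level analysis settings (cohort, discounting, PSA, bookkeeping)."""

    start_age: int = 62
    max_age: int = 100
    cycle_length: float = 1.0
    discount_rate_costs: float = 0.03
    discount_rate_outcomes: float = 0.03
    wtp: float = 160_000.0
    perspective: str = "societal"
    psa_iterations: int = 1000
    rng_seed: int = 12345
    half_cycle: bool = True
    exchange_rate_thb_per_usd: float = 35.2952
    post_event_mortality: str = "max"          # event_only | max | competing
    acs_cost_states: str = "no_event_only"     # no_event_only | all_living
    discount_timing: str = "mid"               # mid | end
    psa_link_arms: bool = False

    def __post_init__(self) -> None:
        if self.discount_rate_costs < 0 or self.discount_rate_outcomes < 0:
            raise ParameterValidationError("discount rates must be >= 0")
        if self.psa_iterations < 1:
            raise ParameterValidationError("psa_iterations must be >= 1")
        if self.start_age >= self.max_age:
            raise ParameterValidationError("start_age must be < max_age")
        if self.perspective not in ("societal", "provider"):
            raise ParameterValidationError(
                f"unknown perspective {self.perspective!r}")
        if self.post_event_mortality not in ("event_only", "max", "competing"):
            raise ParameterValidationError(
                f"unknown post_event_mortality {self.post_event_mortality!r}")
        if self.acs_cost_states not in ("no_event_only", "all_living"):
            raise ParameterValidationError(
                f"unknown acs_cost_states {self.acs_cost_states!r}")
        if self.discount_timing not in ("mid", "end"):
            raise ParameterValidationError(
                f"unknown discount_timing {self.discount_timing!r}")
        if self.exchange_rate_thb_per_usd <= 0:
            raise ParameterValidationError("exchange rate must be > 0")

    @property
    def n_cycles(self) -> int:
        return int(round((self.max_age - self.start_age) / self.cycle_length))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class DistributionFit:
    """A fitted sampling distribution for one parameter.

    ``shape`` holds family-specific parameters: beta ``(alpha, beta)``,
    gamma ``(shape, scale)``, lognormal ``(meanlog, sdlog)``, fixed
    ``(value,)``.  ``log_scale_value`` marks fits whose draws are reported on
    the log scale (the excess-mortality hazard ratio is sampled as a
    log-normal HR but the model parameter is ln(HR)).
    """

    family: str
    shape: tuple[float, ...]
    log_scale_value: bool = False

    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.shape
            return a / (a + b)
        if self.family == "gamma":
            k, theta = self.shape
            return k * theta
        if self.family == "lognormal":
            mu, sd = self.shape
            return math.exp(mu + 0.5 * sd * sd)
        return self.shape[0]

    def median(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.shape[0])
        if self.family == "fixed":
            return self.shape[0]
        raise NotImplementedError(self.family)

    def var(self) -> float:
        if self.family == "beta":
            a, b = self.shape
            return a * b / ((a + b) ** 2 * (a + b + 1))
        if self.family == "gamma":
            k, theta = self.shape
            return k * theta * theta
        if self.family == "lognormal":
            mu, sd = self.shape
            return (math.exp(sd * sd) - 1) * math.exp(2 * mu + sd * sd)
        return 0.0

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            a, b = self.shape
            return rng.beta(a, b, size=size)
        if self.family == "gamma":
            k, theta = self.shape
            return rng.gamma(k, theta, size=size)
        if self.family == "lognormal":
            mu, sd = self.shape
            draw = rng.lognormal(mu, sd, size=size)
            return np.log(draw) if self.log_scale_value else draw
        value = self.shape[0]
        return value if size is None else np.full(size, value)


def se_from_interval(low: float, high: float) -> float:
    """Standard error implied by a 95% interval: ``(high - low) / 3.92``."""
    if high <= low:
        raise ParameterValidationError(
            f"interval upper bound must exceed lower ({low}, {high})")
    return (high - low) / (2 * Z95)


def fit_beta(spec: ParameterSpec) -> DistributionFit:
    """Method-of-moments beta fit; the fitted mean equals the base value."""
    if spec.role not in ("probability", "utility"):
        raise ParameterValidationError(
            f"{spec.name}: beta fit requires a probability or utility role")
    if not (0.0 < spec.base < 1.0):
        raise ParameterValidationError(
            f"{spec.name}: beta fit requires base in (0,1)")
    se = se_from_interval(*spec.interval())
    nu = spec.base * (1 - spec.base) / (se * se) - 1.0
    if nu <= 0:
        raise InfeasibleMomentsError(
            f"{spec.name}: SE^2 >= base(1-base); no beta matches the moments")
    return DistributionFit("beta", (spec.base * nu, (1 - spec.base) * nu))


def fit_gamma(spec: ParameterSpec) -> DistributionFit:
    """Method-of-moments gamma fit; the fitted mean equals the base value."""
    if spec.role not in ("cost", "utility_decrement"):
        raise ParameterValidationError(
            f"{spec.name}: gamma fit requires a cost or utility-decrement role")
    if spec.base <= 0:
        raise ParameterValidationError(
            f"{spec.name}: gamma fit requires base > 0")
    se = se_from_interval(*spec.interval())
    return DistributionFit("gamma", ((spec.base / se) ** 2, se * se / spec.base))


def fit_lognormal(spec: ParameterSpec) -> DistributionFit:
    """Median-preserving log-normal fit.

    For relative risks the interval is on the natural scale:
    ``meanlog = ln(base)``, ``sdlog = (ln high - ln low) / 3.92``.  For the
    excess-mortality parameter the base value and interval already live on
    the log scale (the stored quantity is ln(HR)); the ratio itself is
    log-normal with ``meanlog = base`` and draws are returned as ln(HR).
    """
    if spec.role == "log_hazard_ratio":
        low, high = spec.interval()
        sd = (high - low) / (2 * Z95)
        return DistributionFit("lognormal", (spec.base, sd), log_scale_value=True)
    if spec.role != "relative_risk":
        raise ParameterValidationError(
            f"{spec.name}: lognormal fit requires a relative-risk or "
            f"log-hazard-ratio role")
    low, high = spec.interval()
    if low <= 0 or spec.base <= 0:
        raise ParameterValidationError(
            f"{spec.name}: lognormal fit requires positive base and bounds")
    sd = (math.log(high) - math.log(low)) / (2 * Z95)
    return DistributionFit("lognormal", (math.log(spec.base), sd))


def fit_distribution(spec: ParameterSpec) -> DistributionFit:
    """Dispatch to the family-appropriate moment fit; fixed stays fixed."""
    if spec.is_fixed:
        return DistributionFit("fixed", (spec.base,))
    if spec.dist_family == "beta":
        return fit_beta(spec)
    if spec.dist_family == "gamma":
        return fit_gamma(spec)
    if spec.dist_family == "lognormal":
        return fit_lognormal(spec)
    return DistributionFit("fixed", (spec.base,))


def owsa_range(spec: ParameterSpec) -> tuple[float, float]:
    """One-way sensitivity bounds: the stated interval, else the fallback
    proportional span, else the degenerate ``(base, base)`` for fixed rows."""
    if spec.is_fixed:
        return (spec.base, spec.base)
    return spec.interval()


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

_MANDATORY_PARAM_KEYS = ("base", "dist", "role")


def _default_raw() -> dict:
    text = (resources.files("acscea.data") / "default_config.yaml").read_text()
    return yaml.safe_load(text)


def default_metadata() -> dict:
    """The metadata block of the packaged default configuration."""
    return dict(_default_raw().get("metadata", {}))


def _build_spec(name: str, entry: Mapping) -> ParameterSpec:
    missing = [k for k in _MANDATORY_PARAM_KEYS if k not in entry]
    if missing:
        raise ConfigurationError(
            f"parameter {name!r}: missing mandatory key(s) {missing}")
    unknown = set(entry) - {"base", "low", "high", "dist", "role"}
    if unknown:
        raise ConfigurationError(
            f"parameter {name!r}: unknown key(s) {sorted(unknown)}")
    return ParameterSpec(
        name=name,
        base=float(entry["base"]),
        low=None if entry.get("low") is None else float(entry["low"]),
        high=None if entry.get("high") is None else float(entry["high"]),
        dist_family=str(entry["dist"]),
        role=str(entry["role"]),
    )


def load_config(path: str | Path | None = None
                ) -> tuple[ModelParameters, AnalysisSettings]:
    """Load the packaged defaults, overlaying a user YAML config if given.

    Overrides merge key-by-key: a user entry for an existing parameter may
    set any subset of ``base/low/high/dist/role``; new parameters must be
    complete.  Settings keys overlay individually.
    """
    raw = _default_raw()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        user = yaml.safe_load(path.read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigurationError("config root must be a mapping")
        unknown = set(user) - {"parameters", "settings", "metadata"}
        if unknown:
            raise ConfigurationError(f"unknown top-level key(s) {sorted(unknown)}")
        for name, entry in (user.get("parameters") or {}).items():
            if name in raw["parameters"]:
                merged = dict(raw["parameters"][name])
                merged.update(entry or {})
                # an override of base without bounds drops the stale interval
                if "base" in (entry or {}) and not {"low", "high"} & set(entry):
                    b = float(entry["base"])
                    if not (merged.get("low") is None
                            or merged["low"] <= b <= merged["high"]):
                        merged["low"], merged["high"] = None, None
                raw["parameters"][name] = merged
            else:
                raw["parameters"][name] = entry
        settings_raw = dict(raw.get("settings") or {})
        settings_raw.update(user.get("settings") or {})
        raw["settings"] = settings_raw

    specs = tuple(_build_spec(name, entry)
                  for name, entry in raw["parameters"].items())
    params = ModelParameters(specs)
    params.validate_cross()

    settings_raw = dict(raw.get("settings") or {})
    known = {f.name for f in fields(AnalysisSettings)}
    unknown = set(settings_raw) - known
    if unknown:
        raise ConfigurationError(f"unknown settings key(s) {sorted(unknown)}")
    settings = AnalysisSettings(**settings_raw)
    return params, settings


def canonical_config_text(params: ModelParameters,
                          settings: AnalysisSettings) -> str:
    """Deterministic YAML serialisation of a validated configuration.

    Loading the result reproduces the same objects, and re-serialising is
    byte-identical (a stable audit form for hashing into run manifests).
    """
    doc = {
        "parameters": {
            s.name: {
                "base": float(s.base),
                "low": None if s.low is None else float(s.low),
                "high": None if s.high is None else float(s.high),
                "dist": s.dist_family,
                "role": s.role,
            }
            for s in params.specs
        },
        "settings": settings.to_dict(),
    }
    return yaml.safe_dump(doc, sort_keys=True, default_flow_style=False)


def params_to_csv(params: ModelParameters) -> str:
    """Flat audit CSV: name, base, low, high, distribution, role."""
    buf = io.StringIO()
    buf.write("name,base,low,high,distribution,role\n")
    for s in params.specs:
        low = "" if s.low is None else repr(s.low)
        high = "" if s.high is None else repr(s.high)
        buf.write(f"{s.name},{s.base!r},{low},{high},{s.dist_family},{s.role}\n")
    return buf.getvalue()
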