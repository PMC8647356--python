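"""Model inputs for the asthma cost-utility analysis.

Every quantitative input of the decision model — per-cycle transition
probabilities, annual state utilities, unit costs in 2020 US dollars,
treatment-effect ratios, adherence, and run settings — lives here as a
:class:`RangedValue` carrying a base-case value plus the low/high bounds
used by the deterministic and probabilistic sensitivity analyses.

The canonical base case is hard-coded in :func:`base_case_parameters`;
a YAML configuration file can override any subset of fields through
:func:`load_parameters`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Iterator, NamedTuple

import pandas as pd
import yaml

__all__ = [
    "Strategy",
    "RangedValue",
    "TransitionInputs",
    "UtilityInputs",
    "CostInputs",
    "EffectInputs",
    "ModelSettings",
    "ParameterSet",
    "Violation",
    "ConfigurationError",
    "ValidationError",
    "FIELD_REGISTRY",
    "base_case_parameters",
    "load_parameters",
    "validate_parameters",
    "parameters_to_dict",
    "parameters_from_dict",
    "save_parameters",
    "parameter_frame",
    "get_ranged",
    "set_ranged_base",
]

DAYS_PER_YEAR = 365.25


class ConfigurationError(ValueError):
    """A configuration file could not be parsed into a parameter set."""


class ValidationError(ValueError):
    """A parameter set violates one or more invariants.

    Carries the full list of violations, not just the first.
    """

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        msg = "; ".join(str(v) for v in violations)
        super().__init__(f"{len(violations)} parameter violation(s): {msg}")


class Strategy(enum.Enum):
    """The two treatment strategies compared by the model."""

    AS_NEEDED_ICS_FORMOTEROL = "as_needed_ics_formoterol"
    MAINTENANCE_ICS = "maintenance_ics"


class Violation(NamedTuple):
    field: str
    value: Any
    rule: str

    def __str__(self) -> str:  # pragma: no cover - formatting
        return f"{self.field}={self.value!r}: {self.rule}"


@dataclass(frozen=True)
class RangedValue:
    """A base-case value with the low/high range used in sensitivity analyses.

    ``low <= base <= high`` is required of a valid instance.  Source tables
    for this kind of model sometimes print the columns as high-then-low;
    :meth:`canonical` restores the ordering instead of failing.
    """

    base: float
    low: float
    high: float

    @classmethod
    def canonical(cls, base: float, low: float, high: float) -> "RangedValue":
        if low > high:
            low, high = high, low
        return cls(float(base), float(low), float(high))

    @classmethod
    def symmetric(cls, base: float, rel: float = 0.25) -> "RangedValue":
        """Range of +/- ``rel`` (default 25%) around the base value."""
        return cls(float(base), base * (1.0 - rel), base * (1.0 + rel))

    @classmethod
    def fixed(cls, base: float) -> "RangedValue":
        return cls(float(base), float(base), float(base))

    def as_dict(self) -> dict[str, float]:
        return {"base": self.base, "low": self.low, "high": self.high}


@dataclass(frozen=True)
class TransitionInputs:
    """Per-4-week-cycle transition probabilities of the natural history."""

    p_controlled_to_ocs_burst: RangedValue
    p_ocs_burst_to_ed: RangedValue
    p_ed_to_hospitalization: RangedValue
    p_hospitalization_to_asthma_death: RangedValue


@dataclass(frozen=True)
class UtilityInputs:
    """Annual utility weights (dimensionless, 1 = perfect health)."""

    u_controlled: RangedValue
    u_ocs_burst: RangedValue
    u_ed_visit: RangedValue
    u_hospitalization: RangedValue


@dataclass(frozen=True)
class CostInputs:
    """Unit costs in US dollars."""

    drug_cost_per_120_doses: RangedValue
    annual_cost_controlled: RangedValue
    cost_mild_exacerbation: RangedValue
    cost_moderate_exacerbation: RangedValue
    cost_severe_exacerbation: RangedValue


@dataclass(frozen=True)
class EffectInputs:
    """Treatment effects of as-needed budesonide-formoterol and dosing inputs."""

    rr_exacerbation: RangedValue
    or_ed_visit: RangedValue
    adherence_as_needed: RangedValue
    adherence_maintenance: RangedValue
    as_needed_doses_per_day: RangedValue


@dataclass(frozen=True)
class ModelSettings:
    """Run-level settings: cycle length, horizon, discounting, PSA controls."""

    cycle_length_days: int = 28
    annual_discount_rate: RangedValue = field(
        default_factory=lambda: RangedValue(0.05, 0.0, 0.06)
    )
    starting_age_years: int = 30
    horizon_age_years: int = 100
    half_cycle_correction: bool = True
    wtp_per_qaly: float = 19_000.0
    psa_iterations: int = 1_000
    rng_seed: int = 2021
    # how the 0.65 ED-visit effect is applied: as an odds ratio or a risk ratio
    ed_effect_scale: str = "odds"
    # if true, effect ratios are interpolated toward the null at zero adherence
    adherence_scales_effect: bool = False
    efs_landmark_years: float = 1.0


@dataclass(frozen=True)
class ParameterSet:
    transitions: TransitionInputs
    utilities: UtilityInputs
    costs: CostInputs
    effects: EffectInputs
    settings: ModelSettings


class FieldSpec(NamedTuple):
    """Registry entry for one ranged model input."""

    name: str          # flat configuration key
    group: str         # attribute of ParameterSet holding the value
    kind: str          # probability | utility | cost | ratio | fraction | rate | discount
    units: str
    source: str
    psa_family: str    # beta_ci | gamma_ci | beta_rescaled | dirichlet_row | fixed


#: Every ranged input of the model, in canonical (sampling) order.
FIELD_REGISTRY: tuple[FieldSpec, ...] = (
    FieldSpec("p_controlled_to_ocs_burst", "transitions", "probability",
              "per 4-week cycle", "clinical trials of as-needed budesonide-formoterol",
              "dirichlet_row"),
    FieldSpec("p_ocs_burst_to_ed", "transitions", "probability",
              "probability", "clinical trials of as-needed budesonide-formoterol",
              "dirichlet_row"),
    FieldSpec("p_ed_to_hospitalization", "transitions", "probability",
              "probability", "clinical trials; range +/-25%", "dirichlet_row"),
    FieldSpec("p_hospitalization_to_asthma_death", "transitions", "probability",
              "per cycle, conditional on hospitalization", "national statistics; range +/-25%",
              "dirichlet_row"),
    FieldSpec("u_controlled", "utilities", "utility", "annual weight",
              "systematic review of asthma utilities", "beta_ci"),
    FieldSpec("u_ocs_burst", "utilities", "utility", "annual weight",
              "systematic review of asthma utilities", "beta_ci"),
    FieldSpec("u_ed_visit", "utilities", "utility", "annual weight",
              "systematic review of asthma utilities", "beta_ci"),
    FieldSpec("u_hospitalization", "utilities", "utility", "annual weight",
              "systematic review of asthma utilities", "beta_ci"),
    FieldSpec("drug_cost_per_120_doses", "costs", "cost", "USD per 120 doses",
              "national drug price information system", "gamma_ci"),
    FieldSpec("annual_cost_controlled", "costs", "cost", "USD per year",
              "Colombian costing study", "gamma_ci"),
    FieldSpec("cost_mild_exacerbation", "costs", "cost", "USD per episode",
              "Colombian costing study", "gamma_ci"),
    FieldSpec("cost_moderate_exacerbation", "costs", "cost", "USD per episode",
              "Colombian costing study", "gamma_ci"),
    FieldSpec("cost_severe_exacerbation", "costs", "cost", "USD per episode",
              "Colombian costing study", "gamma_ci"),
    FieldSpec("rr_exacerbation", "effects", "ratio", "rate ratio",
              "meta-analysis of four RCTs (95% CI as range)", "beta_rescaled"),
    FieldSpec("or_ed_visit", "effects", "ratio", "odds ratio",
              "meta-analysis of four RCTs (95% CI as range)", "beta_rescaled"),
    FieldSpec("adherence_as_needed", "effects", "fraction", "fraction",
              "trial adherence data", "fixed"),
    FieldSpec("adherence_maintenance", "effects", "fraction", "fraction",
              "trial adherence data", "fixed"),
    FieldSpec("as_needed_doses_per_day", "effects", "rate", "doses per day",
              "trial dosing data", "fixed"),
    FieldSpec("annual_discount_rate", "settings", "discount", "per year",
              "national guideline (base 5%, range 0-6%)", "fixed"),
)

_REGISTRY_BY_NAME = {spec.name: spec for spec in FIELD_REGISTRY}

_SETTING_SCALARS = (
    "cycle_length_days",
    "starting_age_years",
    "horizon_age_years",
    "half_cycle_correction",
    "wtp_per_qaly",
    "psa_iterations",
    "rng_seed",
    "ed_effect_scale",
    "adherence_scales_effect",
    "efs_landmark_years",
)


def base_case_parameters() -> ParameterSet:
    """Return the hard-coded base-case parameter set.

    Ranges are the published sensitivity ranges; where the source leaves a
    range blank or unusable, a symmetric +/-25% band around the base value
    is applied (ED-visit-to-hospitalization probability and the asthma
    death probability).
    """
    transitions = TransitionInputs(
        p_controlled_to_ocs_burst=RangedValue(0.11, 0.10, 0.14),
        p_ocs_burst_to_ed=RangedValue(0.02, 0.02, 0.03),
        p_ed_to_hospitalization=RangedValue.symmetric(0.0117),
        p_hospitalization_to_asthma_death=RangedValue.symmetric(0.000002),
    )
    utilities = UtilityInputs(
        u_controlled=RangedValue(0.92, 0.69, 1.0),
        u_ocs_burst=RangedValue(0.86, 0.65, 1.0),
        u_ed_visit=RangedValue(0.83, 0.62, 1.0),
        u_hospitalization=RangedValue(0.74, 0.56, 0.93),
    )
    costs = CostInputs(
        drug_cost_per_120_doses=RangedValue(53.0, 40.0, 66.0),
        annual_cost_controlled=RangedValue(416.0, 312.0, 520.0),
        cost_mild_exacerbation=RangedValue(94.0, 71.0, 118.0),
        cost_moderate_exacerbation=RangedValue(191.0, 143.0, 239.0),
        cost_severe_exacerbation=RangedValue(386.0, 290.0, 483.0),
    )
    effects = EffectInputs(
        rr_exacerbation=RangedValue(0.85, 0.72, 1.00),
        or_ed_visit=RangedValue(0.65, 0.43, 0.98),
        adherence_as_needed=RangedValue(0.68, 0.51, 0.85),
        adherence_maintenance=RangedValue(0.62, 0.47, 0.78),
        as_needed_doses_per_day=RangedValue(0.52, 0.39, 0.65),
    )
    return ParameterSet(
        transitions=transitions,
        utilities=utilities,
        costs=costs,
        effects=effects,
        settings=ModelSettings(),
    )


# ---------------------------------------------------------------------------
# access helpers


def get_ranged(params: ParameterSet, name: str) -> RangedValue:
    """Look up a ranged input by its flat registry name."""
    spec = _REGISTRY_BY_NAME.get(name)
    if spec is None:
        raise KeyError(f"unknown ranged parameter {name!r}")
    return getattr(getattr(params, spec.group), name)


def set_ranged_base(params: ParameterSet, name: str, base: float) -> ParameterSet:
    """Return a copy of ``params`` with one input's base value replaced.

    The low/high range is widened if needed so the result stays valid;
    used by the one-way sensitivity analysis and the PSA.
    """
    spec = _REGISTRY_BY_NAME.get(name)
    if spec is None:
        raise KeyError(f"unknown ranged parameter {name!r}")
    old = get_ranged(params, name)
    new = RangedValue(float(base), min(old.low, base), max(old.high, base))
    group = getattr(params, spec.group)
    return replace(params, **{spec.group: replace(group, **{name: new})})


def iter_ranged(params: ParameterSet) -> Iterator[tuple[FieldSpec, RangedValue]]:
    for spec in FIELD_REGISTRY:
        yield spec, getattr(getattr(params, spec.group), spec.name)


# ---------------------------------------------------------------------------
# validation

_KIND_BOUNDS = {
    "probability": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "fraction": (0.0, 1.0),
    "discount": (0.0, 1.0),
    "cost": (0.0, None),
    "rate": (0.0, None),
    "ratio": (None, None),  # strictly positive, handled separately
}


def validate_parameters(params: ParameterSet) -> list[Violation]:
    """Check every invariant; return the full list of violations (never raises)."""
    out: list[Violation] = []
    for spec, rv in iter_ranged(params):
        if rv.low > rv.high:
            out.append(Violation(
                spec.name, (rv.low, rv.high),
                "low > high; the range appears column-swapped — normalize to low <= high",
            ))
        elif not (rv.low <= rv.base <= rv.high):
            out.append(Violation(spec.name, rv.base, "base outside [low, high]"))
        lo, hi = _KIND_BOUNDS[spec.kind]
        for part in ("base", "low", "high"):
            v = getattr(rv, part)
            if spec.kind == "ratio":
                if v <= 0:
                    out.append(Violation(f"{spec.name}.{part}", v, "ratio must be > 0"))
                continue
            if lo is not None and v < lo:
                out.append(Violation(f"{spec.name}.{part}", v, f"{spec.kind} < {lo}"))
            if hi is not None and v > hi:
                out.append(Violation(f"{spec.name}.{part}", v, f"{spec.kind} > {hi}"))
    s = params.settings
    if s.cycle_length_days <= 0:
        out.append(Violation("cycle_length_days", s.cycle_length_days, "must be positive"))
    if s.horizon_age_years <= s.starting_age_years:
        out.append(Violation(
            "horizon_age_years", s.horizon_age_years,
            "horizon must exceed starting age"))
    if s.psa_iterations < 1:
        out.append(Violation("psa_iterations", s.psa_iterations, "must be >= 1"))
    if s.wtp_per_qaly < 0:
        out.append(Violation("wtp_per_qaly", s.wtp_per_qaly, "must be >= 0"))
    if s.ed_effect_scale not in ("odds", "risk"):
        out.append(Violation("ed_effect_scale", s.ed_effect_scale,
                             "must be 'odds' or 'risk'"))
    if s.efs_landmark_years <= 0:
        out.append(Violation("efs_landmark_years", s.efs_landmark_years,
                             "must be positive"))
    return out


# ---------------------------------------------------------------------------
# (de)serialization


def parameters_to_dict(params: ParameterSet) -> dict[str, Any]:
    """Flat-key dict representation (the YAML configuration schema)."""
    out: dict[str, Any] = {}
    for spec, rv in iter_ranged(params):
        out[spec.name] = rv.as_dict()
    for key in _SETTING_SCALARS:
        out[key] = getattr(params.settings, key)
    return out


def _coerce_ranged(name: str, value: Any, default: RangedValue) -> RangedValue:
    if isinstance(value, dict):
        unknown = set(value) - {"base", "low", "high"}
        if unknown:
            raise ConfigurationError(
                f"key {name!r}: unknown sub-key(s) {sorted(unknown)}")
        try:
            base = float(value.get("base", default.base))
            low = float(value.get("low", default.low))
            high = float(value.get("high", default.high))
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"key {name!r}: non-numeric value") from exc
        return RangedValue.canonical(base, min(low, base), max(high, base)) \
            if "base" in value and not {"low", "high"} & set(value) \
            else RangedValue.canonical(base, low, high)
    if isinstance(value, (list, tuple)):
        if len(value) != 3:
            raise ConfigurationError(
                f"key {name!r}: expected [base, low, high], got {value!r}")
        base, low, high = (float(v) for v in value)
        return RangedValue.canonical(base, low, high)
    try:
        base = float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"key {name!r}: non-numeric value {value!r}") from exc
    # scalar override: move the range just enough to contain the new base
    return RangedValue(base, min(default.low, base), max(default.high, base))


def parameters_from_dict(data: dict[str, Any]) -> ParameterSet:
    """Build a ParameterSet from a flat-key dict, falling back to the base case.

    Raises :class:`ConfigurationError` on unknown keys or unparseable values
    and :class:`ValidationError` (listing every violation) if the merged set
    breaks an invariant.
    """
    defaults = base_case_parameters()
    if not isinstance(data, dict):
        raise ConfigurationError(f"configuration root must be a mapping, got {type(data).__name__}")
    groups = {g: dict() for g in ("transitions", "utilities", "costs", "effects")}
    settings_kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _REGISTRY_BY_NAME:
            spec = _REGISTRY_BY_NAME[key]
            default = getattr(getattr(defaults, spec.group), key)
            rv = _coerce_ranged(key, value, default)
            if spec.group == "settings":
                settings_kwargs[key] = rv
            else:
                groups[spec.group][key] = rv
        elif key in _SETTING_SCALARS:
            settings_kwargs[key] = value
        else:
            raise ConfigurationError(f"unknown configuration key {key!r}")
    params = ParameterSet(
        transitions=replace(defaults.transitions, **groups["transitions"]),
        utilities=replace(defaults.utilities, **groups["utilities"]),
        costs=replace(defaults.costs, **groups["costs"]),
        effects=replace(defaults.effects, **groups["effects"]),
        settings=replace(defaults.settings, **settings_kwargs),
    )
    violations = validate_parameters(params)
    if violations:
        raise ValidationError(violations)
    return params


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Load a parameter set from a YAML file; absent keys fall back to defaults."""
    path = Path(config_path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigurationError(f"cannot read configuration {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
    if data is None:
        data = {}
    return parameters_from_dict(data)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write the full flat-key YAML representation of a parameter set."""
    Path(path).write_text(
        yaml.safe_dump(parameters_to_dict(params), sort_keys=False))


def parameter_frame(params: ParameterSet) -> pd.DataFrame:
    """Parameter dump: one row per ranged input with units and source."""
    rows = [
        {"field": spec.name, "base": rv.base, "low": rv.low, "high": rv.high,
         "units": spec.units, "source": spec.source}
        for spec, rv in iter_ranged(params)
    ]
    return pd.DataFrame(rows, columns=["field", "base", "low", "high", "units", "source"])
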