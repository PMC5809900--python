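"""Typed parameter registry for the screening model.

Every model input is a printed value from the study's input tables, shipped as
versioned YAML files under :mod:`vfscreen.configs` so the package runs with zero
external data.  A :class:`ParameterSet` bundles the epidemiology (prevalence and
incidence of vertebral fractures), diagnostic accuracy of the two imaging tests,
unit costs, radiation doses and run controls for one sex and one scenario.

Incidence probabilities in the shipped tables are *total* (clinical plus
radiographic) probabilities, i.e. already scaled by the asymptomatic-to-
symptomatic ratio of 2.8; :func:`adjust_symptomatic_incidence` documents that
derivation but is never applied to the shipped values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = [
    "ParameterSet",
    "ConfigurationError",
    "ValidationError",
    "available_scenarios",
    "load_parameter_set",
    "adjust_symptomatic_incidence",
    "convert_cycle_probability",
    "univariate_variants",
]

SEXES = ("female", "male")


class ConfigurationError(KeyError):
    """A requested scenario/sex is not present in the configuration source."""


class ValidationError(ValueError):
    """A parameter value violates its domain invariant."""


_PROBABILITY_FIELDS = (
    "vf_prevalence",
    "vf_incidence",
    "new_vf_incidence",
    "vfa_sensitivity",
    "vfa_specificity",
    "p_vfa_unreadable",
    "xray_sensitivity",
    "xray_specificity",
)
_NONNEGATIVE_FIELDS = (
    "cost_vfa",
    "cost_xray",
    "cost_vf_treatment",
    "cost_physician_visit",
    "cost_drug_year",
    "cost_procedure",
    "dose_xray",
    "dose_vfa",
    "discount_rate",
)


@dataclass(frozen=True)
class ParameterSet:
    """All inputs for one (sex, scenario) model run.

    Probabilities are per model cycle of ``cycle_length`` years unless noted.
    ``rr_treatment`` multiplies ``new_vf_incidence`` while a patient is on
    anti-osteoporotic therapy.  Costs are euros per event; doses are
    microsievert per performed test.
    """

    sex: str
    scenario: str
    vf_prevalence: float
    vf_incidence: float
    new_vf_incidence: float
    rr_treatment: float
    vfa_sensitivity: float
    vfa_specificity: float
    p_vfa_unreadable: float
    cost_vfa: float
    cost_xray: float
    cost_vf_treatment: float
    cost_drug_year: float
    cost_procedure: float
    population_weight: float
    xray_sensitivity: float = 1.0
    xray_specificity: float = 1.0
    cost_physician_visit: float = 9.0
    dose_xray: float = 600.0
    dose_vfa: float = 25.0
    discount_rate: float = 0.05
    cycle_length: float = 2.0
    horizon: float = 10.0
    asymptomatic_ratio: float = 2.8
    cohort_size: int = 1000

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.rr_treatment <= 1.0:
            raise ValidationError(
                f"rr_treatment must lie in (0, 1], got {self.rr_treatment}"
            )
        for name in _NONNEGATIVE_FIELDS:
            v = getattr(self, name)
            if v < 0.0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.cycle_length <= 0 or self.horizon < 0:
            raise ValidationError("cycle_length must be > 0 and horizon >= 0")
        n = self.horizon / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"cycle_length {self.cycle_length} does not divide horizon {self.horizon}"
            )
        if self.asymptomatic_ratio <= 0:
            raise ValidationError("asymptomatic_ratio must be > 0")
        if self.cohort_size < 0:
            raise ValidationError("cohort_size must be >= 0")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))

    @property
    def symptomatic_fraction(self) -> float:
        """Fraction of incident VFs that are clinically recognised, 1/(1+ratio)."""
        return 1.0 / (1.0 + self.asymptomatic_ratio)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        return cls(**dict(d))


def _read_config(source) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    raise TypeError(f"unsupported config source: {type(source)!r}")


def _builtin_config(scenario: str) -> dict:
    ref = resources.files("vfscreen.configs").joinpath(f"{scenario}.yaml")
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; shipped scenarios: {available_scenarios()}"
        ) from None
    return yaml.safe_load(text)


def available_scenarios() -> list[str]:
    """Names of the configuration files shipped with the package."""
    root = resources.files("vfscreen.configs")
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_parameter_set(config_source=None, sex: str = "female",
                       scenario: str = "base_case") -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a configuration source.

    Parameters
    ----------
    config_source
        A mapping, a path to a YAML file, or ``None`` to use the shipped
        configuration named ``scenario``.
    sex
        ``"female"`` or ``"male"``.
    scenario
        Scenario label; with ``config_source=None`` this selects the shipped
        file (``base_case``, ``cycle_1y``, ``subgroup_old_age``).
    """
    if sex not in SEXES:
        raise ConfigurationError(f"unknown sex {sex!r}; expected one of {SEXES}")
    cfg = _builtin_config(scenario) if config_source is None else _read_config(config_source)
    if cfg.get("scenario", scenario) != scenario:
        raise ConfigurationError(
            f"config declares scenario {cfg.get('scenario')!r}, requested {scenario!r}"
        )
    if sex not in cfg:
        raise ConfigurationError(f"config for scenario {scenario!r} has no block for sex {sex!r}")
    values = dict(cfg.get("shared", {}))
    values.update(cfg[sex])
    values["sex"] = sex
    values["scenario"] = scenario
    known = {f.name for f in fields(ParameterSet)}
    unknown = set(values) - known
    if unknown:
        raise ConfigurationError(f"unknown parameter keys in config: {sorted(unknown)}")
    return ParameterSet(**values)


def adjust_symptomatic_incidence(symptomatic_probability: float, ratio: float = 2.8) -> float:
    """Scale a clinically-recognised VF probability to total (incl. radiographic) VFs.

    Claims data only record symptomatic fractures; the total probability is the
    symptomatic one multiplied by ``ratio`` (asymptomatic-to-symptomatic, 2.8).
    Shipped table values are already adjusted; this utility documents the
    derivation for users supplying their own claims-derived inputs.
    """
    if symptomatic_probability < 0:
        raise ValidationError("symptomatic_probability must be >= 0")
    if ratio <= 0:
        raise ValidationError("ratio must be > 0")
    total = symptomatic_probability * ratio
    if total > 1.0:
        raise ValidationError(
            f"adjusted probability {total} exceeds 1; inputs are inconsistent"
        )
    return total


def convert_cycle_probability(p: float, from_years: float, to_years: float) -> float:
    """Re-express a per-period probability for a different period length.

    Assumes a constant hazard: ``1 - (1 - p) ** (to_years / from_years)``.
    Printed one- and two-year table values are used directly at their native
    cycle lengths; this conversion only supports non-standard cycles.
    A probability of exactly 1 stays 1 for any positive target duration.
    """
    if from_years <= 0 or to_years <= 0:
        raise ValidationError("durations must be > 0")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    if p == 1.0:
        return 1.0
    return 1.0 - (1.0 - p) ** (to_years / from_years)


# Fields eligible for one-way variation, in the printed table's row order.
_UNIVARIATE_ORDER = (
    "vf_prevalence",
    "vf_incidence",
    "new_vf_incidence",
    "rr_treatment",
    "vfa_sensitivity",
    "vfa_specificity",
    "p_vfa_unreadable",
    "cost_vfa",
    "cost_xray",
    "cost_vf_treatment",
    "dose_vfa",
)


def univariate_variants(base: ParameterSet,
                        config_source=None) -> Iterator[tuple[str, ParameterSet]]:
    """Yield ``(field_name, variant)`` pairs for the one-way sensitivity analysis.

    Each variant differs from ``base`` in exactly one field, set to the
    bracketed alternative printed alongside the base value.  The base set is
    never mutated.
    """
    cfg = _builtin_config(base.scenario) if config_source is None else _read_config(config_source)
    try:
        brackets = cfg["univariate"][base.sex]
    except KeyError:
        raise ConfigurationError(
            f"scenario {base.scenario!r} has no univariate block for {base.sex!r}"
        ) from None
    unknown = set(brackets) - set(_UNIVARIATE_ORDER)
    if unknown:
        raise ConfigurationError(f"unexpected univariate fields: {sorted(unknown)}")
    for name in _UNIVARIATE_ORDER:
        if name in brackets:
            yield name, replace(base, scenario=f"{base.scenario}:{name}",
                                **{name: brackets[name]})
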