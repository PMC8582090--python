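"""Candidate-variable registry and unit conversions.

The cohort carries 19 candidate fall-risk variables spanning physical
fitness, body composition, physical activity, health condition and
environmental hazards.  Eight of them enter the multivariate fall model
("key factors"); all are registered here with their units, risk
direction, presentation precision and the scale applied before model
evaluation (physical-activity variables are modelled per 100 MET-min/wk).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional

__all__ = [
    "VariableSpec",
    "variable_registry",
    "registry_names",
    "key_factor_specs",
    "get_spec",
    "met_to_model_units",
    "met_round_up_hundred",
    "round_to_precision",
    "precision_step",
    "registry_to_json",
    "KEY_FACTOR_ORDER",
]

#: Canonical key-factor order, matching the multivariate model equation:
#: balance, lean mass, fat mass, total PA, vigorous PA, rest period,
#: health conditions, environmental hazards.
KEY_FACTOR_ORDER: tuple[str, ...] = (
    "multidimensional_balance",
    "lean_body_mass",
    "fat_body_mass",
    "total_physical_activity",
    "vigorous_physical_activity",
    "rest_period_weekdays",
    "health_conditions",
    "environmental_hazards",
)


@dataclass(frozen=True)
class VariableSpec:
    """Static description of one candidate variable.

    Parameters
    ----------
    name:
        Canonical snake_case identifier used in file headers and DataFrames.
    label:
        Human-readable label (the field-instrument name).
    units:
        Natural measurement units.
    direction:
        ``"protective"`` if a higher value lowers the probability of
        falling, ``"risk"`` otherwise.
    precision:
        Presentation granularity: ``"integer"``, ``"one-decimal"`` or
        ``"hundred-met"`` (MET-min/wk rounded up to the next hundred).
    model_scale:
        Multiplicative factor applied before model evaluation (0.01 for
        physical-activity variables, 1.0 otherwise).
    key_symbol:
        Single-letter symbol in the model equation for the eight key
        factors (B, L, F, TPA, VPA, R, HC, H); ``None`` otherwise.
    lower, upper:
        Plausible bounds in natural units (``None`` = unbounded).
    integer:
        Whether the variable is integer-valued in natural units.
    """

    name: str
    label: str
    units: str
    direction: str
    precision: str
    model_scale: float = 1.0
    key_symbol: Optional[str] = None
    lower: Optional[float] = None
    upper: Optional[float] = None
    integer: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("protective", "risk"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.precision not in ("integer", "one-decimal", "hundred-met"):
            raise ValueError(f"invalid precision {self.precision!r}")
        if not self.model_scale > 0:
            raise ValueError("model_scale must be strictly positive")

    @property
    def is_key_factor(self) -> bool:
        return self.key_symbol is not None


_REGISTRY: tuple[VariableSpec, ...] = (
    VariableSpec("lower_body_strength", "Lower body strength", "rep",
                 "protective", "integer", lower=0, integer=True),
    VariableSpec("upper_body_strength", "Upper body strength", "rep",
                 "protective", "integer", lower=0, integer=True),
    VariableSpec("lower_body_flexibility", "Lower body flexibility", "cm",
                 "risk", "one-decimal"),
    VariableSpec("upper_body_flexibility", "Upper body flexibility", "cm",
                 "protective", "one-decimal"),
    VariableSpec("agility_dynamic_balance", "Agility and dynamic balance", "sec",
                 "risk", "one-decimal", lower=0),
    VariableSpec("aerobic_endurance", "Aerobic endurance", "m",
                 "protective", "integer", lower=0, integer=True),
    VariableSpec("multidimensional_balance", "Multidimensional balance score", "point",
                 "protective", "integer", key_symbol="B",
                 lower=0, upper=40, integer=True),
    VariableSpec("body_weight", "Body weight", "kg",
                 "protective", "one-decimal", lower=0),
    VariableSpec("body_height", "Body height", "cm",
                 "protective", "one-decimal", lower=0),
    VariableSpec("body_mass_index", "Body mass index", "kg/m2",
                 "risk", "one-decimal", lower=0),
    VariableSpec("lean_body_mass", "Lean body mass", "kg",
                 "protective", "integer", key_symbol="L", lower=0),
    VariableSpec("fat_body_mass", "Fat body mass", "%",
                 "risk", "integer", key_symbol="F", lower=0, upper=100),
    VariableSpec("walking_physical_activity", "Walking physical activity", "MET-min/wk",
                 "protective", "hundred-met", model_scale=0.01, lower=0),
    VariableSpec("moderate_physical_activity", "Moderate physical activity", "MET-min/wk",
                 "protective", "hundred-met", model_scale=0.01, lower=0),
    VariableSpec("vigorous_physical_activity", "Vigorous physical activity", "MET-min/wk",
                 "risk", "hundred-met", model_scale=0.01, key_symbol="VPA", lower=0),
    VariableSpec("total_physical_activity", "Total physical activity", "MET-min/wk",
                 "protective", "hundred-met", model_scale=0.01, key_symbol="TPA", lower=0),
    VariableSpec("rest_period_weekdays", "Rest period weekdays", "hr/day",
                 "risk", "one-decimal", key_symbol="R", lower=0, upper=24),
    VariableSpec("health_conditions", "Health conditions", "count",
                 "risk", "integer", key_symbol="HC", lower=0, integer=True),
    VariableSpec("environmental_hazards", "Environmental hazards", "count",
                 "risk", "integer", key_symbol="H", lower=0, upper=34, integer=True),
)

_BY_NAME = {spec.name: spec for spec in _REGISTRY}
assert len(_BY_NAME) == len(_REGISTRY), "registry names must be unique"


def variable_registry() -> tuple[VariableSpec, ...]:
    """Return the 19 candidate variables in canonical order."""
    return _REGISTRY


def registry_names() -> tuple[str, ...]:
    return tuple(spec.name for spec in _REGISTRY)


def key_factor_specs() -> tuple[VariableSpec, ...]:
    """The eight key-model variables in model-equation order."""
    return tuple(_BY_NAME[name] for name in KEY_FACTOR_ORDER)


def get_spec(name: str) -> VariableSpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown variable {name!r}; known: {sorted(_BY_NAME)}") from None


def met_to_model_units(met: float) -> float:
    """Convert MET-min/wk to the model's 100 MET-min/wk units (unrounded)."""
    if met < 0:
        raise ValueError(f"MET-min/wk must be non-negative, got {met}")
    return met / 100.0


def met_round_up_hundred(met: float) -> float:
    """Round MET-min/wk up to the nearest hundred (1887 -> 1900)."""
    if met < 0:
        raise ValueError(f"MET-min/wk must be non-negative, got {met}")
    up = 100.0 * math.ceil(met / 100.0)
    if up < met:  # guard against rounding in the division
        up += 100.0
    return up


def precision_step(precision: str) -> float:
    """Smallest representable increment for a presentation precision."""
    return {"integer": 1.0, "one-decimal": 0.1, "hundred-met": 100.0}[precision]


def round_to_precision(value: float, precision: str) -> float:
    """Round a continuous value to presentation precision.

    Integers and tenths use round-half-away-from-zero; MET values are
    always rounded *up* to the next hundred, following the presentation
    convention for physical-activity units.
    """
    if precision == "hundred-met":
        return met_round_up_hundred(value)
    step = precision_step(precision)
    out = math.floor(abs(value) / step + 0.5) * step * (1 if value >= 0 else -1)
    return round(out, 10)


def registry_to_json(path=None) -> str:
    """Serialize the registry as a JSON document (optionally to ``path``)."""
    doc = json.dumps([asdict(s) for s in _REGISTRY], indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(doc)
    return doc
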