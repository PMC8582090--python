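"""Individual risk profiling against a cutoff table.

Given one person's eight key-factor measurements: per-factor strata,
the model probability of falling with its overall stratum, and the
minimum improvement per factor needed to reach each lower-risk stratum
(e.g. a balance score of 29 — very high risk — needs +1 point to reach
high risk, +3 to moderate, +5 to low).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np

from .model import FittedLogisticModel, published_model
from .registry import KEY_FACTOR_ORDER, get_spec, precision_step
from .stratify import STRATA, CutoffTable, CutProbabilities, FactorCutoffs

__all__ = [
    "RiskProfile",
    "classify_factor",
    "individual_probability",
    "improvement_deltas",
    "profile_report",
]


def classify_factor(value: float, factor: str, table: CutoffTable) -> str:
    """Stratum whose presented interval contains ``value`` (direction-aware).

    Values outside the factor's plausible range are clamped with a
    warning before classification.
    """
    fc = table[factor]
    spec = get_spec(factor)
    lo = -np.inf if spec.lower is None else spec.lower
    hi = np.inf if spec.upper is None else spec.upper
    if not lo <= value <= hi:
        clamped = float(np.clip(value, lo, hi))
        warnings.warn(
            f"{factor} value {value} outside [{lo}, {hi}]; clamped to {clamped}",
            stacklevel=2,
        )
        value = clamped
    return fc.classify(value)


def individual_probability(model: FittedLogisticModel,
                           measurements: Mapping[str, float]) -> float:
    """Falling probability from natural-unit key-factor measurements."""
    missing = [v for v in model.variables if v not in measurements]
    if missing:
        raise ValueError(f"missing measurements for: {missing}")
    return float(np.atleast_1d(model.predict_proba(dict(measurements)))[0])


def improvement_deltas(measurements: Mapping[str, float], factor: str,
                       table: CutoffTable) -> Dict[str, float]:
    """Minimum sign-aware change moving ``factor`` into each better stratum.

    Deltas are in the factor's representable precision steps (1 point,
    1 kg, 1 %, 100 MET-min/wk, 0.1 h, 1 count); an empty map means the
    factor is already at low risk.
    """
    fc: FactorCutoffs = table[factor]
    spec = get_spec(factor)
    step = precision_step(spec.precision)
    value = float(measurements[factor])
    current = fc.classify(value)
    intervals = fc.stratum_intervals()
    out: Dict[str, float] = {}
    for target in STRATA[:STRATA.index(current)]:
        lo, hi = intervals[target]
        if fc.direction == "protective":
            # improvement = increase up to the stratum's lower edge
            edge = lo if lo is not None else hi
            delta = edge - value
        else:
            # improvement = decrease down to the stratum's upper edge
            edge = hi if hi is not None else lo
            delta = edge - value
        # snap to representable steps, away from the current value
        delta = np.sign(delta) * np.ceil(abs(delta) / step - 1e-9) * step
        out[target] = float(round(delta, 10))
    return out


@dataclass
class RiskProfile:
    """One person's stratified fall-risk assessment."""

    inputs: Dict[str, float]
    per_factor_stratum: Dict[str, str]
    probability: float
    overall_stratum: str
    deltas: Dict[str, Dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "per_factor_stratum": self.per_factor_stratum,
            "probability": self.probability,
            "overall_stratum": self.overall_stratum,
            "deltas": self.deltas,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, doc: str) -> "RiskProfile":
        return cls(**json.loads(doc))

    def to_text(self) -> str:
        lines = [
            f"Probability of falling: {self.probability:.3f} "
            f"({self.overall_stratum.replace('_', ' ')} risk)",
            "Per-factor profile:",
        ]
        for name, stratum in self.per_factor_stratum.items():
            spec = get_spec(name)
            line = (f"  {spec.label}: {self.inputs[name]:g} {spec.units} "
                    f"-> {stratum.replace('_', ' ')} risk")
            d = self.deltas.get(name)
            if d:
                moves = ", ".join(
                    f"{v:+g} to {k.replace('_', ' ')}" for k, v in d.items()
                )
                line += f" (improve: {moves})"
            lines.append(line)
        return "\n".join(lines)


def _overall_stratum(pi: float, cuts: CutProbabilities) -> str:
    edges = np.array(cuts.as_tuple())
    return STRATA[int(np.searchsorted(edges, pi, side="right"))]


def profile_report(model: Optional[FittedLogisticModel],
                   table: CutoffTable,
                   measurements: Mapping[str, float]) -> RiskProfile:
    """Full individual assessment: strata, probability, improvement deltas."""
    model = model if model is not None else published_model()
    pi = individual_probability(model, measurements)
    per_factor = {
        name: classify_factor(float(measurements[name]), name, table)
        for name in KEY_FACTOR_ORDER if name in table.factors
    }
    deltas = {
        name: improvement_deltas(measurements, name, table)
        for name in per_factor
    }
    inputs = {k: float(v) for k, v in measurements.items()}
    return RiskProfile(
        inputs=inputs,
        per_factor_stratum=per_factor,
        probability=pi,
        overall_stratum=_overall_stratum(pi, table.cuts),
        deltas=deltas,
    )
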