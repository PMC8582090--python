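"""Percentile anchors and quantile reconstruction.

Each variable's marginal distribution is summarised by five printed
percentile anchors (1st/25th/50th/75th/99th).  The full quantile
function is reconstructed by piecewise-linear interpolation between
anchors; for data generation the tails beyond the 1st/99th anchors are
extended linearly with the nearest segment's slope and truncated at
physical bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np

from .cohort import Cohort
from .registry import VariableSpec, get_spec, variable_registry

__all__ = [
    "QuantileAnchors",
    "default_anchors",
    "interp_quantile",
    "extended_quantile",
    "anchors_from_cohort",
    "DEFAULT_ANCHOR_PERCENTILES",
]

DEFAULT_ANCHOR_PERCENTILES = (1.0, 25.0, 50.0, 75.0, 99.0)


@dataclass(frozen=True)
class QuantileAnchors:
    """Anchor set (percentile rank -> value) for one variable."""

    variable: str
    anchor_percentiles: tuple[float, ...] = DEFAULT_ANCHOR_PERCENTILES
    anchor_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.anchor_percentiles, dtype=float)
        v = np.asarray(self.anchor_values, dtype=float)
        if len(p) != len(v) or len(p) < 2:
            raise ValueError(
                f"{self.variable}: need matching percentile/value anchors (>=2)"
            )
        if np.any(np.diff(p) <= 0) or p[0] <= 0 or p[-1] >= 100:
            raise ValueError(
                f"{self.variable}: percentile ranks must be strictly increasing in (0, 100)"
            )
        if np.any(np.diff(v) < 0):
            raise ValueError(
                f"{self.variable}: anchor values must be non-decreasing"
            )


# Printed cohort percentiles (n = 500) for the 19 candidate variables.
_DEFAULT_VALUES: Dict[str, tuple[float, ...]] = {
    "lower_body_strength": (7, 13, 15, 18, 30),
    "upper_body_strength": (6, 13, 17, 20, 29),
    "lower_body_flexibility": (-32.0, -8.0, 0.0, 3.0, 18.5),
    "upper_body_flexibility": (-37.0, -18.0, -10.0, -2.0, 13.0),
    "agility_dynamic_balance": (3.9, 5.1, 5.7, 6.6, 12.2),
    "aerobic_endurance": (240, 438, 499, 550, 714),
    "multidimensional_balance": (12, 28, 32, 35, 40),
    "body_weight": (44.9, 61.0, 68.6, 77.4, 108.1),
    "body_height": (137.0, 150.0, 155.0, 162.9, 176.0),
    "body_mass_index": (20.5, 25.6, 28.0, 31.1, 39.6),
    "lean_body_mass": (26.3, 37.1, 42.2, 48.9, 67.9),
    "fat_body_mass": (15.5, 32.6, 38.3, 43.3, 48.5),
    "walking_physical_activity": (0, 297, 578, 990, 2772),
    "moderate_physical_activity": (0, 960, 1680, 2400, 10080),
    "vigorous_physical_activity": (0, 0, 0, 0, 7200),
    "total_physical_activity": (170, 1646, 2473, 3884, 12797),
    "rest_period_weekdays": (0.6, 3.0, 4.3, 5.5, 10.0),
    "health_conditions": (0, 2, 3, 5, 12),
    "environmental_hazards": (0, 4, 6, 9, 21),
}


def default_anchors() -> Dict[str, QuantileAnchors]:
    """The printed anchor sets for all 19 candidate variables."""
    return {
        name: QuantileAnchors(name, DEFAULT_ANCHOR_PERCENTILES, tuple(float(x) for x in vals))
        for name, vals in _DEFAULT_VALUES.items()
    }


def interp_quantile(anchors: QuantileAnchors, p: float) -> float:
    """Piecewise-linear quantile at percentile rank ``p`` in [1, 99].

    Exact at the anchors and monotone non-decreasing in ``p``.
    """
    lo, hi = anchors.anchor_percentiles[0], anchors.anchor_percentiles[-1]
    if not (lo <= p <= hi):
        raise ValueError(
            f"{anchors.variable}: percentile {p} outside anchored range [{lo}, {hi}]"
        )
    return float(
        np.interp(p, anchors.anchor_percentiles, anchors.anchor_values)
    )


def extended_quantile(
    anchors: QuantileAnchors,
    p,
    spec: Optional[VariableSpec] = None,
):
    """Quantile over (0, 100), extending linearly beyond the outer anchors.

    Below the first / above the last anchor the nearest segment's slope
    is continued; the result is truncated at the variable's physical
    bounds when a spec is given.  Vectorised over ``p``.
    """
    pa = np.asarray(anchors.anchor_percentiles, dtype=float)
    va = np.asarray(anchors.anchor_values, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.interp(p, pa, va)
    lo_slope = (va[1] - va[0]) / (pa[1] - pa[0])
    hi_slope = (va[-1] - va[-2]) / (pa[-1] - pa[-2])
    below = p < pa[0]
    above = p > pa[-1]
    out = np.where(below, va[0] + lo_slope * (p - pa[0]), out)
    out = np.where(above, va[-1] + hi_slope * (p - pa[-1]), out)
    if spec is None:
        try:
            spec = get_spec(anchors.variable)
        except KeyError:
            spec = None
    if spec is not None:
        lo = -np.inf if spec.lower is None else spec.lower
        hi = np.inf if spec.upper is None else spec.upper
        out = np.clip(out, lo, hi)
    return out if out.ndim else float(out)


def anchors_from_cohort(
    cohort: Cohort,
    percentiles: Iterable[float] = DEFAULT_ANCHOR_PERCENTILES,
) -> Dict[str, QuantileAnchors]:
    """Empirical anchor sets (linear-interpolation quantile definition)."""
    pct = tuple(float(p) for p in percentiles)
    out = {}
    for spec in cohort.registry:
        vals = np.percentile(cohort.values(spec.name), pct, method="linear")
        out[spec.name] = QuantileAnchors(spec.name, pct, tuple(float(v) for v in vals))
    return out


def _check_registry_coverage(anchors: Dict[str, QuantileAnchors]) -> None:
    missing = [s.name for s in variable_registry() if s.name not in anchors]
    if missing:
        raise ValueError(f"anchor sets missing for: {missing}")
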