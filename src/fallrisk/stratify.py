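"""Model inversion along the joint risk-profile percentile curve.

The probability cutoffs pi = 0.25 (low/moderate), the Youden cutoff
(moderate/high, study value 0.35939) and pi = 0.50 (high/very high) are
turned into per-factor interval reference values by solving the model
along a one-parameter family of covariate vectors: at profile
percentile p the protective factors (balance, lean mass, total PA) take
their p-th percentile and the risk factors (fat mass, rest period,
health conditions, hazards) their (100-p)-th percentile, with vigorous
PA identically zero across the relevant band.  The probability along
this curve is strictly decreasing in p, so each cut probability has a
unique percentile root; each factor's quantile at the root, rounded to
the factor's presentation precision, is its stratum boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .anchors import QuantileAnchors, anchors_from_cohort, default_anchors, interp_quantile
from .cohort import Cohort
from .model import FittedLogisticModel, published_model
from .registry import (
    KEY_FACTOR_ORDER,
    get_spec,
    precision_step,
    round_to_precision,
)

__all__ = [
    "CutProbabilities",
    "RiskFactorVector",
    "FactorCutoffs",
    "CutoffTable",
    "build_profile",
    "profile_probability",
    "solve_percentile",
    "derive_cutoffs",
    "present_cutoffs",
    "RiskStratifier",
    "STRATA",
    "STUDY_YOUDEN_CUTOFF",
]

STRATA = ("low", "moderate", "high", "very_high")
STUDY_YOUDEN_CUTOFF = 0.35939

#: Key factors at percentile p on the profile curve (higher value = safer).
PROTECTIVE_PROFILE = ("multidimensional_balance", "lean_body_mass",
                      "total_physical_activity")
#: Key factors at percentile 100 - p (higher value = riskier).
RISK_PROFILE = ("fat_body_mass", "rest_period_weekdays",
                "health_conditions", "environmental_hazards")


@dataclass(frozen=True)
class CutProbabilities:
    """The three probability cutoffs separating the four risk strata."""

    low_mod: float = 0.25
    mod_high: float = STUDY_YOUDEN_CUTOFF
    high_vhigh: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 < self.low_mod < self.mod_high < self.high_vhigh < 1.0:
            raise ValueError(
                "cut probabilities must satisfy 0 < low_mod < mod_high < high_vhigh < 1"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.low_mod, self.mod_high, self.high_vhigh)


@dataclass(frozen=True)
class RiskFactorVector:
    """The eight model covariates in model units (PA per 100 MET-min/wk)."""

    B: float
    L: float
    F: float
    TPA: float
    VPA: float
    R: float
    HC: float
    H: float

    def __post_init__(self) -> None:
        vals = [self.B, self.L, self.F, self.TPA, self.VPA, self.R, self.HC, self.H]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all risk-factor values must be finite")
        if not (self.TPA >= self.VPA >= 0):
            raise ValueError("need TPA >= VPA >= 0")
        if not 0 <= self.B <= 40:
            raise ValueError("balance score must lie in [0, 40]")

    def as_frame(self) -> pd.DataFrame:
        """Natural-unit one-row DataFrame (PA back in MET-min/wk)."""
        return pd.DataFrame({
            "multidimensional_balance": [self.B],
            "lean_body_mass": [self.L],
            "fat_body_mass": [self.F],
            "total_physical_activity": [self.TPA * 100.0],
            "vigorous_physical_activity": [self.VPA * 100.0],
            "rest_period_weekdays": [self.R],
            "health_conditions": [self.HC],
            "environmental_hazards": [self.H],
        })


def build_profile(anchors: Mapping[str, QuantileAnchors], p: float) -> RiskFactorVector:
    """Joint risk-profile covariate vector at profile percentile ``p``.

    Protective factors at their p-th percentile, risk factors at the
    (100-p)-th, vigorous PA fixed at zero (only the top fifth of the
    cohort performs any, so it is identically zero on the profile band).
    """
    q = {name: interp_quantile(anchors[name], p) for name in PROTECTIVE_PROFILE}
    q.update({name: interp_quantile(anchors[name], 100.0 - p) for name in RISK_PROFILE})
    return RiskFactorVector(
        B=q["multidimensional_balance"],
        L=q["lean_body_mass"],
        F=q["fat_body_mass"],
        TPA=q["total_physical_activity"] / 100.0,
        VPA=0.0,
        R=q["rest_period_weekdays"],
        HC=q["health_conditions"],
        H=q["environmental_hazards"],
    )


def _check_sign_consistency(model: FittedLogisticModel) -> None:
    """The profile probability is monotone only if every coefficient's
    sign matches the factor's registered direction."""
    for name, beta in zip(model.variables, model.coefficients):
        if name == "vigorous_physical_activity":
            continue  # fixed at zero on the profile
        direction = get_spec(name).direction
        if direction == "protective" and beta > 0 or direction == "risk" and beta < 0:
            raise ValueError(
                f"model coefficient for {name!r} ({beta:+g}) contradicts its "
                f"{direction} direction; profile probability would not be monotone"
            )


def profile_probability(model: FittedLogisticModel,
                        anchors: Mapping[str, QuantileAnchors],
                        p: float) -> float:
    """Falling probability of the joint profile at percentile ``p``."""
    _check_sign_consistency(model)
    vec = build_profile(anchors, p)
    return float(np.atleast_1d(model.predict_proba(vec.as_frame()))[0])


def solve_percentile(model: FittedLogisticModel,
                     anchors: Mapping[str, QuantileAnchors],
                     c: float, tol: float = 1e-10) -> float:
    """Profile percentile where the falling probability equals ``c``.

    Unique by monotonicity; bisection on [1, 99] until |pi - c| < tol.
    """
    _check_sign_consistency(model)

    def pi(p: float) -> float:
        return float(np.atleast_1d(model.predict_proba(build_profile(anchors, p).as_frame()))[0])

    hi_pi, lo_pi = pi(1.0), pi(99.0)
    if not lo_pi < c < hi_pi:
        raise ValueError(
            f"cut probability {c} outside the attainable profile range "
            f"({lo_pi:.6f} at p=99, {hi_pi:.6f} at p=1)"
        )
    a, b = 1.0, 99.0
    for _ in range(200):
        mid = 0.5 * (a + b)
        val = pi(mid)
        if abs(val - c) < tol:
            return mid
        if val > c:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


@dataclass
class FactorCutoffs:
    """One key factor's boundaries and presented strata.

    ``boundaries`` and ``rounded`` are ordered by cut probability
    (low/mod, mod/high, high/very-high); for protective factors the
    values decrease along that order, for risk factors they increase.
    """

    factor: str
    direction: str
    boundaries: tuple[float, float, float]
    rounded: tuple[float, float, float]
    percentile_roots: Dict[float, float]

    def classify(self, value: float) -> str:
        b1, b2, b3 = self.rounded
        if self.direction == "protective":
            if value > b1:
                return "low"
            if value > b2:
                return "moderate"
            if value > b3:
                return "high"
            return "very_high"
        if value < b1:
            return "low"
        if value <= b2:
            return "moderate"
        if value <= b3:
            return "high"
        return "very_high"

    def stratum_intervals(self) -> Dict[str, tuple[Optional[float], Optional[float]]]:
        """Inclusive representable (lo, hi) per stratum; None = unbounded."""
        b1, b2, b3 = self.rounded
        s = precision_step(get_spec(self.factor).precision)
        if self.direction == "protective":
            return {
                "low": (b1 + s, None),
                "moderate": (b2 + s, b1),
                "high": (b3 + s, b2),
                "very_high": (None, b3),
            }
        return {
            "low": (None, b1 - s),
            "moderate": (b1, b2),
            "high": (b2 + s, b3),
            "very_high": (b3 + s, None),
        }


@dataclass
class CutoffTable:
    """Per-factor interval reference values for the four risk strata."""

    cuts: CutProbabilities
    factors: Dict[str, FactorCutoffs]
    percentile_roots: Dict[float, float] = field(default_factory=dict)

    def __getitem__(self, factor: str) -> FactorCutoffs:
        return self.factors[factor]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fc in self.factors.values():
            rows.append({
                "factor": fc.factor,
                "direction": fc.direction,
                "boundary_low_mod": fc.boundaries[0],
                "boundary_mod_high": fc.boundaries[1],
                "boundary_high_vhigh": fc.boundaries[2],
                "rounded_low_mod": fc.rounded[0],
                "rounded_mod_high": fc.rounded[1],
                "rounded_high_vhigh": fc.rounded[2],
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "cut_probabilities": list(self.cuts.as_tuple()),
            "percentile_roots": {str(k): v for k, v in self.percentile_roots.items()},
            "factors": {
                name: {
                    "direction": fc.direction,
                    "boundaries": list(fc.boundaries),
                    "rounded": list(fc.rounded),
                    "strata": {
                        s: list(iv) for s, iv in fc.stratum_intervals().items()
                    },
                }
                for name, fc in self.factors.items()
            },
        }


def derive_cutoffs(model: FittedLogisticModel,
                   anchors: Mapping[str, QuantileAnchors],
                   cuts: CutProbabilities = CutProbabilities()) -> CutoffTable:
    """Invert the model at the three cut probabilities.

    For each cut, the profile percentile root p* is found by bisection;
    each protective factor is then evaluated at p*, each risk factor at
    100 - p* (complement symmetry is exact by construction), and the
    continuous boundary rounded to the factor's presentation precision.
    Vigorous PA is excluded: it is identically zero over the band.
    """
    roots = {c: solve_percentile(model, anchors, c) for c in cuts.as_tuple()}
    factors: Dict[str, FactorCutoffs] = {}
    for name in PROTECTIVE_PROFILE + RISK_PROFILE:
        spec = get_spec(name)
        if spec.direction == "protective":
            bounds = tuple(interp_quantile(anchors[name], roots[c]) for c in cuts.as_tuple())
        else:
            bounds = tuple(interp_quantile(anchors[name], 100.0 - roots[c]) for c in cuts.as_tuple())
        rounded = tuple(round_to_precision(b, spec.precision) for b in bounds)
        _check_ordered(name, spec.direction, bounds)
        factors[name] = FactorCutoffs(
            factor=name, direction=spec.direction,
            boundaries=bounds, rounded=rounded,
            percentile_roots=dict(roots),
        )
    # keep the canonical key-factor presentation order
    ordered = {n: factors[n] for n in KEY_FACTOR_ORDER if n in factors}
    return CutoffTable(cuts=cuts, factors=ordered, percentile_roots=roots)


def _check_ordered(name: str, direction: str, bounds: tuple[float, ...]) -> None:
    b = np.asarray(bounds)
    ok = np.all(np.diff(b) < 0) if direction == "protective" else np.all(np.diff(b) > 0)
    if not ok:
        raise ValueError(f"{name}: boundaries {bounds} not ordered along the risk direction")


def _fmt(value: float, precision: str) -> str:
    if precision == "one-decimal":
        return f"{value:.1f}"
    return f"{value:.0f}"


def present_cutoffs(table: CutoffTable) -> str:
    """Human-readable four-interval report, one line per factor.

    Extreme strata are rendered as open inequalities against the
    adjacent boundary (e.g. balance "low risk: > 33 ... very high: < 30");
    interior strata as inclusive ranges at the factor's precision, a
    singleton collapsing to a single value.
    """
    lines = []
    for fc in table.factors.values():
        spec = get_spec(fc.factor)
        s = precision_step(spec.precision)
        b1, b2, b3 = fc.rounded
        if fc.direction == "protective":
            parts = [
                f"low risk: > {_fmt(b1, spec.precision)}",
                _range_text("moderate risk", b2 + s, b1, spec.precision),
                _range_text("high risk", b3 + s, b2, spec.precision),
                f"very high risk: < {_fmt(b3 + s, spec.precision)}",
            ]
        else:
            parts = [
                f"low risk: < {_fmt(b1, spec.precision)}",
                _range_text("moderate risk", b1, b2, spec.precision),
                _range_text("high risk", b2 + s, b3, spec.precision),
                f"very high risk: > {_fmt(b3, spec.precision)}",
            ]
        lines.append(f"{spec.label} ({spec.units}) - " + ", ".join(parts))
    return "\n".join(lines)


def _range_text(label: str, lo: float, hi: float, precision: str) -> str:
    if np.isclose(lo, hi):
        return f"{label}: {_fmt(lo, precision)}"
    return f"{label}: {_fmt(lo, precision)}–{_fmt(hi, precision)}"


class RiskStratifier(BaseEstimator):
    """Derive a cutoff table and classify individuals against it.

    Parameters
    ----------
    model : FittedLogisticModel or None
        Probability model to invert; the published equation by default.
    cuts : CutProbabilities or None
        In ``mode="reproduce"`` (default) the study cutoffs
        (0.25 / 0.35939 / 0.50); in ``mode="re-derive"`` the middle cut
        is replaced by the Youden cutoff computed from the cohort passed
        to :meth:`fit`, and the anchors by the cohort's empirical
        quantiles.
    mode : {"reproduce", "re-derive"}

    Attributes
    ----------
    cutoff_table_ : CutoffTable
    percentile_roots_ : dict
        Cut probability -> profile percentile root.
    """

    def __init__(self, model: Optional[FittedLogisticModel] = None,
                 cuts: Optional[CutProbabilities] = None,
                 mode: str = "reproduce"):
        self.model = model
        self.cuts = cuts
        self.mode = mode

    def fit(self, X: Optional[Cohort] = None, y=None) -> "RiskStratifier":
        if self.mode not in ("reproduce", "re-derive"):
            raise ValueError("mode must be 'reproduce' or 're-derive'")
        model = self.model if self.model is not None else published_model()
        cuts = self.cuts
        if self.mode == "re-derive":
            if X is None:
                raise ValueError("re-derive mode needs a cohort")
            from .discrimination import youden_cutoff

            anchors = anchors_from_cohort(X)
            if cuts is None:
                scores = np.atleast_1d(model.predict_proba(X.data))
                mid, _, _ = youden_cutoff(scores, X.outcome)
                cuts = CutProbabilities(mod_high=float(mid))
        else:
            anchors = default_anchors()
            if cuts is None:
                cuts = CutProbabilities()
        self.anchors_ = anchors
        self.model_ = model
        self.cutoff_table_ = derive_cutoffs(model, anchors, cuts)
        self.percentile_roots_ = self.cutoff_table_.percentile_roots
        return self

    def transform(self, X) -> pd.DataFrame:
        """Per-factor strata for rows of natural-unit measurements."""
        df = X.data if isinstance(X, Cohort) else pd.DataFrame(X)
        out = {}
        for name, fc in self.cutoff_table_.factors.items():
            out[name] = [fc.classify(v) for v in np.asarray(df[name], dtype=float)]
        return pd.DataFrame(out, index=df.index)

    def predict(self, X) -> np.ndarray:
        """Overall stratum from the model probability and the cuts."""
        df = X.data if isinstance(X, Cohort) else pd.DataFrame(X)
        pi = np.atleast_1d(self.model_.predict_proba(df))
        cuts = self.cutoff_table_.cuts
        edges = np.array(cuts.as_tuple())
        return np.array(STRATA)[np.searchsorted(edges, pi, side="right")]
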