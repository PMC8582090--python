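"""Synthetic cohort generator.

Emulates the study population's statistical structure so every
downstream stage is testable without raw data:

* marginals reproduce the printed percentile anchors via an
  inverse-quantile (Gaussian copula) transform of correlated latent
  uniforms;
* vigorous physical activity is zero below its 80th-percentile rank and
  climbs linearly to the 99th-percentile anchor above it (only the most
  active fifth of the cohort performs any vigorous activity);
* faller labels are Bernoulli draws from the published eight-factor
  logistic model, with a calibrated intercept so the cohort prevalence
  matches the study's 37.2%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .anchors import QuantileAnchors, default_anchors, extended_quantile
from .cohort import Cohort
from .model import FittedLogisticModel, published_model, sigmoid
from .registry import VariableSpec, registry_names, variable_registry

__all__ = [
    "GeneratorConfig",
    "default_correlation",
    "sample_covariates",
    "calibrate_intercept",
    "label_outcomes",
    "generate_cohort",
    "NonPSDCorrelationError",
]


class NonPSDCorrelationError(ValueError):
    """Correlation matrix is not positive semidefinite.

    Carries ``nearest_psd``, the eigenvalue-clipped nearest valid
    correlation matrix, as a repair suggestion.
    """

    def __init__(self, msg: str, nearest_psd: np.ndarray):
        super().__init__(msg)
        self.nearest_psd = nearest_psd


_FITNESS_GROUP = (
    "lower_body_strength", "upper_body_strength", "upper_body_flexibility",
    "aerobic_endurance", "multidimensional_balance", "lean_body_mass",
    "walking_physical_activity", "moderate_physical_activity",
    "total_physical_activity",
)
_COUNT_GROUP = ("health_conditions", "environmental_hazards")


def default_correlation() -> pd.DataFrame:
    """Default latent correlation over the 19 registry variables.

    Protective fitness variables are mutually correlated at +0.4, fat
    mass at -0.3 with each of them, and the two hazard/condition counts
    at +0.2; everything else is uncorrelated.  The structure exists only
    to make the joint distribution non-degenerate — it is configurable
    and no reference quantity depends on it.
    """
    names = registry_names()
    k = len(names)
    r = np.eye(k)
    idx = {n: i for i, n in enumerate(names)}
    for a in _FITNESS_GROUP:
        for b in _FITNESS_GROUP:
            if a != b:
                r[idx[a], idx[b]] = 0.4
    for a in _FITNESS_GROUP:
        r[idx[a], idx["fat_body_mass"]] = r[idx["fat_body_mass"], idx[a]] = -0.3
    r[idx["health_conditions"], idx["environmental_hazards"]] = 0.2
    r[idx["environmental_hazards"], idx["health_conditions"]] = 0.2
    return pd.DataFrame(r, index=names, columns=names)


@dataclass
class GeneratorConfig:
    """Everything the generator needs, with study-condition defaults."""

    n: int = 500
    seed: int = 0
    anchors: Dict[str, QuantileAnchors] = field(default_factory=default_anchors)
    correlation: Optional[pd.DataFrame] = None
    outcome_model: FittedLogisticModel = field(default_factory=published_model)
    target_prevalence: float = 0.372
    vigorous_zero_fraction: float = 0.80

    def __post_init__(self) -> None:
        if self.correlation is None:
            self.correlation = default_correlation()
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie strictly in (0, 1)")
        if not 0.0 <= self.vigorous_zero_fraction < 1.0:
            raise ValueError("vigorous_zero_fraction must lie in [0, 1)")


def _cholesky_or_raise(corr: pd.DataFrame) -> np.ndarray:
    r = np.asarray(corr, dtype=float)
    if not np.allclose(r, r.T, atol=1e-12):
        raise NonPSDCorrelationError("correlation matrix is not symmetric", r)
    if not np.allclose(np.diag(r), 1.0, atol=1e-12):
        raise NonPSDCorrelationError("correlation diagonal must be 1", r)
    vals, vecs = np.linalg.eigh(r)
    if vals.min() < -1e-10:
        clipped = (vecs * np.clip(vals, 1e-12, None)) @ vecs.T
        d = np.sqrt(np.diag(clipped))
        nearest = clipped / np.outer(d, d)
        np.fill_diagonal(nearest, 1.0)
        raise NonPSDCorrelationError(
            f"correlation matrix is not positive semidefinite "
            f"(min eigenvalue {vals.min():.3e}); nearest valid matrix attached",
            nearest,
        )
    jitter = max(0.0, -vals.min()) + 1e-12
    return np.linalg.cholesky(r + jitter * np.eye(len(r)))


def _vigorous_values(u: np.ndarray, anchors: QuantileAnchors,
                     zero_fraction: float) -> np.ndarray:
    """Zero-inflated vigorous activity from latent uniforms.

    Zero below the ``zero_fraction`` rank; linear from 0 at that rank to
    the 99th-percentile anchor above it, continuing with the same slope
    in the extreme tail.
    """
    p99 = float(np.interp(99.0, anchors.anchor_percentiles, anchors.anchor_values))
    p0 = 100.0 * zero_fraction
    slope = p99 / (99.0 - p0) if 99.0 > p0 else 0.0
    v = np.where(u * 100.0 <= p0, 0.0, (u * 100.0 - p0) * slope)
    return np.clip(v, 0.0, None)


def sample_covariates(config: GeneratorConfig) -> Cohort:
    """Draw a cohort's covariates (no outcome labels yet).

    Deterministic given ``config.seed``.  Latent Gaussians are mapped
    through each variable's reconstructed quantile function; integer
    variables are rounded and all physical bounds enforced.
    """
    registry = variable_registry()
    names = [s.name for s in registry]
    corr = config.correlation.loc[names, names]
    L = _cholesky_or_raise(corr)
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((config.n, len(names))) @ L.T
    u = stats.norm.cdf(z)

    cols: Dict[str, np.ndarray] = {}
    tpa_col = names.index("total_physical_activity")
    for j, spec in enumerate(registry):
        anch = config.anchors[spec.name]
        if spec.name == "vigorous_physical_activity":
            # comonotone with total activity: the most active participants
            # are the ones performing any vigorous activity, and the total's
            # quantile dominates the vigorous quantile at every rank, so the
            # TPA >= VPA constraint holds without distorting TPA's marginal
            vals = _vigorous_values(u[:, tpa_col], anch, config.vigorous_zero_fraction)
        else:
            vals = extended_quantile(anch, 100.0 * u[:, j], spec)
        vals = np.asarray(vals, dtype=float)
        if spec.integer:
            vals = np.round(vals)
        if spec.lower is not None or spec.upper is not None:
            vals = np.clip(
                vals,
                -np.inf if spec.lower is None else spec.lower,
                np.inf if spec.upper is None else spec.upper,
            )
        cols[spec.name] = vals
    # enforce TPA >= VPA (sub-domain cannot exceed the total)
    cols["total_physical_activity"] = np.maximum(
        cols["total_physical_activity"], cols["vigorous_physical_activity"]
    )
    # sociodemographics, carried but never key factors
    cols["sex"] = (rng.random(config.n) < 138 / 500).astype(float)  # 1 = male
    cols["age"] = np.clip(rng.normal(72.2, 5.4, config.n), 65.0, None).round(1)
    cols["education"] = np.clip(rng.normal(5.2, 3.9, config.n), 0.0, None).round(1)
    return Cohort(pd.DataFrame(cols), registry)


def calibrate_intercept(outcome_model: FittedLogisticModel, cohort: Cohort,
                        target_prevalence: float) -> float:
    """Intercept beta0 making the mean predicted probability hit the target.

    The mean of sigmoid(beta0 + lp_i) is continuous and strictly
    increasing in beta0, so the root is unique; solved by Brent's method
    to 1e-12.
    """
    if len(cohort) == 0:
        raise ValueError("covariate cohort is empty")
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence of 0 or 1 is unattainable")
    lp = outcome_model.linear_predictor(cohort.data) - outcome_model.intercept

    def gap(b0: float) -> float:
        return float(np.mean(sigmoid(b0 + lp))) - target_prevalence

    return float(optimize.brentq(gap, -60.0, 60.0, xtol=1e-12))


def label_outcomes(cohort: Cohort, outcome_model: FittedLogisticModel,
                   intercept: float, seed: int) -> Cohort:
    """Attach Bernoulli faller labels drawn from the outcome model."""
    pi = np.atleast_1d(
        outcome_model.with_intercept(intercept).predict_proba(cohort.data)
    )
    rng = np.random.default_rng(seed)
    df = cohort.data.copy()
    df["faller"] = (rng.random(len(df)) < pi).astype(int)
    return Cohort(df, cohort.registry)


def generate_cohort(n: int = 500, seed: int = 0,
                    config: Optional[GeneratorConfig] = None) -> Cohort:
    """Covariates + calibrated outcome labels in one call."""
    config = replace(config, n=n, seed=seed) if config is not None else GeneratorConfig(n=n, seed=seed)
    cov = sample_covariates(config)
    b0 = calibrate_intercept(config.outcome_model, cov, config.target_prevalence)
    # label stream decoupled from the covariate stream
    return label_outcomes(cov, config.outcome_model, b0, seed=config.seed + 1_000_003)
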