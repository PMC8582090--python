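"""Fitted logistic fall model: container, evaluation, serialization.

The multivariate fall model gives the probability of falling as

    pi(x) = 1 / (1 + exp(-(b0 + sum_i beta_i x_i)))

with covariates in *model units* (physical activity per 100 MET-min/wk,
everything else in natural units).  The published eight-factor model is

    logit pi = -0.053 B - 0.026 L + 0.027 F - 0.012 TPA
               + 0.034 VPA + 0.125 R + 0.112 HC + 0.063 H

with no intercept term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .registry import KEY_FACTOR_ORDER, get_spec

__all__ = [
    "FittedLogisticModel",
    "published_model",
    "PUBLISHED_COEFFICIENTS",
    "odds_ratio_report",
    "sigmoid",
]

#: Printed multivariate coefficients, per model unit.
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "multidimensional_balance": -0.053,
    "lean_body_mass": -0.026,
    "fat_body_mass": 0.027,
    "total_physical_activity": -0.012,
    "vigorous_physical_activity": 0.034,
    "rest_period_weekdays": 0.125,
    "health_conditions": 0.112,
    "environmental_hazards": 0.063,
}


def sigmoid(eta):
    """Numerically safe logistic function, strictly inside (0, 1)."""
    eta = np.asarray(eta, dtype=float)
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    tiny = np.finfo(float).tiny
    out = np.clip(out, tiny, 1.0 - np.finfo(float).epsneg)
    return out if out.ndim else float(out)


@dataclass
class FittedLogisticModel:
    """Intercept + per-variable coefficients with optional inference info.

    Coefficients are on the model-unit scale; :meth:`predict_proba` takes
    natural units and applies each variable's ``model_scale`` itself.
    """

    variables: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float = 0.0
    covariance: Optional[np.ndarray] = None
    n_obs: Optional[int] = None
    converged: bool = True
    log_likelihood: Optional[float] = None
    removal_log: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.variables),):
            raise ValueError("one coefficient per variable required")
        if self.covariance is not None:
            self.covariance = np.asarray(self.covariance, dtype=float)

    # -- evaluation -----------------------------------------------------

    def _model_matrix(self, data) -> np.ndarray:
        if isinstance(data, Mapping):
            data = pd.DataFrame({k: [v] for k, v in data.items()})
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise ValueError(f"missing model variables: {missing}")
        cols = []
        for name in self.variables:
            scale = get_spec(name).model_scale if _known(name) else 1.0
            cols.append(np.asarray(data[name], dtype=float) * scale)
        return np.column_stack(cols)

    def linear_predictor(self, data) -> np.ndarray:
        """Linear predictor from natural-unit data (mapping or DataFrame)."""
        X = self._model_matrix(data)
        return self.intercept + X @ self.coefficients

    def predict_proba(self, data) -> np.ndarray:
        """Probability of falling from natural-unit data."""
        return sigmoid(self.linear_predictor(data))

    def predict_proba_model_units(self, X: np.ndarray) -> np.ndarray:
        """Probability from a design matrix already in model units."""
        X = np.asarray(X, dtype=float)
        return sigmoid(self.intercept + X @ self.coefficients)

    # -- inference helpers ----------------------------------------------

    def standard_errors(self) -> np.ndarray:
        if self.covariance is None:
            raise ValueError("model carries no covariance matrix")
        k = len(self.variables)
        # covariance is ordered [intercept?, variables...]
        off = self.covariance.shape[0] - k
        return np.sqrt(np.diag(self.covariance)[off:])

    def with_intercept(self, intercept: float) -> "FittedLogisticModel":
        return FittedLogisticModel(
            self.variables, self.coefficients.copy(), float(intercept),
            self.covariance, self.n_obs, self.converged, self.log_likelihood,
        )

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "coefficients": [float(b) for b in self.coefficients],
            "intercept": float(self.intercept),
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "log_likelihood": self.log_likelihood,
        }

    def to_json(self, path=None) -> str:
        doc = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_dict(cls, d: dict) -> "FittedLogisticModel":
        return cls(
            variables=tuple(d["variables"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d.get("intercept", 0.0)),
            covariance=None if d.get("covariance") is None else np.asarray(d["covariance"]),
            n_obs=d.get("n_obs"),
            converged=bool(d.get("converged", True)),
            log_likelihood=d.get("log_likelihood"),
        )

    @classmethod
    def from_json(cls, path) -> "FittedLogisticModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _known(name: str) -> bool:
    try:
        get_spec(name)
        return True
    except KeyError:
        return False


def published_model() -> FittedLogisticModel:
    """The printed eight-factor model, intercept fixed at 0."""
    return FittedLogisticModel(
        variables=KEY_FACTOR_ORDER,
        coefficients=np.array([PUBLISHED_COEFFICIENTS[v] for v in KEY_FACTOR_ORDER]),
        intercept=0.0,
    )


_Z975 = 1.959964


def odds_ratio_report(model: FittedLogisticModel,
                      z: float = _Z975) -> pd.DataFrame:
    """Odds ratios per model unit with Wald 95% CIs and percent change.

    OR = exp(beta); CI = exp(beta +- z * SE); percent change is
    100 * (OR - 1), the per-unit change in the odds of falling.
    """
    from scipy import stats

    beta = model.coefficients
    rows = {"variable": list(model.variables), "beta": beta, "or": np.exp(beta)}
    if model.covariance is not None:
        se = model.standard_errors()
        rows["se"] = se
        rows["ci_low"] = np.exp(beta - z * se)
        rows["ci_high"] = np.exp(beta + z * se)
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        rows["p_value"] = 2.0 * stats.norm.sf(np.abs(zstat))
    rows["pct_change"] = 100.0 * (np.exp(beta) - 1.0)
    return pd.DataFrame(rows)
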