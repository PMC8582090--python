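"""From-scratch binary logistic regression by IRLS, with the model-building
steps used for fall-risk screening: univariate odds ratios, backward
elimination on Wald p-values, and the Hosmer-Lemeshow goodness-of-fit test.

The estimator follows the scikit-learn protocol (``fit`` /
``predict_proba`` / ``get_params``), so it composes with sklearn
pipelines and model selection; the module-level functions are thin
wrappers that work directly on :class:`~fallrisk.cohort.Cohort` objects
and return :class:`~fallrisk.model.FittedLogisticModel` containers.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import Cohort
from .model import FittedLogisticModel, odds_ratio_report, sigmoid
from .registry import get_spec

__all__ = [
    "FallRiskLogit",
    "SeparationError",
    "CollinearityError",
    "fit_logistic",
    "univariate_or_table",
    "backward_select",
    "hosmer_lemeshow",
    "odds_ratio_report",
]


class SeparationError(RuntimeError):
    """Perfect (or quasi-) separation: coefficients diverge."""


class CollinearityError(ValueError):
    """Rank-deficient design matrix; names the collinear columns."""


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class FallRiskLogit(BaseEstimator, ClassifierMixin):
    """Maximum-likelihood binary logistic regression via IRLS.

    Parameters
    ----------
    include_intercept : bool, default True
        Whether to estimate an intercept term.
    tol : float, default 1e-8
        Convergence threshold on the infinity norm of the score vector.
    max_iter : int, default 100
        Maximum IRLS iterations.
    separation_threshold : float, default 15.0
        A coefficient exceeding this magnitude on the standardized scale
        is treated as evidence of separation.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Slope estimates.
    intercept_ : float
        Intercept estimate (0.0 when ``include_intercept=False``).
    covariance_ : ndarray
        Inverse observed information over [intercept?, slopes].
    converged_ : bool
    n_iter_ : int
    log_likelihood_ : float
    """

    def __init__(self, include_intercept: bool = True, tol: float = 1e-8,
                 max_iter: int = 100, separation_threshold: float = 15.0):
        self.include_intercept = include_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.separation_threshold = separation_threshold

    # -- sklearn protocol ------------------------------------------------

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns) if feature_names is None else list(feature_names)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        y = np.asarray(y, dtype=float).ravel()
        classes = np.unique(y)
        if not np.all(np.isin(classes, (0.0, 1.0))) or len(classes) < 2:
            raise ValueError("y must contain both classes, coded 0/1")
        n, k = X.shape
        names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(k)]
        D = np.column_stack([np.ones(n), X]) if self.include_intercept else X
        if n <= D.shape[1]:
            raise ValueError("more parameters than observations")
        self._check_rank(D, names)

        beta = np.zeros(D.shape[1])
        eta = D @ beta
        ll = _log_likelihood(y, eta)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            p = sigmoid(eta)
            score = D.T @ (y - p)
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            w = p * (1.0 - p)
            info = D.T @ (D * w[:, None])
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as exc:
                raise SeparationError(
                    "information matrix singular during IRLS (separation?)"
                ) from exc
            # step-halving keeps the log-likelihood non-decreasing
            alpha = 1.0
            for _ in range(30):
                cand = beta + alpha * step
                eta_c = D @ cand
                ll_c = _log_likelihood(y, eta_c)
                if ll_c >= ll - 1e-12:
                    break
                alpha *= 0.5
            beta, eta, ll = cand, eta_c, ll_c
            self._check_separation(D, beta)
        p = sigmoid(eta)
        w = p * (1.0 - p)
        info = D.T @ (D * w[:, None])
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full_like(info, np.nan)

        self.feature_names_ = names
        self.classes_ = np.array([0.0, 1.0])
        if self.include_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.covariance_ = cov
        self.converged_ = converged
        self.n_iter_ = it
        self.log_likelihood_ = ll
        self.n_obs_ = n
        return self

    def decision_function(self, X):
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = sigmoid(self.decision_function(X))
        p1 = np.atleast_1d(p1)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (np.atleast_1d(sigmoid(self.decision_function(X))) >= 0.5).astype(int)

    # -- internals -------------------------------------------------------

    def _check_rank(self, D: np.ndarray, names: Sequence[str]) -> None:
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            # pivoted QR flags which columns are linearly dependent
            from scipy.linalg import qr

            _, r, piv = qr(D, pivoting=True, mode="economic")
            diag = np.abs(np.diag(r))
            thresh = diag[0] * max(D.shape) * np.finfo(float).eps
            dead = sorted(piv[i] for i in range(len(diag)) if diag[i] <= thresh)
            labels = []
            for j in dead:
                if self.include_intercept:
                    labels.append("intercept" if j == 0 else names[j - 1])
                else:
                    labels.append(names[j])
            raise CollinearityError(
                f"design matrix is rank deficient; collinear column(s): {labels}"
            )

    def _check_separation(self, D: np.ndarray, beta: np.ndarray) -> None:
        sd = D.std(axis=0)
        sd[sd == 0] = 1.0
        if np.max(np.abs(beta) * sd) > self.separation_threshold:
            raise SeparationError(
                "diverging coefficients; the classes appear perfectly separated"
            )

    def to_model(self) -> FittedLogisticModel:
        return FittedLogisticModel(
            variables=tuple(self.feature_names_),
            coefficients=self.coef_,
            intercept=self.intercept_,
            covariance=self.covariance_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            log_likelihood=self.log_likelihood_,
        )


# -- cohort-level wrappers ----------------------------------------------


def _design(cohort: Cohort, variables: Sequence[str]) -> pd.DataFrame:
    """Model-unit design frame (physical activity scaled to 100-MET units)."""
    cols = {}
    for name in variables:
        scale = 1.0
        try:
            scale = get_spec(name).model_scale
        except KeyError:
            pass
        cols[name] = cohort.data[name].to_numpy(dtype=float) * scale
    return pd.DataFrame(cols)


def fit_logistic(cohort: Cohort, variables: Sequence[str],
                 include_intercept: bool = True, **kw) -> FittedLogisticModel:
    """Fit a multivariate logistic fall model on a cohort.

    Covariates enter in model units; the returned model's
    ``predict_proba`` takes natural units again.
    """
    est = FallRiskLogit(include_intercept=include_intercept, **kw)
    est.fit(_design(cohort, variables), cohort.outcome, feature_names=list(variables))
    return est.to_model()


def wald_p_values(model: FittedLogisticModel) -> np.ndarray:
    se = model.standard_errors()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, model.coefficients / se, np.inf)
    return 2.0 * stats.norm.sf(np.abs(z))


def univariate_or_table(cohort: Cohort,
                        variables: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Single-covariate odds ratios (with intercept), one row per variable.

    Per-variable failures are reported in an ``error`` column without
    aborting the table.
    """
    if variables is None:
        variables = [s.name for s in cohort.registry]
    rows = []
    for name in variables:
        try:
            m = fit_logistic(cohort, [name], include_intercept=True)
            rep = odds_ratio_report(m).iloc[0].to_dict()
            rep["error"] = None
        except Exception as exc:  # noqa: BLE001 - per-variable reporting
            rep = {"variable": name, "error": f"{type(exc).__name__}: {exc}"}
        rows.append(rep)
    return pd.DataFrame(rows)


def backward_select(cohort: Cohort, candidates: Sequence[str],
                    alpha: float = 0.05) -> FittedLogisticModel:
    """Backward elimination on Wald p-values.

    Starting from the full candidate model, repeatedly drop the variable
    with the largest p-value above ``alpha`` (ties broken by candidate
    order) until every survivor is significant.  The removal order is
    recorded on the returned model.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    current = list(candidates)
    removed: list[str] = []
    while current:
        model = fit_logistic(cohort, current, include_intercept=True)
        p = wald_p_values(model)
        worst = int(np.argmax(p))  # first occurrence wins ties -> registry order
        if p[worst] <= alpha:
            model.removal_log = tuple(removed)
            return model
        removed.append(current.pop(worst))
    model = fit_logistic_intercept_only(cohort)
    model.removal_log = tuple(removed)
    return model


def fit_logistic_intercept_only(cohort: Cohort) -> FittedLogisticModel:
    y = cohort.outcome
    pbar = float(np.mean(y))
    b0 = float(np.log(pbar / (1 - pbar)))
    ll = _log_likelihood(y.astype(float), np.full(len(y), b0))
    return FittedLogisticModel((), np.empty(0), b0, None, len(y), True, ll)


def hosmer_lemeshow(model: FittedLogisticModel, cohort: Cohort,
                    n_groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow chi-square test over deciles of predicted risk.

    Participants are ranked by predicted probability and split into
    ``n_groups`` near-equal groups; tied probabilities stay together in
    the lower group.  The statistic is the Pearson chi-square over
    observed/expected fallers and non-fallers with ``n_groups - 2``
    degrees of freedom.
    """
    y = cohort.outcome
    n = len(y)
    if n < 5 * n_groups:
        raise ValueError(f"need at least {5 * n_groups} observations for {n_groups} groups")
    pi = np.atleast_1d(model.predict_proba(cohort.data))
    order = np.argsort(pi, kind="stable")
    pi_s, y_s = pi[order], y[order]
    # nominal equal-size boundaries, then extend each group through ties
    # so that identical probabilities stay in the lower group wholesale
    bounds = [round(n * g / n_groups) for g in range(1, n_groups + 1)]
    chi2 = 0.0
    used = 0
    start = 0
    for i, b in enumerate(bounds):
        if start >= n:
            break
        end = n if i == len(bounds) - 1 else max(b, start + 1)
        while end < n and pi_s[end] == pi_s[end - 1]:
            end += 1
        o1 = float(np.sum(y_s[start:end]))
        e1 = float(np.sum(pi_s[start:end]))
        m = end - start
        e0 = m - e1
        o0 = m - o1
        if e1 <= 0 or e0 <= 0:
            raise ValueError(
                "expected count of zero in a risk group; use fewer groups"
            )
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        used += 1
        start = end
    df = n_groups - 2
    if used < 3:
        raise ValueError("too few distinct risk groups for the test")
    return float(chi2), float(stats.chi2.sf(chi2, df))
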