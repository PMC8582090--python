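"""IRLS logistic regression, selection, odds ratios, goodness of fit."""

import numpy as np
import pandas as pd
import pytest

import fallrisk as fr
from fallrisk.cohort import Cohort
from fallrisk.logistic import (
    CollinearityError,
    FallRiskLogit,
    SeparationError,
    _log_likelihood,
    wald_p_values,
)
from fallrisk.model import FittedLogisticModel


def _bernoulli_cohortless(seed, n, beta, intercept=0.0, k=None):
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    k = len(beta) if k is None else k
    X = rng.standard_normal((n, k))
    eta = intercept + X[:, : len(beta)] @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return X, y


def test_null_coefficient_recovered_within_3_se():
    X, y = _bernoulli_cohortless(0, 10_000, [0.0])
    est = FallRiskLogit().fit(X, y)
    se = np.sqrt(np.diag(est.covariance_))[1]
    assert abs(est.coef_[0]) < 3 * se


def test_score_equations_hold_at_convergence():
    X, y = _bernoulli_cohortless(1, 2_000, [0.7, -0.4])
    est = FallRiskLogit().fit(X, y)
    p = est.predict_proba(X)[:, 1]
    D = np.column_stack([np.ones(len(y)), X])
    assert np.max(np.abs(D.T @ (y - p))) < 1e-6
    assert est.converged_


def test_optimum_beats_brute_force_likelihood_grid():
    """On a tiny one-covariate set the IRLS optimum dominates a dense grid."""
    X = np.array([[-2.0], [-1.5], [-1.0], [-0.5], [0.5], [1.0], [1.5], [2.0]])
    y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
    est = FallRiskLogit().fit(X, y)
    ll_opt = est.log_likelihood_
    grid = np.linspace(-4, 4, 1000)
    for b0 in (-1.0, est.intercept_, 1.0):
        lls = [_log_likelihood(y.astype(float), b0 + X[:, 0] * b) for b in grid]
        assert ll_opt >= max(lls) - 1e-9


def test_agreement_with_reference_implementation():
    """Coefficients match statsmodels Logit to 1e-6 on random small cohorts."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 20:
        n = int(rng.integers(40, 120))
        k = int(rng.integers(1, 4))
        X = rng.standard_normal((n, k))
        beta = rng.normal(0, 0.8, k)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + X @ beta)))).astype(int)
        if y.min() == y.max():
            continue
        try:
            est = FallRiskLogit().fit(X, y)
        except SeparationError:
            continue
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton", tol=1e-10)
        np.testing.assert_allclose(
            np.r_[est.intercept_, est.coef_], ref.params, atol=1e-6
        )
        checked += 1


def test_separation_detected():
    X = np.linspace(-2, 2, 40).reshape(-1, 1)
    y = (X[:, 0] > 0).astype(int)
    with pytest.raises(SeparationError):
        FallRiskLogit().fit(X, y)


def test_collinear_columns_named():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(100)
    X = np.column_stack([x, 2.0 * x])
    y = (rng.random(100) < 0.4).astype(int)
    with pytest.raises(CollinearityError, match="x0|x1"):
        FallRiskLogit().fit(X, y, feature_names=["x0", "x1"])


def test_single_class_rejected():
    X = np.random.default_rng(0).standard_normal((30, 1))
    with pytest.raises(ValueError):
        FallRiskLogit().fit(X, np.zeros(30))


def test_cohort_fit_recovers_generator_coefficients(cohort_large):
    m = fr.fit_logistic(cohort_large, list(fr.KEY_FACTOR_ORDER))
    se = m.standard_errors()
    truth = np.array([fr.PUBLISHED_COEFFICIENTS[v] for v in m.variables])
    assert np.all(np.abs(m.coefficients - truth) < 4 * se)
    # covariance symmetric PSD at convergence
    cov = m.covariance
    assert np.allclose(cov, cov.T, atol=1e-10)
    assert np.linalg.eigvalsh(cov).min() > -1e-12


@pytest.mark.parametrize("beta,or_,pct", [
    (0.125, 1.133, 13.3), (-0.026, 0.974, -2.6), (0.0, 1.0, 0.0),
])
def test_odds_ratio_identities(beta, or_, pct):
    m = FittedLogisticModel(("v",), np.array([beta]), 0.0)
    rep = fr.odds_ratio_report(m)
    assert rep["or"].iloc[0] == pytest.approx(or_, abs=5e-4)
    assert rep["pct_change"].iloc[0] == pytest.approx(pct, abs=5e-2)


def test_or_ci_brackets_point_estimate(cohort500):
    m = fr.fit_logistic(cohort500, list(fr.KEY_FACTOR_ORDER))
    rep = fr.odds_ratio_report(m)
    assert (rep["ci_low"] < rep["or"]).all()
    assert (rep["or"] < rep["ci_high"]).all()


def test_outcome_relabel_gives_reciprocal_ors(cohort500):
    m1 = fr.fit_logistic(cohort500, ["multidimensional_balance"])
    flipped = Cohort(
        cohort500.data.assign(faller=1 - cohort500.data["faller"]),
        cohort500.registry,
    )
    m2 = fr.fit_logistic(flipped, ["multidimensional_balance"])
    or1 = np.exp(m1.coefficients[0])
    or2 = np.exp(m2.coefficients[0])
    assert or1 == pytest.approx(1.0 / or2, rel=1e-6)


def test_univariate_table_scales_activity_per_100_met(cohort500):
    tab = fr.univariate_or_table(cohort500, ["total_physical_activity"])
    beta_per_100 = np.log(tab["or"].iloc[0])
    m_raw = FallRiskLogit().fit(
        cohort500.values("total_physical_activity").reshape(-1, 1),
        cohort500.outcome,
    )
    assert beta_per_100 == pytest.approx(100.0 * m_raw.coef_[0], rel=1e-6)
    assert tab["error"].iloc[0] is None


def test_univariate_failures_do_not_abort_table(cohort500):
    df = cohort500.data.copy()
    df["constant"] = 1.0
    registry = cohort500.registry
    cohort = Cohort(df, registry)
    tab = fr.univariate_or_table(cohort, ["lean_body_mass", "constant"])
    assert tab["error"].iloc[0] is None
    assert tab["error"].iloc[1] is not None


def test_backward_selection_drops_noise_keeps_signal():
    """The pure-noise covariate survives only at the 5% type-I rate."""
    n_seeds = 50
    removed_noise = 0
    kept_signal = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n = 5_000
        informative = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        eta = -0.4 + 0.8 * informative
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({
            "informative": informative, "noise": noise, "faller": y,
        })
        cohort = Cohort(df, registry=())
        m = fr.backward_select(cohort, ["informative", "noise"])
        removed_noise += "noise" in m.removal_log
        kept_signal += "informative" in m.variables
    assert kept_signal == n_seeds
    assert removed_noise >= 0.90 * n_seeds


def test_backward_selection_keeps_all_strong_candidates(cohort_large):
    m = fr.backward_select(cohort_large, list(fr.KEY_FACTOR_ORDER))
    assert set(m.variables) == set(fr.KEY_FACTOR_ORDER)
    assert m.removal_log == ()


def test_age_and_sex_eliminated_on_key_factor_outcomes(cohort_large):
    cand = list(fr.KEY_FACTOR_ORDER) + ["age", "sex"]
    m = fr.backward_select(cohort_large, cand)
    assert "age" not in m.variables
    assert "sex" not in m.variables


def test_hosmer_lemeshow_well_specified_model_not_rejected(cohort_large):
    m = fr.fit_logistic(cohort_large, list(fr.KEY_FACTOR_ORDER))
    stat, p = fr.hosmer_lemeshow(m, cohort_large)
    assert stat >= 0
    assert p > 0.01


def test_hosmer_lemeshow_detects_gross_misspecification():
    """Quadratic truth fitted linearly: median p across seeds is tiny."""
    ps = []
    for seed in range(10):
        rng = np.random.default_rng(300 + seed)
        x = rng.standard_normal(2_000)
        eta = -1.0 + 1.5 * x**2
        y = (rng.random(2_000) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"x": x, "faller": y})
        cohort = Cohort(df, registry=())
        m = fr.fit_logistic(cohort, ["x"])
        ps.append(fr.hosmer_lemeshow(m, cohort)[1])
    assert np.median(ps) < 0.05


def test_hosmer_lemeshow_needs_enough_observations(cohort500):
    m = fr.fit_logistic(cohort500, ["multidimensional_balance"])
    small = Cohort(cohort500.data.iloc[:40].reset_index(drop=True), cohort500.registry)
    with pytest.raises(ValueError):
        fr.hosmer_lemeshow(m, small, n_groups=10)


def test_wald_p_values_match_normal_tail(cohort500):
    m = fr.fit_logistic(cohort500, list(fr.KEY_FACTOR_ORDER))
    p = wald_p_values(m)
    assert np.all((p >= 0) & (p <= 1))
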