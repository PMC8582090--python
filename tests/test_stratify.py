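"""Profile curve, model inversion, and the cutoff table."""

import numpy as np
import pytest

import fallrisk as fr
from fallrisk.stratify import CutProbabilities, RiskFactorVector


def test_profile_at_p45_matches_hand_interpolation(anchors):
    """Protective at the 45th, risk at the 55th percentile, VPA = 0."""
    vec = fr.build_profile(anchors, 45.0)
    assert vec.B == pytest.approx(31.2)
    assert vec.L == pytest.approx(41.18)
    assert vec.TPA == pytest.approx(23.076)  # 100 MET-min/wk units
    assert vec.F == pytest.approx(39.3)
    assert vec.R == pytest.approx(4.54)
    assert vec.HC == pytest.approx(3.4)
    assert vec.H == pytest.approx(6.6)
    assert vec.VPA == 0.0


def test_profile_at_median_reproduces_printed_medians(anchors):
    vec = fr.build_profile(anchors, 50.0)
    assert (vec.B, vec.L, vec.F) == (32.0, 42.2, 38.3)
    assert vec.TPA == pytest.approx(24.73)
    assert (vec.R, vec.HC, vec.H) == (4.3, 3.0, 6.0)


@pytest.mark.parametrize("p", [1, 20, 45, 60, 79])
def test_vigorous_component_zero_across_profile_band(anchors, p):
    assert fr.build_profile(anchors, float(p)).VPA == 0.0


def test_probability_at_p45_reproduces_study_youden_cutoff(model, anchors):
    pi = fr.profile_probability(model, anchors, 45.0)
    assert pi == pytest.approx(0.35939, abs=0.001)


def test_probability_at_median_profile(model, anchors):
    assert fr.profile_probability(model, anchors, 50.0) == pytest.approx(0.309, abs=0.001)


def test_profile_probability_strictly_decreasing(model, anchors):
    ps = np.linspace(1, 99, 99)
    pis = [fr.profile_probability(model, anchors, p) for p in ps]
    assert np.all(np.diff(pis) < 0)


def test_sign_inconsistent_model_rejected_with_factor_name(anchors):
    bad = fr.FittedLogisticModel(
        fr.KEY_FACTOR_ORDER,
        np.array([+0.053, -0.026, 0.027, -0.012, 0.034, 0.125, 0.112, 0.063]),
    )
    with pytest.raises(ValueError, match="multidimensional_balance"):
        fr.profile_probability(bad, anchors, 50.0)


def test_inversion_consistency(model, anchors):
    for c in (0.25, 0.35939, 0.50):
        p_star = fr.solve_percentile(model, anchors, c)
        assert fr.profile_probability(model, anchors, p_star) == pytest.approx(c, abs=1e-9)
    # round trip through an arbitrary profile point
    c_mid = fr.profile_probability(model, anchors, 50.0)
    assert fr.solve_percentile(model, anchors, c_mid) == pytest.approx(50.0, abs=1e-6)


def test_percentile_roots_near_study_values(model, anchors):
    """Middle cut at ~45th percentile; outer cuts near 57th/32nd."""
    assert fr.solve_percentile(model, anchors, 0.35939) == pytest.approx(45.0, abs=0.5)
    assert 56.0 <= fr.solve_percentile(model, anchors, 0.25) <= 58.5
    assert 31.0 <= fr.solve_percentile(model, anchors, 0.50) <= 33.0


def test_unattainable_cut_reports_range(model, anchors):
    with pytest.raises(ValueError, match="attainable"):
        fr.solve_percentile(model, anchors, 0.999)


def test_roots_decrease_with_cut_probability(cutoff_table):
    roots = [cutoff_table.percentile_roots[c] for c in (0.25, 0.35939, 0.50)]
    assert roots[0] > roots[1] > roots[2]


@pytest.mark.parametrize("factor,rounded", [
    ("multidimensional_balance", (33, 31, 29)),
    ("lean_body_mass", (44, 41, 39)),
    ("fat_body_mass", (37, 39, 42)),
    ("environmental_hazards", (5, 7, 8)),
    ("health_conditions", (3, 3, 4)),
    ("total_physical_activity", (2900, 2400, 1900)),
    ("rest_period_weekdays", (3.9, 4.5, 5.1)),
])
def test_rounded_boundaries(cutoff_table, factor, rounded):
    assert cutoff_table[factor].rounded == pytest.approx(rounded)


@pytest.mark.parametrize("factor,expected", [
    ("lean_body_mass", 44),        # low/moderate at pi = 0.25
    ("multidimensional_balance", 33),
    ("fat_body_mass", 42),         # high/very-high at pi = 0.50
    ("environmental_hazards", 8),
])
def test_published_boundary_reproduction(cutoff_table, factor, expected):
    fc = cutoff_table[factor]
    idx = 0 if fc.direction == "protective" else 2
    assert fc.rounded[idx] == expected


def test_health_conditions_moderate_stratum_is_three(cutoff_table):
    fc = cutoff_table["health_conditions"]
    assert fc.classify(3) == "moderate"
    assert fc.classify(2) == "low"


def test_boundaries_ordered_along_risk_direction(cutoff_table):
    for fc in cutoff_table.factors.values():
        b = np.array(fc.boundaries)
        if fc.direction == "protective":
            assert np.all(np.diff(b) < 0)
        else:
            assert np.all(np.diff(b) > 0)


def test_complement_symmetry_of_percentiles(model, anchors):
    """Risk factors sit exactly at 100 minus the protective percentile."""
    for c in (0.25, 0.35939, 0.50):
        p_star = fr.solve_percentile(model, anchors, c)
        vec = fr.build_profile(anchors, p_star)
        assert vec.F == pytest.approx(
            fr.interp_quantile(anchors["fat_body_mass"], 100.0 - p_star), abs=1e-10
        )


def test_strata_partition_without_gaps(cutoff_table):
    """Every representable value lands in exactly one stratum."""
    for fc in cutoff_table.factors.values():
        spec = fr.get_spec(fc.factor)
        from fallrisk.registry import precision_step

        step = precision_step(spec.precision)
        lo = min(fc.rounded) - 3 * step
        vals = np.arange(lo, max(fc.rounded) + 3 * step, step)
        strata = [fc.classify(round(v, 10)) for v in vals]
        order = ["low", "moderate", "high", "very_high"]
        seq = [order.index(s) for s in strata]
        if fc.direction == "protective":
            seq = seq[::-1]
        assert np.all(np.diff(seq) >= 0)  # monotone, no reversal or gap


def test_vigorous_excluded_from_table(cutoff_table):
    assert "vigorous_physical_activity" not in cutoff_table.factors


def test_presented_report_matches_printed_intervals(cutoff_table):
    text = fr.present_cutoffs(cutoff_table)
    assert "low risk: > 33, moderate risk: 32–33, high risk: 30–31, very high risk: < 30" in text
    assert "low risk: > 44, moderate risk: 42–44" in text  # lean mass
    assert "very high risk: > 42" in text                  # fat mass
    assert "very high risk: > 8" in text                   # hazards


def test_cut_probability_ordering_enforced():
    with pytest.raises(ValueError):
        CutProbabilities(0.5, 0.35, 0.25)


def test_risk_factor_vector_invariants():
    with pytest.raises(ValueError):
        RiskFactorVector(B=45, L=40, F=38, TPA=20, VPA=0, R=4, HC=3, H=6)
    with pytest.raises(ValueError):
        RiskFactorVector(B=30, L=40, F=38, TPA=1, VPA=2, R=4, HC=3, H=6)


def test_stratifier_estimator_reproduce_mode(cohort500):
    strat = fr.RiskStratifier().fit()
    assert strat.cutoff_table_["lean_body_mass"].rounded[0] == 44
    labels = strat.predict(cohort500)
    assert set(labels) <= {"low", "moderate", "high", "very_high"}
    per_factor = strat.transform(cohort500)
    assert list(per_factor.columns) == [
        n for n in fr.KEY_FACTOR_ORDER if n != "vigorous_physical_activity"
    ]


def test_stratifier_rederive_mode_uses_cohort_youden(cohort500):
    strat = fr.RiskStratifier(mode="re-derive").fit(cohort500)
    mid = strat.cutoff_table_.cuts.mod_high
    scores = np.atleast_1d(fr.published_model().predict_proba(cohort500.data))
    expected, _, _ = fr.youden_cutoff(scores, cohort500.outcome)
    assert mid == pytest.approx(expected)
    assert 0.25 < mid < 0.50


def test_overall_stratum_half_open_at_cuts():
    from fallrisk.profiler import _overall_stratum

    cuts = CutProbabilities()
    # a probability exactly on a cut belongs to the higher-risk stratum
    assert _overall_stratum(0.25, cuts) == "moderate"
    assert _overall_stratum(0.35939, cuts) == "high"
    assert _overall_stratum(0.50, cuts) == "very_high"
    assert _overall_stratum(0.2499, cuts) == "low"
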