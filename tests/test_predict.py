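"""Monte Carlo percentile estimation, adjustment factors, and assessment."""

import dataclasses
import math

import numpy as np
import pytest

from silicarisk import (
    Scenario,
    apply_duration_discount,
    apply_separation_factor,
    assess,
    fit_model,
    mc_percentile,
    recommend_respirator,
    validate_against_measurements,
)
from silicarisk.errors import InvalidInputError
from silicarisk.predict import DEFAULT_N_DRAWS, DEFAULT_OEL

from conftest import control_model, intercept_only_model, make_record


class TestMCPercentile:
    def test_zero_variance_is_exact_for_any_seed(self, toy_scenario):
        model = intercept_only_model(math.log(0.1), se=0.0)
        for seed in (0, 1, 12345):
            assert mc_percentile(model, toy_scenario, seed=seed) == pytest.approx(
                0.1, rel=1e-12
            )

    def test_matches_analytic_normal_quantile(self, toy_scenario):
        mu, s = math.log(0.05), 0.4
        model = intercept_only_model(mu, se=s)
        est = mc_percentile(model, toy_scenario, n_draws=200_000, seed=3)
        analytic = math.exp(mu + 1.6448536269514722 * s)
        assert est == pytest.approx(analytic, rel=0.01)

    def test_default_draw_count_is_1000(self):
        assert DEFAULT_N_DRAWS == 1000
        import inspect

        sig = inspect.signature(mc_percentile)
        assert sig.parameters["n_draws"].default == 1000
        assert sig.parameters["percentile"].default == 95.0

    def test_seed_determinism(self, toy_scenario):
        model = intercept_only_model(math.log(0.05), se=0.3)
        a = mc_percentile(model, toy_scenario, seed=11)
        b = mc_percentile(model, toy_scenario, seed=11)
        c = mc_percentile(model, toy_scenario, seed=12)
        assert a == b
        assert a != c

    def test_monotone_in_percentile_and_mean(self, toy_scenario):
        model_lo = intercept_only_model(math.log(0.05), se=0.3)
        model_hi = intercept_only_model(math.log(0.08), se=0.3)
        p50 = mc_percentile(model_lo, toy_scenario, percentile=50, seed=5)
        p95 = mc_percentile(model_lo, toy_scenario, percentile=95, seed=5)
        p99 = mc_percentile(model_lo, toy_scenario, percentile=99, seed=5)
        assert p50 < p95 < p99
        assert mc_percentile(model_hi, toy_scenario, seed=5) > p95

    def test_small_draw_count_warns(self, toy_scenario):
        model = intercept_only_model(math.log(0.05), se=0.3)
        with pytest.warns(UserWarning, match="n_draws"):
            mc_percentile(model, toy_scenario, n_draws=50, seed=1)

    def test_residual_flag_widens_the_distribution(self, toy_scenario):
        model = intercept_only_model(math.log(0.05), se=0.1, residual_log_sd=0.8)
        narrow = mc_percentile(model, toy_scenario, seed=2)
        wide = mc_percentile(model, toy_scenario, seed=2, include_residual=True)
        assert wide > narrow


class TestAdjustmentFactors:
    def test_separation_is_25_percent_reduction(self):
        assert apply_separation_factor(0.100) == pytest.approx(0.075)
        assert apply_separation_factor(0.0) == 0.0

    def test_separation_composition(self):
        twice = apply_separation_factor(apply_separation_factor(0.1))
        assert twice == pytest.approx(0.1 * 0.5625)

    def test_separation_rejects_negative(self):
        with pytest.raises(InvalidInputError):
            apply_separation_factor(-0.1)

    @pytest.mark.parametrize(
        "hours, expected",
        [(3.0, 0.05), (3.999, 0.05), (4.0, 0.10), (5.0, 0.10)],
    )
    def test_duration_discount_strict_boundary(self, hours, expected):
        assert apply_duration_discount(0.10, hours) == pytest.approx(expected)

    def test_duration_discount_rejects_nonpositive_duration(self):
        with pytest.raises(InvalidInputError):
            apply_duration_discount(0.1, 0.0)


class TestRespirator:
    def test_under_oel_not_required(self):
        rec = recommend_respirator(0.020, 0.025)
        assert not rec.required and rec.minimum_apf == 1.0

    def test_hazard_ratio_8_selects_apf_10(self):
        rec = recommend_respirator(0.200, 0.025)
        assert rec.required
        assert rec.minimum_apf == 10.0
        assert rec.hazard_ratio == pytest.approx(8.0)

    def test_ladder_is_least_protective_sufficient_class(self):
        assert recommend_respirator(0.025 * 49, 0.025).minimum_apf == 50.0
        assert recommend_respirator(0.025 * 99, 0.025).minimum_apf == 100.0

    def test_extreme_ratio_escalates(self):
        rec = recommend_respirator(10.0, 0.025)  # ratio 400 < 1000 → supplied air
        assert rec.minimum_apf == 1000.0
        rec = recommend_respirator(50.0, 0.025)  # ratio 2000 → beyond the ladder
        assert rec.escalate and rec.required

    def test_nonpositive_oel_rejected(self):
        with pytest.raises(InvalidInputError):
            recommend_respirator(0.1, 0.0)


class TestAssess:
    def test_no_controls_means_equal_estimates(self, toy_scenario, oel):
        model = intercept_only_model(math.log(0.05), se=0.2)
        est = assess(model, toy_scenario, oel=oel, seed=4)
        assert est.controlled_p95 == est.uncontrolled_p95
        assert not est.separation_applied
        assert not est.duration_discount_applied

    def test_wetting_halves_with_zero_variance(self, oel):
        model = control_model(math.log(0.2), {"wetting": -math.log(2)})
        scen = Scenario(
            csp_id="x", sector="s", project_type="p", environment="e",
            region="r", controls={"wetting"},
        )
        est = assess(model, scen, oel=oel, seed=0)
        assert est.uncontrolled_p95 == pytest.approx(0.2, rel=1e-12)
        assert est.controlled_p95 == pytest.approx(0.1, rel=1e-12)

    def test_separation_and_discount_audit_flags(self, oel):
        model = control_model(math.log(0.2), {})
        scen = Scenario(
            csp_id="x", sector="s", project_type="p", environment="e",
            region="r", task_duration_hours=3.0, controls={"separation"},
        )
        est = assess(model, scen, oel=oel, seed=0)
        assert est.separation_applied and est.duration_discount_applied
        # 0.2 × 0.75 (separation) × 0.5 (short duration), each applied once
        assert est.controlled_p95 == pytest.approx(0.2 * 0.75 * 0.5, rel=1e-12)
        assert est.uncontrolled_p95 == pytest.approx(0.2, rel=1e-12)

    def test_oel_verdicts_and_respirator_contract(self, oel):
        model = control_model(math.log(0.2), {"wetting": -3.0})
        scen = Scenario(csp_id="x", sector="s", project_type="p",
                        environment="e", region="r", controls={"wetting"})
        est = assess(model, scen, oel=oel, seed=0)
        assert est.over_oel_uncontrolled
        assert not est.over_oel_controlled
        assert not est.respirator.required

    def test_what_if_iteration_does_not_mutate_inputs(self, oel):
        model = control_model(math.log(0.2), {"wetting": -0.7})
        scen = Scenario(csp_id="x", sector="s", project_type="p",
                        environment="e", region="r", controls={"wetting"})
        before_model = dataclasses.asdict(model)
        before_scen = dataclasses.asdict(scen)
        for ctls in [set(), {"wetting"}, {"wetting", "separation"}]:
            assess(model, dataclasses.replace(scen, controls=frozenset(ctls)),
                   oel=oel, seed=1)
        assert dataclasses.asdict(model) == before_model
        assert dataclasses.asdict(scen) == before_scen

    def test_default_oel_is_bc_value(self):
        assert DEFAULT_OEL == 0.025


class TestValidationRoutine:
    def test_empty_set_returns_empty_report(self):
        model = intercept_only_model(math.log(0.05))
        report = validate_against_measurements(model, [])
        assert report.n_csps == 0
        assert math.isnan(report.mean_gm_ratio)

    def test_identical_training_data_zero_se_gm_ratio_one(self):
        vals = [0.02, 0.05, 0.04, 0.03, 0.06]
        recs = [make_record(concentration=v, sector="a") for v in vals]
        recs += [make_record(concentration=v * 2, sector="b") for v in vals]
        model = fit_model(
            recs,
            {"categoricals": ("sector",), "duration_term": None,
             "controls": (), "min_cell_count": 2},
        )
        # force zero coefficient uncertainty so the GM comparison is exact
        coeffs = {t: (e, 0.0) for t, (e, _) in model.coefficients.items()}
        model = dataclasses.replace(model, coefficients=coeffs)
        report = validate_against_measurements(model, recs, seed=0)
        assert report.n_csps == 1  # single CSP in the fixture records
        assert report.per_csp[0].gm_ratio == pytest.approx(1.0, rel=1e-9)

    def test_small_csp_groups_excluded_with_warning(self):
        model = intercept_only_model(math.log(0.05))
        recs = [make_record(csp_id="lonely"), make_record(csp_id="lonely")]
        with pytest.warns(UserWarning, match="excluded"):
            report = validate_against_measurements(model, recs)
        assert report.excluded_csps == ("lonely",)
        assert report.n_csps == 0
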