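"""Exposure-model fitting, scenario encoding, and serialization."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from silicarisk import (
    Scenario,
    SilicaExposureRegressor,
    deserialize_model,
    encode_scenario,
    fit_model,
    serialize_model,
)
from silicarisk.errors import (
    InsufficientDataError,
    InvalidInputError,
    RankDeficiencyError,
    SchemaVersionError,
    UnknownLevelError,
)

from conftest import intercept_only_model, make_record


def two_group_records():
    """Binary sector predictor, three concentrations per group."""
    a_vals = [0.02, 0.05, 0.04]
    b_vals = [0.10, 0.20, 0.15]
    recs = [make_record(concentration=v, sector="a") for v in a_vals]
    recs += [make_record(concentration=v, sector="b") for v in b_vals]
    return recs, a_vals, b_vals


TOY_SPEC = {
    "categoricals": ("sector",),
    "duration_term": None,
    "controls": (),
    "min_cell_count": 2,
}


class TestFitModel:
    def test_two_group_closed_form(self):
        recs, a_vals, b_vals = two_group_records()
        model = fit_model(recs, TOY_SPEC, db_version="toy-v1")
        expected = np.mean(np.log(b_vals)) - np.mean(np.log(a_vals))
        est, se = model.coefficients["sector=b"]
        assert est == pytest.approx(expected, abs=1e-10)
        assert se > 0
        assert model.reference_levels == {"sector": "a"}
        assert model.db_version == "toy-v1"
        assert model.fit_n == 6

    def test_matches_brute_force_normal_equations(self):
        # independent oracle: build the one-hot design by hand, solve lstsq
        rng = np.random.default_rng(11)
        sectors = ["a", "b", "c"] * 6
        envs = ["in", "out"] * 9
        y = rng.lognormal(-3, 0.7, size=18)
        recs = [
            make_record(concentration=float(yi), sector=s, environment=e)
            for yi, s, e in zip(y, sectors, envs)
        ]
        spec = {**TOY_SPEC, "categoricals": ("sector", "environment")}
        model = fit_model(recs, spec)

        X = np.column_stack([
            np.ones(18),
            [1.0 if s == "b" else 0.0 for s in sectors],
            [1.0 if s == "c" else 0.0 for s in sectors],
            [1.0 if e == "out" else 0.0 for e in envs],
        ])
        beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
        fitted = [model.coefficients[t][0] for t in
                  ("Intercept", "sector=b", "sector=c", "environment=out")]
        assert fitted == pytest.approx(list(beta), abs=1e-8)

    def test_scale_equivariance_shifts_only_intercept(self):
        recs, *_ = two_group_records()
        base = fit_model(recs, TOY_SPEC)
        k = 3.7
        scaled_recs = [
            make_record(concentration=r.concentration * k, sector=r.sector)
            for r in recs
        ]
        scaled = fit_model(scaled_recs, TOY_SPEC)
        assert scaled.coefficients["Intercept"][0] == pytest.approx(
            base.coefficients["Intercept"][0] + math.log(k), abs=1e-10
        )
        assert scaled.coefficients["sector=b"][0] == pytest.approx(
            base.coefficients["sector=b"][0], abs=1e-10
        )

    def test_row_permutation_invariance(self):
        recs, *_ = two_group_records()
        a = fit_model(recs, TOY_SPEC)
        b = fit_model(list(reversed(recs)), TOY_SPEC)
        for t in a.term_catalog:
            assert a.coefficients[t][0] == pytest.approx(
                b.coefficients[t][0], abs=1e-10
            )

    def test_rank_deficient_design_names_aliased_terms(self):
        # sector and environment perfectly confounded
        recs = [
            make_record(concentration=0.05 * (i + 1), sector=s,
                        environment="in" if s == "a" else "out")
            for i, s in enumerate(["a", "a", "a", "b", "b", "b"])
        ]
        spec = {**TOY_SPEC, "categoricals": ("sector", "environment")}
        with pytest.raises(RankDeficiencyError) as err:
            fit_model(recs, spec)
        assert err.value.aliased_terms  # names at least one offender

    def test_insufficient_cell_count_names_variable(self):
        recs, *_ = two_group_records()
        with pytest.raises(InsufficientDataError) as err:
            fit_model(recs, {**TOY_SPEC, "min_cell_count": 5})
        assert err.value.variable == "sector"

    def test_nonpositive_concentration_rejected(self):
        recs = [make_record(concentration=0.0, sector="a")] * 3
        with pytest.raises(InvalidInputError):
            fit_model(recs, TOY_SPEC)

    def test_separation_cannot_be_fitted(self):
        recs, *_ = two_group_records()
        with pytest.raises(InvalidInputError):
            fit_model(recs, {**TOY_SPEC, "controls": ("separation",)})


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = SilicaExposureRegressor(min_cell_count=3, db_version="v9")
        params = est.get_params()
        assert params["min_cell_count"] == 3
        clone = SilicaExposureRegressor(**params)
        assert clone.get_params() == params

    def test_fitted_attributes_and_predict(self):
        recs, a_vals, b_vals = two_group_records()
        est = SilicaExposureRegressor(**TOY_SPEC)
        from silicarisk.model import records_to_frame

        est.fit(records_to_frame(recs))
        assert est.residual_log_sd_ > 0
        assert est.term_catalog_ == ["Intercept", "sector=b"]
        preds = est.predict(pd.DataFrame(
            {"sector": ["a", "b"], "controls": [set(), set()]}
        ))
        gm_a = np.exp(np.mean(np.log(a_vals)))
        gm_b = np.exp(np.mean(np.log(b_vals)))
        assert preds == pytest.approx([gm_a, gm_b], rel=1e-9)


class TestEncodeScenario:
    def test_reference_scenario_is_intercept_plus_duration(self):
        recs, *_ = two_group_records()
        recs = [
            dataclasses.replace(r, duration=60.0 * (i + 1))
            for i, r in enumerate(recs)
        ]
        model = fit_model(recs, {**TOY_SPEC, "duration_term": "log_duration"})
        scen = Scenario(
            csp_id="x", sector="a", project_type="p", environment="e",
            region="r", sampling_duration=math.e,
        )
        x = encode_scenario(scen, model)
        assert dict(zip(model.term_catalog, x)) == {
            "Intercept": 1.0, "log_duration": 1.0, "sector=b": 0.0,
        }

    def test_single_nonreference_indicator(self):
        recs, *_ = two_group_records()
        model = fit_model(recs, TOY_SPEC)
        scen = Scenario(csp_id="x", sector="b", project_type="p",
                        environment="e", region="r")
        x = encode_scenario(scen, model)
        assert list(x) == [1.0, 1.0]

    def test_unknown_level_never_coerced(self):
        recs, *_ = two_group_records()
        model = fit_model(recs, TOY_SPEC)
        scen = Scenario(csp_id="x", sector="z", project_type="p",
                        environment="e", region="r")
        with pytest.raises(UnknownLevelError) as err:
            encode_scenario(scen, model)
        assert err.value.variable == "sector"
        assert err.value.level == "z"

    def test_unfitted_control_raises(self):
        model = intercept_only_model(math.log(0.1))
        scen = Scenario(csp_id="x", sector="s", project_type="p",
                        environment="e", region="r", controls={"LEV"})
        with pytest.raises(UnknownLevelError):
            encode_scenario(scen, model)


class TestSerialization:
    def test_round_trip_is_lossless(self):
        recs, *_ = two_group_records()
        model = fit_model(recs, TOY_SPEC, db_version="db-2026-01")
        doc = serialize_model(model)
        back = deserialize_model(doc)
        assert back == model  # bit-exact dataclass equality
        assert back.db_version == "db-2026-01"

    def test_missing_field_is_schema_error(self):
        model = intercept_only_model(0.0)
        doc = serialize_model(model)
        del doc["residual_log_sd"]
        with pytest.raises(SchemaVersionError):
            deserialize_model(doc)

    def test_wrong_schema_version_rejected(self):
        doc = serialize_model(intercept_only_model(0.0))
        doc["schema_version"] = "99"
        with pytest.raises(SchemaVersionError):
            deserialize_model(doc)
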