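import math

import pytest

from silicarisk import (
    ExposureMeasurement,
    ExposureModel,
    Scenario,
)


def make_record(**overrides) -> ExposureMeasurement:
    """A fully QC-passing measurement; override fields to plant failures."""
    fields = dict(
        concentration=0.08,
        duration=240.0,
        csp_id="concrete_cutting_saw",
        sector="civil",
        project_type="new",
        environment="outdoor",
        region="coast",
        analyte="RCS",
        method="NIOSH 7602",
        sample_type="personal",
        flow_rate=2.5,
        qaqc_confirmed=True,
        context_complete=True,
    )
    fields.update(overrides)
    return ExposureMeasurement(**fields)


def intercept_only_model(mu: float, se: float = 0.0, residual_log_sd: float = 0.5,
                         db_version: str = "toy") -> ExposureModel:
    return ExposureModel(
        coefficients={"Intercept": (mu, se)},
        reference_levels={},
        residual_log_sd=residual_log_sd,
        db_version=db_version,
        fit_n=10,
        term_catalog=("Intercept",),
        duration_term=None,
    )


def control_model(mu: float, control_effects: dict[str, float],
                  se: float = 0.0) -> ExposureModel:
    """Intercept + zero-SE control terms; closed-form predictions."""
    coeffs = {"Intercept": (mu, se)}
    for ctl, eff in control_effects.items():
        coeffs[f"control={ctl}"] = (eff, se)
    catalog = tuple(coeffs)
    return ExposureModel(
        coefficients=coeffs,
        reference_levels={},
        residual_log_sd=0.5,
        db_version="toy",
        fit_n=len(catalog) + 5,
        term_catalog=catalog,
        duration_term=None,
    )


@pytest.fixture
def passing_record():
    return make_record()


@pytest.fixture
def toy_scenario():
    return Scenario(
        csp_id="concrete_cutting_saw",
        sector="civil",
        project_type="new",
        environment="outdoor",
        region="coast",
        sampling_duration=240.0,
        task_duration_hours=8.0,
    )


@pytest.fixture
def oel():
    return 0.025


@pytest.fixture
def log01():
    return math.log(0.1)
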