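"""Synthetic exposure databases with known ground truth.

Real RCS exposure databases are proprietary, so testable ground truth comes
from simulation: concentrations follow the same multiplicative structure
the regression assumes, ``C = exp(xβ + ε)`` with ``ε ~ N(0, σ²)`` on the
log scale, over categorical determinants drawn from configurable level
frequencies and Bernoulli engineering-control indicators with negative true
effects. Values falling below a configurable LOD are flagged non-detect
(with that LOD recorded) and left for the QC layer to substitute, exactly
as literature data would arrive.

The default specification mirrors a construction-sector database: 24 CSP
levels, three sectors, three project types, four environments, three
regions, four fitted controls, a baseline geometric mean of 0.05 mg/m³
(intercept ln 0.05), residual log-SD 0.8 (GSD ≈ 2.2), and an LOD placed so
roughly 15% of generated values are non-detects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidInputError
from .measurements import Analyte, ExposureMeasurement, SampleType, Source
from .model import INTERCEPT, LOG_DURATION

#: Reference levels implied by the default generating model (levels whose
#: true effect is zero); pass these to the fitter when comparing recovered
#: coefficients with the ground truth term-for-term.
DEFAULT_REFERENCE_LEVELS = {
    "csp_id": "csp_00",
    "sector": "civil",
    "project_type": "new",
    "environment": "outdoor",
    "region": "coast",
}


@dataclass(frozen=True)
class TrueModelSpec:
    """Ground-truth generating model for a synthetic exposure database.

    ``true_coefficients`` uses the same term names as the fitted model:
    ``Intercept``, ``log_duration``, ``var=level`` and ``control=id``.
    Levels without a coefficient have true effect zero (reference levels).
    ``level_frequencies`` gives a sampling distribution per categorical
    variable; ``control_frequencies`` the marginal probability each control
    is present (independent Bernoulli).
    """

    true_coefficients: dict[str, float]
    residual_log_sd: float
    level_frequencies: dict[str, dict[str, float]]
    control_frequencies: dict[str, float] = field(default_factory=dict)
    nondetect_lod: Optional[float] = None  # mg/m³
    n: int = 1000
    seed: int = 0
    duration_minutes: tuple[float, float] = (60.0, 480.0)  # log-uniform range

    def __post_init__(self):
        if self.n < 1:
            raise InvalidInputError(f"n must be ≥ 1, got {self.n}")
        if self.residual_log_sd < 0:
            raise InvalidInputError("residual_log_sd must be ≥ 0")
        if not self.true_coefficients:
            raise InvalidInputError("true_coefficients must not be empty")
        for var, dist in self.level_frequencies.items():
            total = sum(dist.values())
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise InvalidInputError(
                    f"level frequencies for {var!r} sum to {total}, not 1"
                )


def default_true_model(
    n: int = 5000, seed: int = 0, nondetect_lod: Optional[float] = 0.0078
) -> TrueModelSpec:
    """The default construction-sector generating model (see module docs).

    CSP effects span about e^±1 around the baseline; controls reduce
    exposure by factors between ~0.35 and ~0.6. The default LOD of
    0.0078 mg/m³ (the marginal 15th percentile of the generated
    concentrations) puts the non-detect fraction near 15%.
    """
    rng = np.random.default_rng(20210521)  # fixed: the *spec* is a constant
    csp_ids = [f"csp_{i:02d}" for i in range(24)]
    csp_effects = {
        f"csp_id={c}": float(e)
        for c, e in zip(csp_ids[1:], rng.uniform(-1.0, 1.5, size=23))
    }
    coeffs = {
        INTERCEPT: math.log(0.05),
        LOG_DURATION: -0.15,
        **csp_effects,
        "sector=industrial": 0.3,
        "sector=residential": -0.2,
        "project_type=demolition": 0.5,
        "project_type=renovation": 0.2,
        "environment=indoor": 0.4,
        "environment=restricted": 0.7,
        "environment=confined": 1.0,
        "region=interior": 0.1,
        "region=north": -0.1,
        "control=LEV": -0.5,
        "control=LEV_integrated": -0.9,
        "control=wetting": -0.7,
        "control=waterspray_integrated": -1.0,
    }
    uniform = {c: 1.0 / len(csp_ids) for c in csp_ids}
    return TrueModelSpec(
        true_coefficients=coeffs,
        residual_log_sd=0.8,
        level_frequencies={
            "csp_id": uniform,
            "sector": {"civil": 0.3, "industrial": 0.3, "residential": 0.4},
            "project_type": {"new": 0.5, "renovation": 0.3, "demolition": 0.2},
            "environment": {"outdoor": 0.5, "indoor": 0.3, "restricted": 0.15,
                            "confined": 0.05},
            "region": {"coast": 0.5, "interior": 0.3, "north": 0.2},
        },
        control_frequencies={
            "LEV": 0.15, "LEV_integrated": 0.1, "wetting": 0.2,
            "waterspray_integrated": 0.1,
        },
        nondetect_lod=nondetect_lod,
        n=n,
        seed=seed,
    )


def true_log_mean(spec: TrueModelSpec, covariates: dict[str, str],
                  controls: set[str], duration: float) -> float:
    """Ground-truth linear predictor for a fixed covariate pattern."""
    lp = spec.true_coefficients.get(INTERCEPT, 0.0)
    lp += spec.true_coefficients.get(LOG_DURATION, 0.0) * math.log(duration)
    for var, level in covariates.items():
        lp += spec.true_coefficients.get(f"{var}={level}", 0.0)
    for ctl in controls:
        lp += spec.true_coefficients.get(f"control={ctl}", 0.0)
    return lp


def generate_database(spec: TrueModelSpec) -> list[ExposureMeasurement]:
    """Draw a synthetic measurement database from the ground-truth model.

    Non-detects are flagged (concentration kept at the true simulated value,
    LOD recorded); substitution with ½ LOD is the QC layer's job. All
    records carry complete QC metadata so they pass validation unchanged.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.duration_minutes
    records: list[ExposureMeasurement] = []
    for _ in range(spec.n):
        covariates = {
            var: str(rng.choice(list(dist), p=list(dist.values())))
            for var, dist in spec.level_frequencies.items()
        }
        controls = {
            ctl for ctl, p in spec.control_frequencies.items()
            if rng.random() < p
        }
        duration = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        lp = true_log_mean(spec, covariates, controls, duration)
        eps = rng.normal(0.0, spec.residual_log_sd) if spec.residual_log_sd else 0.0
        conc = float(np.exp(lp + eps))
        nondetect = spec.nondetect_lod is not None and conc < spec.nondetect_lod
        records.append(
            ExposureMeasurement(
                concentration=conc,
                duration=duration,
                csp_id=covariates.get("csp_id", "csp_00"),
                sector=covariates.get("sector", "civil"),
                project_type=covariates.get("project_type", "new"),
                environment=covariates.get("environment", "outdoor"),
                region=covariates.get("region", "coast"),
                analyte=Analyte.RCS,
                method="NIOSH 7500",
                sample_type=SampleType.PERSONAL,
                nondetect_flag=nondetect,
                lod=spec.nondetect_lod if nondetect else None,
                flow_rate=2.5,
                qaqc_confirmed=True,
                context_complete=True,
                controls=frozenset(controls),
                source=Source.SYNTHETIC,
            )
        )
    return records


@dataclass(frozen=True)
class QCFixtureSet:
    """Labeled records with planted QC failures for exact expected counts."""

    records: tuple[ExposureMeasurement, ...]
    expected_failures: tuple[tuple[str, ...], ...]  # per record, () = passes

    @property
    def n_passing(self) -> int:
        return sum(1 for f in self.expected_failures if not f)


def generate_qc_fixtures(seed: int = 0) -> QCFixtureSet:
    """Six single-criterion failures plus four fully passing records.

    Each failing record violates exactly one of the six validity criteria,
    so a QC report over the set enumerates every criterion identifier.
    """
    rng = np.random.default_rng(seed)

    def base(**overrides) -> ExposureMeasurement:
        fields = dict(
            concentration=float(rng.lognormal(math.log(0.05), 0.8)),
            duration=float(rng.uniform(120, 480)),
            csp_id="concrete_cutting_saw",
            sector="civil",
            project_type="new",
            environment="outdoor",
            region="coast",
            analyte=Analyte.RCS,
            method="NIOSH 7500",
            sample_type=SampleType.PERSONAL,
            flow_rate=2.5,
            qaqc_confirmed=True,
            context_complete=True,
            source=Source.SYNTHETIC,
        )
        fields.update(overrides)
        return ExposureMeasurement(**fields)

    records = [
        base(analyte=Analyte.RESPIRABLE_DUST),      # fails i
        base(method="gravimetric, in-house"),       # fails ii
        base(flow_rate=None),                       # fails iii
        base(qaqc_confirmed=False),                 # fails iv
        base(context_complete=False),               # fails v
        base(sample_type=SampleType.AREA),          # fails vi
        base(), base(), base(), base(),             # four passing
    ]
    expected = (
        ("i_analyte",), ("ii_method",), ("iii_params",),
        ("iv_qaqc",), ("v_context",), ("vi_personal",),
        (), (), (), (),
    )
    return QCFixtureSet(records=tuple(records), expected_failures=expected)
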