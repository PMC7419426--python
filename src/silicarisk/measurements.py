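"""Exposure-measurement data model, QC validation, and non-detect handling.

A measurement record is one personal (or area) sample of respirable
crystalline silica (RCS) with the covariates the exposure model uses
(task/tool/material via a CSP id, sector, project type, environment,
region, duration) plus the analytical metadata the QC rules inspect.

Quality control applies six independent validity criteria:

``i_analyte``
    the analyte must be RCS (quartz/cristobalite pass only when masses and
    air volume permit consolidation; respirable dust never passes);
``ii_method``
    a standard analytical method must have been used;
``iii_params``
    key sampling parameters (flow rate, duration) must be reported;
``iv_qaqc``
    original QA/QC (calibration, field blanks, sample volume) confirmed;
``v_context``
    sufficient supplementary data to judge equivalence of work operations;
``vi_personal``
    the sample must be personal (breathing-zone), not area.

Validation never raises: every failed criterion is reported, so a curator
sees all problems with a record at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

from .errors import InvalidInputError

#: Standard analytical methods accepted by default. The set is open —
#: pass your own ``allowed_methods`` to extend or restrict it.
DEFAULT_ALLOWED_METHODS = frozenset(
    {"NIOSH 7500", "NIOSH 7500-PPI-8LPM", "NIOSH 7602", "OSHA ID-142"}
)

QC_CRITERIA = (
    "i_analyte",
    "ii_method",
    "iii_params",
    "iv_qaqc",
    "v_context",
    "vi_personal",
)


class Analyte(str, Enum):
    RCS = "RCS"
    QUARTZ = "quartz"
    CRISTOBALITE = "cristobalite"
    RESPIRABLE_DUST = "respirable_dust"
    OTHER = "other"


class SampleType(str, Enum):
    PERSONAL = "personal"
    AREA = "area"


class Source(str, Enum):
    LITERATURE = "literature"
    INDUSTRY = "industry"
    GOVERNMENT = "government"
    CAMPAIGN = "campaign"
    DEAGGREGATED = "deaggregated"
    SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class ExposureMeasurement:
    """One RCS sample with covariates and QC metadata.

    Concentrations are stored in mg/m³ throughout; µg/m³ inputs must be
    converted at parse time. ``controls`` holds engineering-control
    identifiers (see :mod:`silicarisk.model`).
    """

    concentration: float  # mg/m³
    duration: float  # sampling duration, minutes
    csp_id: str
    sector: str
    project_type: str
    environment: str
    region: str
    analyte: Analyte = Analyte.RCS
    method: str = ""
    sample_type: SampleType = SampleType.PERSONAL
    nondetect_flag: bool = False
    lod: Optional[float] = None  # mg/m³, present when nondetect_flag
    quartz_mass: Optional[float] = None  # mg
    cristobalite_mass: Optional[float] = None  # mg
    air_volume: Optional[float] = None  # m³
    flow_rate: Optional[float] = None  # L/min
    qaqc_confirmed: bool = False
    context_complete: bool = False
    controls: frozenset[str] = field(default_factory=frozenset)
    source: Source = Source.CAMPAIGN
    weight: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "controls", frozenset(self.controls))
        object.__setattr__(self, "analyte", Analyte(self.analyte))
        object.__setattr__(self, "sample_type", SampleType(self.sample_type))
        object.__setattr__(self, "source", Source(self.source))


@dataclass(frozen=True)
class QCResult:
    """Outcome of validating one record: all failed criteria with reasons."""

    passed: bool
    failures: tuple[tuple[str, str], ...]  # (criterion id, human-readable reason)

    @property
    def failed_criteria(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.failures)


@dataclass(frozen=True)
class CSPDescriptor:
    """A Common Silica Process: task + material + tool triple."""

    csp_id: str
    material: str
    task: str
    tool: str
    label: str = ""


def validate_record(
    record: ExposureMeasurement,
    allowed_methods: Iterable[str] = DEFAULT_ALLOWED_METHODS,
) -> QCResult:
    """Apply the six validity criteria to a record.

    All criteria are evaluated independently; every failure is reported.
    Never raises — malformed field values become failures.
    """
    allowed = {m.strip().casefold() for m in allowed_methods}
    failures: list[tuple[str, str]] = []

    if record.analyte == Analyte.RCS:
        pass
    elif record.analyte in (Analyte.QUARTZ, Analyte.CRISTOBALITE):
        if record.air_volume is None or record.air_volume <= 0:
            failures.append(
                (
                    "i_analyte",
                    f"analyte {record.analyte.value} cannot be consolidated to RCS "
                    "without a positive air volume",
                )
            )
    else:
        failures.append(
            ("i_analyte", f"analyte is {record.analyte.value}, not RCS")
        )

    if record.method.strip().casefold() not in allowed:
        failures.append(
            ("ii_method", f"method {record.method!r} is not an accepted standard method")
        )

    param_problems = []
    if record.flow_rate is None or record.flow_rate <= 0:
        param_problems.append("flow rate missing or nonpositive")
    if record.duration is None or record.duration <= 0:
        param_problems.append("duration missing or nonpositive")
    if param_problems:
        failures.append(("iii_params", "; ".join(param_problems)))

    if not record.qaqc_confirmed:
        failures.append(("iv_qaqc", "original QA/QC not confirmed"))

    if not record.context_complete:
        failures.append(
            ("v_context", "insufficient supplementary data to judge equivalence")
        )

    if record.sample_type != SampleType.PERSONAL:
        failures.append(
            ("vi_personal", f"sample type is {record.sample_type.value}, not personal")
        )

    return QCResult(passed=not failures, failures=tuple(failures))


def consolidate_polymorphs(
    quartz_mass: Optional[float],
    cristobalite_mass: Optional[float],
    air_volume: float,
) -> float:
    """Consolidate quartz and cristobalite masses into an RCS concentration.

    Adds the polymorph masses (mg; an absent mass counts as zero) and
    divides by the total air volume sampled (m³), giving mg/m³.
    """
    if air_volume is None or air_volume <= 0:
        raise InvalidInputError(f"air_volume must be positive, got {air_volume}")
    q = 0.0 if quartz_mass is None else float(quartz_mass)
    c = 0.0 if cristobalite_mass is None else float(cristobalite_mass)
    if q < 0 or c < 0:
        raise InvalidInputError("polymorph masses must be nonnegative")
    return (q + c) / float(air_volume)


def substitute_nondetect(record: ExposureMeasurement) -> ExposureMeasurement:
    """Replace a non-detect's concentration with half its limit of detection.

    Detected records are returned unchanged; the operation is idempotent.
    """
    if not record.nondetect_flag:
        return record
    if record.lod is None or record.lod <= 0:
        raise InvalidInputError(
            f"non-detect record requires a positive LOD, got {record.lod}"
        )
    return replace(record, concentration=record.lod / 2.0)


def filter_database(
    records: Iterable[ExposureMeasurement],
    allowed_methods: Iterable[str] = DEFAULT_ALLOWED_METHODS,
) -> tuple[list[ExposureMeasurement], list[QCResult]]:
    """Validate every record; return (passing records, one QCResult per input).

    The report preserves input order; the passing list preserves the relative
    order of passing records. Idempotent on the passing subset.
    """
    records = list(records)
    report = [validate_record(r, allowed_methods) for r in records]
    passing = [r for r, qc in zip(records, report) if qc.passed]
    return passing, report
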