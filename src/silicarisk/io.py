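"""CSV and JSON I/O for the measurement and summary-statistic schemas.

The measurement CSV is one row per sample, UTF-8 with a header. A
``units`` column is required and must be ``mg/m3`` or ``ug/m3``;
microgram inputs are converted at parse time so concentrations are mg/m³
everywhere downstream. Controls are a semicolon-separated identifier list.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .deaggregate import SummaryStatRecord
from .errors import InvalidInputError
from .measurements import ExposureMeasurement, QCResult

MEASUREMENT_COLUMNS = [
    "concentration", "units", "nondetect_flag", "lod",
    "quartz_mass", "cristobalite_mass", "air_volume",
    "analyte", "method", "flow_rate", "duration", "sample_type",
    "qaqc_confirmed", "context_complete",
    "csp_id", "sector", "project_type", "environment", "region",
    "controls", "source", "weight",
]

_UNIT_FACTORS = {"mg/m3": 1.0, "ug/m3": 1e-3}


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes", "y"}
    return bool(value)


def read_measurements(path: Path) -> list[ExposureMeasurement]:
    df = pd.read_csv(path, dtype={"controls": str, "method": str})
    if "units" not in df.columns:
        raise InvalidInputError("measurement CSV requires an explicit 'units' column")
    records = []
    for row in df.to_dict("records"):
        unit = str(row["units"]).strip()
        if unit not in _UNIT_FACTORS:
            raise InvalidInputError(
                f"unknown concentration unit {unit!r}; expected mg/m3 or ug/m3"
            )
        f = _UNIT_FACTORS[unit]
        controls_raw = row.get("controls")
        controls = (
            frozenset(c for c in str(controls_raw).split(";") if c)
            if isinstance(controls_raw, str) and controls_raw
            else frozenset()
        )
        lod = _opt(row.get("lod"))
        records.append(
            ExposureMeasurement(
                concentration=float(row["concentration"]) * f,
                duration=float(row["duration"]),
                csp_id=str(row["csp_id"]),
                sector=str(row["sector"]),
                project_type=str(row["project_type"]),
                environment=str(row["environment"]),
                region=str(row["region"]),
                analyte=str(row.get("analyte", "RCS")),
                method=str(row.get("method", "") or ""),
                sample_type=str(row.get("sample_type", "personal")),
                nondetect_flag=_bool(row.get("nondetect_flag", False)),
                lod=lod * f if lod is not None else None,
                quartz_mass=_opt(row.get("quartz_mass")),
                cristobalite_mass=_opt(row.get("cristobalite_mass")),
                air_volume=_opt(row.get("air_volume")),
                flow_rate=_opt(row.get("flow_rate")),
                qaqc_confirmed=_bool(row.get("qaqc_confirmed", False)),
                context_complete=_bool(row.get("context_complete", False)),
                controls=controls,
                source=str(row.get("source", "campaign")),
                weight=float(row.get("weight", 1.0) if _opt(row.get("weight")) is not None else 1.0),
            )
        )
    return records


def write_measurements(records: Iterable[ExposureMeasurement], path: Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "concentration": r.concentration,
                "units": "mg/m3",
                "nondetect_flag": r.nondetect_flag,
                "lod": r.lod,
                "quartz_mass": r.quartz_mass,
                "cristobalite_mass": r.cristobalite_mass,
                "air_volume": r.air_volume,
                "analyte": r.analyte.value,
                "method": r.method,
                "flow_rate": r.flow_rate,
                "duration": r.duration,
                "sample_type": r.sample_type.value,
                "qaqc_confirmed": r.qaqc_confirmed,
                "context_complete": r.context_complete,
                "csp_id": r.csp_id,
                "sector": r.sector,
                "project_type": r.project_type,
                "environment": r.environment,
                "region": r.region,
                "controls": ";".join(sorted(r.controls)),
                "source": r.source.value,
                "weight": r.weight,
            }
        )
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def read_summaries(path: Path) -> list[SummaryStatRecord]:
    """Summary-statistic CSV: n, center, center_kind, dispersion, dispersion_kind + covariates."""
    df = pd.read_csv(path)
    out = []
    for row in df.to_dict("records"):
        controls_raw = row.get("controls")
        controls = (
            frozenset(c for c in str(controls_raw).split(";") if c)
            if isinstance(controls_raw, str) and controls_raw
            else frozenset()
        )
        out.append(
            SummaryStatRecord(
                n=int(row["n"]),
                center=float(row["center"]),
                center_kind=str(row["center_kind"]),
                dispersion=float(row["dispersion"]),
                dispersion_kind=str(row["dispersion_kind"]),
                csp_id=str(row.get("csp_id", "")),
                sector=str(row.get("sector", "")),
                project_type=str(row.get("project_type", "")),
                environment=str(row.get("environment", "")),
                region=str(row.get("region", "")),
                duration=float(row.get("duration", 480.0)),
                controls=controls,
            )
        )
    return out


def write_qc_report(report: Iterable[QCResult], path: Path) -> None:
    doc = [
        {"passed": qc.passed,
         "failures": [{"criterion": c, "reason": r} for c, r in qc.failures]}
        for qc in report
    ]
    Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")
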