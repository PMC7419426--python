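"""Exposure control plan (ECP) assembly, archive, and rendering.

An ECP is the regulator-required document for work that may expose
workers to RCS: who is doing what, where, the quantitative risk
assessment (uncontrolled and controlled 95th-percentile estimates against
the OEL), the engineering and administrative controls, and the PPE —
including the respirator recommendation when controls leave a residual
over-exposure. One document covers exactly one silica control process;
more complex jobs are broken into separate task-level ECPs.

Administrative controls are printed but never enter the quantitative
estimates. Every document is version-stamped with the database release
behind its exposure model. The archive is a plain directory of JSON
documents plus an index: recallable, copyable, editable (new version),
and soft-deletable so the audit trail survives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .errors import ConsistencyError, InvalidInputError, NotFoundError, RenderError
from .model import Scenario
from .predict import RespiratorRecommendation, RiskEstimate

ECP_SCHEMA_VERSION = "1"

#: Sections a rendered ECP must contain, in order.
REQUIRED_SECTIONS = (
    "title_page",
    "job_details",
    "task_description",
    "risk_assessment",
    "engineering_controls",
    "administrative_controls",
    "ppe",
    "vicinity_statement",
    "version_stamp",
)

VICINITY_BOILERPLATE = (
    "Workers in the vicinity of this task, although not conducting it, may "
    "also be exposed to respirable crystalline silica. The employer must "
    "restrict access to the work area, post signage, and extend controls or "
    "protection to nearby workers as needed."
)


@dataclass(frozen=True)
class CompanyProfile:
    company_name: str
    contact: str = ""
    address: str = ""
    logo_path: Optional[str] = None

    def __post_init__(self):
        if not self.company_name.strip():
            raise InvalidInputError("company_name must be nonempty")


@dataclass(frozen=True)
class JobDetails:
    address: str = ""
    supervisor: str = ""
    start_date: str = ""
    end_date: str = ""


@dataclass(frozen=True)
class ECPDocument:
    profile: CompanyProfile
    job: JobDetails
    scenario: Scenario
    estimate: RiskEstimate
    engineering_controls: tuple[str, ...]
    administrative_controls: tuple[str, ...]
    ppe: tuple[str, ...]
    db_version: str
    created: str  # ISO timestamp, injectable for reproducible output
    ecp_id: str = ""
    provenance: Optional[str] = None  # source ecp_id when copied
    version: int = 1

    def __post_init__(self):
        if self.db_version != self.estimate.model_version:
            raise ConsistencyError(
                f"document db_version {self.db_version!r} must equal the "
                f"estimate's model_version {self.estimate.model_version!r}"
            )


_CONTROL_DESCRIPTIONS = {
    "LEV": "Local exhaust ventilation at the emission point",
    "LEV_integrated": "Local exhaust ventilation integrated with the tool",
    "wetting": "Material wetting (water suppression)",
    "waterspray_integrated": "Water-spray system integrated with the tool",
    "separation": "Separation from source (e.g., enclosed cab)",
}


def build_ecp(
    profile: CompanyProfile,
    job: JobDetails,
    scenario: Scenario,
    estimate: RiskEstimate,
    administrative_controls: Sequence[str] = (),
    created: str = "1970-01-01T00:00:00Z",
) -> ECPDocument:
    """Assemble an ECP from a scenario and its computed risk estimate.

    The scenario and estimate must describe the same CSP (one task per
    document). Administrative controls are listed verbatim and never alter
    the estimates.
    """
    if isinstance(scenario, (list, tuple)):
        raise InvalidInputError(
            "an ECP covers exactly one silica control process; "
            "build one document per task"
        )
    if scenario.csp_id != estimate.csp_id:
        raise ConsistencyError(
            f"scenario csp_id {scenario.csp_id!r} does not match the "
            f"estimate's csp_id {estimate.csp_id!r}"
        )
    engineering = tuple(
        _CONTROL_DESCRIPTIONS.get(c, c) for c in sorted(scenario.controls)
    )
    ppe = ["Eye protection and task-appropriate protective clothing"]
    if estimate.respirator.required:
        ppe.append(
            f"Respirator: {estimate.respirator.class_label} "
            f"(minimum APF {estimate.respirator.minimum_apf:g})"
        )
    else:
        ppe.append("Respirator: none required at the controlled exposure level")
    return ECPDocument(
        profile=profile,
        job=job,
        scenario=scenario,
        estimate=estimate,
        engineering_controls=engineering,
        administrative_controls=tuple(administrative_controls),
        ppe=tuple(ppe),
        db_version=estimate.model_version,
        created=created,
    )


# ---------------------------------------------------------------------------
# serialization

def document_to_dict(doc: ECPDocument) -> dict:
    return {
        "schema_version": ECP_SCHEMA_VERSION,
        "ecp_id": doc.ecp_id,
        "version": doc.version,
        "provenance": doc.provenance,
        "created": doc.created,
        "db_version": doc.db_version,
        "profile": {
            "company_name": doc.profile.company_name,
            "contact": doc.profile.contact,
            "address": doc.profile.address,
            "logo_path": doc.profile.logo_path,
        },
        "job": {
            "address": doc.job.address,
            "supervisor": doc.job.supervisor,
            "start_date": doc.job.start_date,
            "end_date": doc.job.end_date,
        },
        "scenario": {
            "csp_id": doc.scenario.csp_id,
            "sector": doc.scenario.sector,
            "project_type": doc.scenario.project_type,
            "environment": doc.scenario.environment,
            "region": doc.scenario.region,
            "sampling_duration": doc.scenario.sampling_duration,
            "task_duration_hours": doc.scenario.task_duration_hours,
            "controls": sorted(doc.scenario.controls),
        },
        "estimate": doc.estimate.to_dict(),
        "engineering_controls": list(doc.engineering_controls),
        "administrative_controls": list(doc.administrative_controls),
        "ppe": list(doc.ppe),
    }


def document_from_dict(d: dict) -> ECPDocument:
    est = d["estimate"]
    resp = est["respirator"]
    estimate = RiskEstimate(
        uncontrolled_p95=est["uncontrolled_p95_mg_m3"],
        controlled_p95=est["controlled_p95_mg_m3"],
        applied_controls=frozenset(est["applied_controls"]),
        separation_applied=est["separation_applied"],
        duration_discount_applied=est["duration_discount_applied"],
        oel=est["oel_mg_m3"],
        over_oel_uncontrolled=est["over_oel_uncontrolled"],
        over_oel_controlled=est["over_oel_controlled"],
        respirator=RespiratorRecommendation(
            required=resp["required"], minimum_apf=resp["minimum_apf"],
            class_label=resp["class_label"], hazard_ratio=resp["hazard_ratio"],
            escalate=resp["escalate"],
        ),
        n_draws=est["n_draws"],
        seed=est["seed"],
        model_version=est["model_version"],
        csp_id=est["csp_id"],
        percentile=est.get("percentile", 95.0),
    )
    return ECPDocument(
        profile=CompanyProfile(**d["profile"]),
        job=JobDetails(**d["job"]),
        scenario=Scenario(
            csp_id=d["scenario"]["csp_id"],
            sector=d["scenario"]["sector"],
            project_type=d["scenario"]["project_type"],
            environment=d["scenario"]["environment"],
            region=d["scenario"]["region"],
            sampling_duration=d["scenario"]["sampling_duration"],
            task_duration_hours=d["scenario"]["task_duration_hours"],
            controls=frozenset(d["scenario"]["controls"]),
        ),
        estimate=estimate,
        engineering_controls=tuple(d["engineering_controls"]),
        administrative_controls=tuple(d["administrative_controls"]),
        ppe=tuple(d["ppe"]),
        db_version=d["db_version"],
        created=d["created"],
        ecp_id=d.get("ecp_id", ""),
        provenance=d.get("provenance"),
        version=d.get("version", 1),
    )


# ---------------------------------------------------------------------------
# archive

class ECPArchive:
    """Directory-backed ECP store: recall, copy, edit, soft delete.

    Layout: ``<root>/index.json`` plus one ``<ecp_id>.v<version>.json`` per
    document version. Deletion tombstones the id in the index; the files
    remain for audit.
    """

    def __init__(self, root: Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._index_path = self.root / "index.json"
        if not self._index_path.exists():
            self._write_index({"next": 1, "entries": {}})

    def _read_index(self) -> dict:
        return json.loads(self._index_path.read_text(encoding="utf-8"))

    def _write_index(self, index: dict) -> None:
        self._index_path.write_text(json.dumps(index, indent=2), encoding="utf-8")

    def _doc_path(self, ecp_id: str, version: int) -> Path:
        return self.root / f"{ecp_id}.v{version}.json"

    def _entry(self, index: dict, ecp_id: str, allow_deleted: bool = False) -> dict:
        entry = index["entries"].get(ecp_id)
        if entry is None or (entry["deleted"] and not allow_deleted):
            raise NotFoundError(f"no ECP with id {ecp_id!r}")
        return entry

    def store(self, doc: ECPDocument, provenance: Optional[str] = None) -> ECPDocument:
        """Assign a fresh id (version 1) and persist the document."""
        index = self._read_index()
        ecp_id = f"ECP-{index['next']:06d}"
        index["next"] += 1
        stored = ECPDocument(
            **{**doc.__dict__, "ecp_id": ecp_id, "version": 1,
               "provenance": provenance},
        )
        self._doc_path(ecp_id, 1).write_text(
            json.dumps(document_to_dict(stored), indent=2), encoding="utf-8"
        )
        index["entries"][ecp_id] = {"latest": 1, "deleted": False,
                                    "provenance": provenance}
        self._write_index(index)
        return stored

    def recall(self, ecp_id: str, version: Optional[int] = None) -> ECPDocument:
        index = self._read_index()
        entry = self._entry(index, ecp_id)
        v = entry["latest"] if version is None else version
        path = self._doc_path(ecp_id, v)
        if not path.exists():
            raise NotFoundError(f"no version {v} of ECP {ecp_id!r}")
        return document_from_dict(json.loads(path.read_text(encoding="utf-8")))

    def copy(self, ecp_id: str) -> ECPDocument:
        """Duplicate under a new id with a provenance link to the source."""
        return self.store(self.recall(ecp_id), provenance=ecp_id)

    def edit(self, ecp_id: str, updated: ECPDocument) -> ECPDocument:
        """Persist a new version of an existing ECP (db_version unchanged)."""
        index = self._read_index()
        entry = self._entry(index, ecp_id)
        v = entry["latest"] + 1
        stored = ECPDocument(
            **{**updated.__dict__, "ecp_id": ecp_id, "version": v},
        )
        self._doc_path(ecp_id, v).write_text(
            json.dumps(document_to_dict(stored), indent=2), encoding="utf-8"
        )
        entry["latest"] = v
        self._write_index(index)
        return stored

    def delete(self, ecp_id: str) -> None:
        """Soft delete: tombstone the id; versions remain on disk for audit."""
        index = self._read_index()
        self._entry(index, ecp_id)["deleted"] = True
        self._write_index(index)

    def ids(self, include_deleted: bool = False) -> list[str]:
        index = self._read_index()
        return [
            k for k, e in sorted(index["entries"].items())
            if include_deleted or not e["deleted"]
        ]


# ---------------------------------------------------------------------------
# rendering

def _sections(doc: ECPDocument) -> dict[str, str]:
    est = doc.estimate
    s = doc.scenario
    verdict = lambda flag: "EXCEEDS the OEL" if flag else "is at or below the OEL"
    resp = est.respirator
    if resp.required and not resp.class_label:
        raise RenderError("respirator recommendation is required but empty")
    risk_lines = [
        f"Occupational exposure limit (OEL): {est.oel:g} mg/m3 (8-h TWA basis)",
        f"Uncontrolled 95th-percentile estimate: {est.uncontrolled_p95:.4f} mg/m3 "
        f"- {verdict(est.over_oel_uncontrolled)}",
        f"Controlled 95th-percentile estimate: {est.controlled_p95:.4f} mg/m3 "
        f"- {verdict(est.over_oel_controlled)}",
        f"Monte Carlo draws: {est.n_draws} (seed {est.seed})",
    ]
    if est.separation_applied:
        risk_lines.append("Separation-from-source factor applied (25% reduction).")
    if est.duration_discount_applied:
        risk_lines.append("Short-duration (<4 h) discount applied (50%).")
    return {
        "title_page": (
            f"EXPOSURE CONTROL PLAN - RESPIRABLE CRYSTALLINE SILICA\n"
            f"Company: {doc.profile.company_name}\n"
            f"Contact: {doc.profile.contact}\n"
            f"Address: {doc.profile.address}"
        ),
        "job_details": (
            f"Job address: {doc.job.address}\n"
            f"Supervisor: {doc.job.supervisor}\n"
            f"Dates: {doc.job.start_date} to {doc.job.end_date}"
        ),
        "task_description": (
            f"Common silica process: {s.csp_id}\n"
            f"Sector: {s.sector} | Project type: {s.project_type} | "
            f"Environment: {s.environment} | Region: {s.region}\n"
            f"Task duration: {s.task_duration_hours:g} h"
        ),
        "risk_assessment": "\n".join(risk_lines),
        "engineering_controls": "\n".join(doc.engineering_controls) or "None selected",
        "administrative_controls": (
            "\n".join(doc.administrative_controls)
            or "None specified"
        ) + "\n(Administrative controls are listed for completeness; they do "
            "not alter the quantitative exposure estimates.)",
        "ppe": "\n".join(doc.ppe),
        "vicinity_statement": VICINITY_BOILERPLATE,
        "version_stamp": (
            f"ECP id: {doc.ecp_id or '(unarchived)'} (version {doc.version})\n"
            f"Exposure database version: {doc.db_version}\n"
            f"Generated: {doc.created}"
        ),
    }


_SECTION_TITLES = {
    "title_page": "Title Page",
    "job_details": "Job Details",
    "task_description": "Task Description",
    "risk_assessment": "Risk Assessment",
    "engineering_controls": "Engineering Controls",
    "administrative_controls": "Administrative Controls",
    "ppe": "Personal Protective Equipment",
    "vicinity_statement": "Workers in the Vicinity",
    "version_stamp": "Document Version",
}


def render(doc: ECPDocument, fmt: str = "text") -> str:
    """Deterministic structured rendering of an ECP ("text" or "html").

    Section order and content are stable across runs for a fixed ``created``
    timestamp. A missing required section raises :class:`RenderError`.
    """
    sections = _sections(doc)
    missing = [s for s in REQUIRED_SECTIONS if not sections.get(s, "").strip()]
    if missing:
        raise RenderError(f"document is missing required section(s): {missing}")
    if fmt == "text":
        parts = []
        for key in REQUIRED_SECTIONS:
            title = _SECTION_TITLES[key]
            parts.append(f"{'=' * 60}\n{title}\n{'-' * 60}\n{sections[key]}")
        return "\n\n".join(parts) + "\n"
    if fmt == "html":
        body = "\n".join(
            f'<section id="{key}">\n<h2>{_SECTION_TITLES[key]}</h2>\n'
            f"<pre>{_escape(sections[key])}</pre>\n</section>"
            for key in REQUIRED_SECTIONS
        )
        return (
            "<!DOCTYPE html>\n<html>\n<head><meta charset=\"utf-8\">"
            f"<title>Exposure Control Plan - {_escape(doc.profile.company_name)}"
            "</title></head>\n<body>\n" + body + "\n</body>\n</html>\n"
        )
    raise InvalidInputError(f"unknown render format {fmt!r}; use 'text' or 'html'")


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )
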