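"""De-aggregation of published summary statistics into pseudo-observations.

Much of the usable RCS exposure data in the literature is reported only as
aggregates (n with a GM/GSD or AM/SD). To let such data enter the modeling
database alongside discrete measurements, each summary record is expanded
into n simulated observations whose empirical geometric mean and geometric
standard deviation reproduce the published values exactly.

Procedure: draw n standard-normal deviates, standardize them to sample mean
0 and sample SD 1 (ddof=1), then map ``x = exp(ln GM + ln GSD * z)``. The
affine rescaling in log space makes the moment match exact rather than
approximate, so downstream regression fits are reproducible and do not
depend on Monte Carlo luck. AM/SD inputs are first converted to GM/GSD
under a lognormal assumption (``ln² GSD = ln(1 + SD²/AM²)``), the standard
occupational-hygiene convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .errors import InvalidInputError
from .measurements import ExposureMeasurement, Source


class CenterKind(str, Enum):
    GM = "GM"
    AM = "AM"


class DispersionKind(str, Enum):
    GSD = "GSD"
    SD = "SD"


@dataclass(frozen=True)
class SummaryStatRecord:
    """A published aggregate awaiting de-aggregation."""

    n: int
    center: float  # mg/m³
    center_kind: CenterKind
    dispersion: float  # GSD (unitless, ≥1) or SD (mg/m³, ≥0)
    dispersion_kind: DispersionKind
    # covariates carried onto every generated record
    csp_id: str = ""
    sector: str = ""
    project_type: str = ""
    environment: str = ""
    region: str = ""
    duration: float = 480.0  # minutes
    controls: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "center_kind", CenterKind(self.center_kind))
        object.__setattr__(
            self, "dispersion_kind", DispersionKind(self.dispersion_kind)
        )
        object.__setattr__(self, "controls", frozenset(self.controls))


def am_sd_to_gm_gsd(am: float, sd: float) -> tuple[float, float]:
    """Convert arithmetic mean/SD to GM/GSD assuming lognormality.

    Uses ``ln² GSD = ln(1 + CV²)`` with CV = SD/AM, then
    ``GM = AM / exp(½ ln² GSD)``.
    """
    if am <= 0:
        raise InvalidInputError(f"arithmetic mean must be positive, got {am}")
    if sd < 0:
        raise InvalidInputError(f"SD must be nonnegative, got {sd}")
    log_var = math.log1p((sd / am) ** 2)
    gm = am / math.exp(log_var / 2.0)
    gsd = math.exp(math.sqrt(log_var))
    return gm, gsd


def gm_gsd_to_am_sd(gm: float, gsd: float) -> tuple[float, float]:
    """Inverse of :func:`am_sd_to_gm_gsd`: ``AM = GM·exp(½ ln² GSD)``."""
    if gm <= 0:
        raise InvalidInputError(f"GM must be positive, got {gm}")
    if gsd < 1:
        raise InvalidInputError(f"GSD must be ≥ 1, got {gsd}")
    log_var = math.log(gsd) ** 2
    am = gm * math.exp(log_var / 2.0)
    sd = am * math.sqrt(math.expm1(log_var))
    return am, sd


def _target_gm_gsd(record: SummaryStatRecord) -> tuple[float, float]:
    if record.center <= 0:
        raise InvalidInputError(f"center must be positive, got {record.center}")
    if record.center_kind == CenterKind.GM:
        gm = record.center
        if record.dispersion_kind == DispersionKind.GSD:
            gsd = record.dispersion
        else:
            # GM with arithmetic SD: recover the implied AM, then the GSD
            am, sd = _am_from_gm_sd(gm, record.dispersion)
            _, gsd = am_sd_to_gm_gsd(am, sd)
        if gsd < 1:
            raise InvalidInputError(f"GSD must be ≥ 1, got {gsd}")
        return gm, gsd
    # AM center
    if record.dispersion_kind == DispersionKind.SD:
        return am_sd_to_gm_gsd(record.center, record.dispersion)
    # AM with GSD: invert AM = GM·exp(½ ln² GSD)
    gsd = record.dispersion
    if gsd < 1:
        raise InvalidInputError(f"GSD must be ≥ 1, got {gsd}")
    gm = record.center / math.exp(math.log(gsd) ** 2 / 2.0)
    return gm, gsd


def _am_from_gm_sd(gm: float, sd: float) -> tuple[float, float]:
    """Solve for (AM, SD) consistent with a GM and arithmetic SD.

    With σ² = ln(1 + SD²/AM²) and AM = GM·exp(σ²/2), AM satisfies
    AM² = GM²·(1 + SD²/AM²) i.e. AM⁴ − GM²·AM² − GM²·SD² = 0.
    """
    g2, s2 = gm * gm, sd * sd
    am2 = (g2 + math.sqrt(g2 * g2 + 4.0 * g2 * s2)) / 2.0
    return math.sqrt(am2), sd


def deaggregate_summary(
    record: SummaryStatRecord,
    seed: int,
    source: Source = Source.DEAGGREGATED,
) -> list[ExposureMeasurement]:
    """Expand a summary record into n pseudo-observations.

    The generated values are lognormal draws rescaled in log space so their
    empirical GM and GSD (sample SD of logs, ddof=1) equal the targets to
    machine precision. Deterministic given ``seed``. Edge cases: n=1 returns
    the GM itself; GSD=1 returns n identical values equal to the GM.
    """
    if record.n < 1:
        raise InvalidInputError(f"n must be ≥ 1, got {record.n}")
    gm, gsd = _target_gm_gsd(record)
    n = int(record.n)
    log_gm, log_gsd = math.log(gm), math.log(gsd)

    if n == 1 or log_gsd == 0.0:
        z = np.zeros(n)
    else:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std(ddof=1)
    values = np.exp(log_gm + log_gsd * z)

    return [
        ExposureMeasurement(
            concentration=float(v),
            duration=record.duration,
            csp_id=record.csp_id,
            sector=record.sector,
            project_type=record.project_type,
            environment=record.environment,
            region=record.region,
            controls=record.controls,
            source=source,
        )
        for v in values
    ]


def empirical_gm_gsd(values: np.ndarray | list[float]) -> tuple[float, float]:
    """Sample GM and GSD (log scale, ddof=1; GSD of a single value is 1)."""
    logs = np.log(np.asarray(values, dtype=float))
    gm = float(np.exp(logs.mean()))
    gsd = 1.0 if logs.size < 2 else float(np.exp(logs.std(ddof=1)))
    return gm, gsd
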