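"""Run configuration: paths, jurisdiction parameters, Monte Carlo settings.

Jurisdiction-specific parameters (the OEL, the respirator APF ladder) and
the adjustment factors live here so they can be modified without touching
code; defaults are the British Columbia values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import InvalidInputError
from .predict import (
    DEFAULT_APF_TABLE,
    DEFAULT_N_DRAWS,
    DEFAULT_OEL,
    SEPARATION_REDUCTION,
    SHORT_DURATION_DISCOUNT,
    SHORT_DURATION_THRESHOLD_HOURS,
)


@dataclass
class RunConfig:
    database_csv: Optional[str] = None
    model_json: Optional[str] = None
    archive_dir: str = "ecp_archive"
    oel: float = DEFAULT_OEL  # mg/m³
    apf_table: tuple[tuple[str, float], ...] = DEFAULT_APF_TABLE
    n_draws: int = DEFAULT_N_DRAWS
    seed: int = 0
    include_residual: bool = False
    separation_reduction: float = SEPARATION_REDUCTION
    short_duration_discount: float = SHORT_DURATION_DISCOUNT
    short_duration_threshold_hours: float = SHORT_DURATION_THRESHOLD_HOURS

    def __post_init__(self):
        if self.oel <= 0:
            raise InvalidInputError(f"OEL must be positive, got {self.oel}")
        for name in ("separation_reduction", "short_duration_discount"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidInputError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "apf_table" in raw:
            raw["apf_table"] = tuple(
                (str(label), float(apf)) for label, apf in raw["apf_table"]
            )
        return cls(**raw)

    def to_yaml(self, path: Path) -> None:
        doc = dict(self.__dict__)
        doc["apf_table"] = [[label, apf] for label, apf in self.apf_table]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
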