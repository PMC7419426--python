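"""Common Silica Process (CSP) registry.

A CSP is a task + material + tool triple describing an RCS-generating work
process (e.g. cutting concrete with a walk-behind saw). The registry ships
as an editable JSON resource and can be extended as users identify new
processes; nothing in the package pins its length.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .errors import InvalidInputError, NotFoundError
from .measurements import CSPDescriptor


class CSPRegistry:
    """Lookup table of CSP descriptors keyed by ``csp_id``.

    The (material, task, tool) triple must be unique within the registry.
    """

    def __init__(self, descriptors: Iterable[CSPDescriptor] = ()):
        self._by_id: dict[str, CSPDescriptor] = {}
        self._by_triple: dict[tuple[str, str, str], str] = {}
        for d in descriptors:
            self.add(d)

    def add(self, descriptor: CSPDescriptor) -> None:
        triple = (descriptor.material, descriptor.task, descriptor.tool)
        if descriptor.csp_id in self._by_id:
            raise InvalidInputError(f"duplicate csp_id {descriptor.csp_id!r}")
        if triple in self._by_triple:
            raise InvalidInputError(
                f"duplicate (material, task, tool) triple {triple!r} "
                f"(already registered as {self._by_triple[triple]!r})"
            )
        self._by_id[descriptor.csp_id] = descriptor
        self._by_triple[triple] = descriptor.csp_id

    def get(self, csp_id: str) -> CSPDescriptor:
        try:
            return self._by_id[csp_id]
        except KeyError:
            raise NotFoundError(f"unknown csp_id {csp_id!r}") from None

    def __contains__(self, csp_id: str) -> bool:
        return csp_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    @classmethod
    def from_json(cls, path: Optional[Path] = None) -> "CSPRegistry":
        """Load a registry from JSON; defaults to the bundled resource."""
        if path is None:
            text = (
                resources.files("silicarisk").joinpath("data/csp_registry.json")
            ).read_text(encoding="utf-8")
        else:
            text = Path(path).read_text(encoding="utf-8")
        doc = json.loads(text)
        return cls(
            CSPDescriptor(
                csp_id=row["csp_id"],
                material=row["material"],
                task=row["task"],
                tool=row["tool"],
                label=row.get("label", ""),
            )
            for row in doc["csps"]
        )

    def to_json(self, path: Path) -> None:
        doc = {
            "schema_version": "1",
            "csps": [
                {
                    "csp_id": d.csp_id,
                    "material": d.material,
                    "task": d.task,
                    "tool": d.tool,
                    "label": d.label,
                }
                for d in self
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")


def default_registry() -> CSPRegistry:
    """The bundled BC construction-sector CSP registry."""
    return CSPRegistry.from_json()
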