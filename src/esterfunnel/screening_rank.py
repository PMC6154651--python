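"""Ingestion and ranking of externally produced docking scores.

Docking itself is delegated to an external engine (the original screen used
AutoDock against the FXR ligand-binding domain, PDB 1OSH, with fexaramine as
the positive control); this module defines the adapter contract around it.
Ligand structures go out, a CSV score table comes back
(``ligand_id,pki,is_control``), and the :class:`DockingConfig` used is
recorded verbatim for provenance — it is validated, never interpreted
numerically. pKi is treated as an opaque monotone affinity score; ranking is
by descending pKi with lexicographic id tie-breaks, and a control check warns
when any library compound outranks a positive control (the validation logic
of screening against a co-crystallized reference ligand).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from math import isfinite
from typing import Sequence

__all__ = [
    "DockingConfig",
    "ScoreRecord",
    "ControlReport",
    "ScoreTableError",
    "load_scores",
    "rank_ligands",
    "control_check",
]


class ScoreTableError(ValueError):
    """Raised for malformed or inconsistent score tables."""


@dataclass(frozen=True)
class DockingConfig:
    """Provenance record of the external docking run (recorded verbatim)."""

    receptor: str = "1OSH"
    grid_points: tuple[int, int, int] = (60, 60, 60)
    runs_per_ligand: int = 10
    engine: str = "autodock-4.2"

    def to_manifest(self) -> dict:
        return {
            "receptor": self.receptor,
            "grid_points": list(self.grid_points),
            "runs_per_ligand": self.runs_per_ligand,
            "engine": self.engine,
        }


@dataclass(frozen=True)
class ScoreRecord:
    ligand_id: str
    pki: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if not isfinite(self.pki):
            raise ScoreTableError(f"non-finite pKi for {self.ligand_id!r}")


@dataclass(frozen=True)
class ControlReport:
    status: str  # "pass" | "warn"
    messages: tuple[str, ...] = field(default=())


def load_scores(table: str) -> list[ScoreRecord]:
    """Parse a CSV payload with header ``ligand_id,pki,is_control``."""
    reader = csv.DictReader(io.StringIO(table))
    required = {"ligand_id", "pki", "is_control"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ScoreTableError(
            f"header must contain {sorted(required)}, got {reader.fieldnames}"
        )
    records: list[ScoreRecord] = []
    seen: dict[str, int] = {}
    for row_number, row in enumerate(reader, start=2):
        ligand_id = row["ligand_id"].strip()
        try:
            pki = float(row["pki"])
        except ValueError:
            raise ScoreTableError(
                f"row {row_number}: non-numeric pKi {row['pki']!r}"
            ) from None
        is_control = row["is_control"].strip().lower() in ("1", "true", "yes")
        seen.setdefault(ligand_id, 0)
        seen[ligand_id] += 1
        records.append(ScoreRecord(ligand_id, pki, is_control))
    duplicates = sorted(lig for lig, count in seen.items() if count > 1)
    if duplicates:
        raise ScoreTableError(f"duplicate ligand ids: {duplicates}")
    return records


def rank_ligands(
    records: Sequence[ScoreRecord], top_n: int | None = None
) -> list[ScoreRecord]:
    """Descending pKi, ties broken by id; truncation happens after ranking.

    Controls are ranked alongside library compounds (flagged, not excluded),
    mirroring a screen where the reference ligand competes in the same list.
    """
    if not records:
        raise ScoreTableError("no score records to rank")
    if top_n is not None and top_n <= 0:
        raise ValueError("top_n must be positive")
    ranked = sorted(records, key=lambda r: (-r.pki, r.ligand_id))
    return ranked if top_n is None else ranked[:top_n]


def control_check(records: Sequence[ScoreRecord]) -> ControlReport:
    """Pass iff every positive control outranks every library compound."""
    controls = [r for r in records if r.is_control]
    if not controls:
        return ControlReport("warn", ("no control present",))
    worst_control = min(r.pki for r in controls)
    beaten_by = sorted(
        r.ligand_id
        for r in records
        if not r.is_control and r.pki > worst_control
    )
    if beaten_by:
        return ControlReport(
            "warn",
            (f"library compounds outrank a control: {', '.join(beaten_by)}",),
        )
    return ControlReport("pass", ())


def ranked_to_csv(ranked: Sequence[ScoreRecord]) -> str:
    lines = ["rank,ligand_id,pki,is_control"]
    for rank, r in enumerate(ranked, start=1):
        lines.append(f"{rank},{r.ligand_id},{r.pki:.2f},{int(r.is_control)}")
    return "\n".join(lines) + "\n"
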