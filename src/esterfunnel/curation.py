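"""Two-pass curation funnel for a carboxylic-acid building-block library.

Stage 0 validates that each record is a single-fragment organic molecule
bearing at least one free carboxylic-acid group (multi-fragment records are
treated as salts and dropped whole). Stage 1 applies drug-likeness thresholds
over the six descriptors — the customized rule-of-5 for small acid building
blocks (MW ≤ 200, HBD ≤ 4, HBA ≤ 8, ≤ 7 rotatable bonds, ≤ 2 rings, ≤ 2
aromatic rings). Stage 2 removes records matching any structural alert in an
editable SMARTS catalogue: reactive/unstable groups (epoxide, aziridine,
disulfide, nitrogen oxides, azo, β-lactam, amino-/thionitrile) and
non-druglike chemotypes (long-chain fatty acids, gem-dicarboxylic acids,
quaternary ammonium, B/Si/Se-containing records).

Rejections are data, not exceptions: every stage returns survivors plus a
:class:`FunnelStage` with per-rule tallies. A record tripping several rules is
counted once in the survivor arithmetic but tallied under every rule it trips,
so tallies are diagnostic and may sum past ``n_in − n_out``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from rdkit import Chem

from .chem_core import Molecule, compute_properties

__all__ = [
    "FilterCriteria",
    "StructuralAlert",
    "FunnelStage",
    "FunnelReport",
    "Rejection",
    "load_alert_catalogue",
    "strip_and_validate_acid",
    "validate_library",
    "apply_druglike_filter",
    "apply_alerts",
]

_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")


@dataclass(frozen=True)
class FilterCriteria:
    """Upper bounds for the six drug-likeness descriptors.

    Defaults are the customized acid-building-block thresholds: the MW cap is
    200 u (not the classical 500) because the esters inherit the 456 u
    triterpene scaffold on top of each acid.
    """

    mw_max: float = 200.0
    hbd_max: int = 4
    hba_max: int = 8
    rotatable_max: int = 7
    ring_max: int = 2
    aromatic_ring_max: int = 2

    def __post_init__(self) -> None:
        for name in (
            "mw_max",
            "hbd_max",
            "hba_max",
            "rotatable_max",
            "ring_max",
            "aromatic_ring_max",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class StructuralAlert:
    """A named substructure (or element-scan) exclusion rule."""

    name: str
    category: str  # "reactive" | "non_druglike"
    pattern: str
    _query: object = field(default=None, repr=False, compare=False)
    _elements: frozenset = field(default=frozenset(), repr=False, compare=False)

    @staticmethod
    def from_pattern(name: str, category: str, pattern: str) -> "StructuralAlert":
        if pattern.startswith("element:"):
            elements = frozenset(pattern[len("element:"):].split(","))
            return StructuralAlert(name, category, pattern, None, elements)
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            raise ValueError(f"alert {name!r}: SMARTS does not compile: {pattern!r}")
        return StructuralAlert(name, category, pattern, query, frozenset())

    def matches(self, m: Molecule) -> bool:
        if self._elements:
            return any(a.GetSymbol() in self._elements for a in m.rdmol.GetAtoms())
        return m.rdmol.HasSubstructMatch(self._query)


def load_alert_catalogue(path: str | None = None) -> tuple[StructuralAlert, ...]:
    """Load the shipped (or a user-edited) alert catalogue TSV."""
    if path is None:
        text = (
            resources.files("esterfunnel.data").joinpath("alerts.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    alerts: list[StructuralAlert] = []
    seen: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, category, pattern = line.split("\t")
        if name in seen:
            raise ValueError(f"duplicate alert name {name!r}")
        seen.add(name)
        alerts.append(StructuralAlert.from_pattern(name, category, pattern))
    return tuple(alerts)


@dataclass(frozen=True)
class Rejection:
    molecule_id: str
    reasons: tuple[str, ...]


@dataclass
class FunnelStage:
    """Input/survivor counts and per-rule rejection tallies for one stage."""

    name: str
    n_in: int
    n_out: int
    rejections: Counter

    def __post_init__(self) -> None:
        assert self.n_out <= self.n_in


@dataclass
class FunnelReport:
    stages: list[FunnelStage] = field(default_factory=list)

    def add(self, stage: FunnelStage) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_out:
            raise ValueError(
                f"stage {stage.name!r} input {stage.n_in} != previous survivors "
                f"{self.stages[-1].n_out}"
            )
        self.stages.append(stage)

    def to_tsv(self) -> str:
        lines = ["stage\tn_in\tn_out\trule_tallies"]
        for s in self.stages:
            tallies = ";".join(f"{k}={v}" for k, v in sorted(s.rejections.items()))
            lines.append(f"{s.name}\t{s.n_in}\t{s.n_out}\t{tallies}")
        return "\n".join(lines) + "\n"


def strip_and_validate_acid(m: Molecule) -> Molecule | Rejection:
    """Reject salts (multi-fragment records) and non-carboxylic-acids.

    Salts are rejected whole rather than desalted: a counter-ion record in the
    source library is a formulation of the acid, not a distinct building
    block, and keeping the parent would double-count it.
    """
    if m.n_fragments > 1:
        return Rejection(m.id, ("salt",))
    if not m.rdmol.HasSubstructMatch(_CARBOXYLIC_ACID):
        return Rejection(m.id, ("not_carboxylic_acid",))
    return m


def validate_library(
    molecules: Sequence[Molecule],
) -> tuple[list[Molecule], list[Rejection], FunnelStage]:
    survivors: list[Molecule] = []
    rejects: list[Rejection] = []
    tallies: Counter = Counter()
    for m in molecules:
        out = strip_and_validate_acid(m)
        if isinstance(out, Rejection):
            rejects.append(out)
            tallies.update(out.reasons)
        else:
            survivors.append(out)
    return survivors, rejects, FunnelStage(
        "validate_acid", len(molecules), len(survivors), tallies
    )


def _violations(m: Molecule, c: FilterCriteria) -> tuple[str, ...]:
    p = compute_properties(m)
    v = []
    if p.mw_average > c.mw_max:
        v.append("mw_max")
    if p.hbd > c.hbd_max:
        v.append("hbd_max")
    if p.hba > c.hba_max:
        v.append("hba_max")
    if p.rotatable_bonds > c.rotatable_max:
        v.append("rotatable_max")
    if p.ring_count > c.ring_max:
        v.append("ring_max")
    if p.aromatic_ring_count > c.aromatic_ring_max:
        v.append("aromatic_ring_max")
    return tuple(v)


def apply_druglike_filter(
    molecules: Sequence[Molecule], criteria: FilterCriteria | None = None
) -> tuple[list[Molecule], list[Rejection], FunnelStage]:
    """Keep molecules whose six descriptors are all within the thresholds."""
    criteria = criteria or FilterCriteria()
    survivors: list[Molecule] = []
    rejects: list[Rejection] = []
    tallies: Counter = Counter()
    for m in molecules:
        v = _violations(m, criteria)
        if v:
            rejects.append(Rejection(m.id, v))
            tallies.update(v)
        else:
            survivors.append(m)
    return survivors, rejects, FunnelStage(
        "druglike_filter", len(molecules), len(survivors), tallies
    )


def apply_alerts(
    molecules: Sequence[Molecule],
    alerts: Iterable[StructuralAlert] | None = None,
) -> tuple[list[Molecule], list[Rejection], FunnelStage]:
    """Keep molecules matching no structural alert; record matched names."""
    alerts = tuple(alerts) if alerts is not None else load_alert_catalogue()
    survivors: list[Molecule] = []
    rejects: list[Rejection] = []
    tallies: Counter = Counter()
    for m in molecules:
        hits = tuple(a.name for a in alerts if a.matches(m))
        if hits:
            rejects.append(Rejection(m.id, hits))
            tallies.update(hits)
        else:
            survivors.append(m)
    return survivors, rejects, FunnelStage(
        "structural_alerts", len(molecules), len(survivors), tallies
    )
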