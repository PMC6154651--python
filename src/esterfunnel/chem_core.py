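"""Molecular graph model, structure I/O, and descriptor/mass calculators.

The in-memory representation wraps an RDKit molecule (aromaticity perception,
ring information and SMARTS matching are delegated to it) behind an immutable
:class:`Molecule` facade carrying a library identifier and the source record.
Descriptors and masses are computed here, by explicit graph walks and a pinned
isotope/atomic-weight table, so that every number the pipeline reports is
bit-stable and its convention documented:

* HBD — count of hydrogens on N or O (Lipinski donor convention).
* HBA — count of N plus O atoms (Lipinski acceptor convention).
* Rotatable bonds — non-ring single bonds between two non-terminal heavy
  atoms, excluding amide C–N.
* Rings — size of the smallest set of smallest rings (SSSR); aromatic rings
  are SSSR rings whose atoms are all aromatic.

Stereochemistry is parsed but ignored throughout: the library-design pipeline
is strictly 2D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rejects are reported, not logged to stderr

__all__ = [
    "Molecule",
    "Formula",
    "PropertyProfile",
    "ParseError",
    "ParseResult",
    "RejectedRecord",
    "parse_structures",
    "parse_smiles",
    "molecular_formula",
    "monoisotopic_mass",
    "average_mass",
    "compute_properties",
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
]


def _load_mass_table() -> dict:
    with resources.files("esterfunnel.data").joinpath("atomic_masses.json").open() as fh:
        return json.load(fh)


ATOMIC_MASSES = _load_mass_table()
ELECTRON_MASS: float = ATOMIC_MASSES["electron_mass"]
PROTON_MASS: float = ATOMIC_MASSES["proton_mass"]

# Hill order: C first, H second, then all other elements alphabetically;
# if no carbon is present, everything is alphabetical.
def _hill_sort(symbols: Sequence[str]) -> list[str]:
    symbols = sorted(set(symbols))
    if "C" in symbols:
        head = [s for s in ("C", "H") if s in symbols]
        return head + [s for s in symbols if s not in ("C", "H")]
    return list(symbols)


class ParseError(ValueError):
    """Raised for unusable payloads (empty input, unknown format tag)."""


@dataclass(frozen=True)
class RejectedRecord:
    """A record that could not be parsed, with its location in the input."""

    line_number: int
    text: str
    reason: str


@dataclass(frozen=True)
class Formula:
    """Element→count map with net formal charge, rendered in Hill order."""

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {el: int(n) for el, n in self.counts.items() if n}
        )
        if any(n < 0 for n in self.counts.values()):
            raise ValueError(f"negative element count in {self.counts!r}")

    def __str__(self) -> str:
        parts = []
        for el in _hill_sort(list(self.counts)):
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        body = "".join(parts)
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            mag = abs(self.charge)
            body += sign if mag == 1 else f"{sign}{mag}"
        return body

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts, self.charge + other.charge)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) - n
        return Formula(counts, self.charge - other.charge)


WATER = Formula({"H": 2, "O": 1})


@dataclass(frozen=True)
class Molecule:
    """Immutable molecular graph with a library identifier.

    ``atoms`` is an ordered tuple of ``(element, formal_charge, is_aromatic,
    n_hydrogens)``; ``bonds`` a tuple of ``(i, j, order)`` with order in
    ``{1, 2, 3, "ar"}``. Both are derived views over the wrapped RDKit mol.
    """

    id: str
    rdmol: Chem.Mol = field(repr=False, compare=False)
    source_text: str = ""

    @property
    def atoms(self) -> tuple[tuple[str, int, bool, int], ...]:
        return tuple(
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic(), a.GetTotalNumHs())
            for a in self.rdmol.GetAtoms()
        )

    @property
    def bonds(self) -> tuple[tuple[int, int, object], ...]:
        order_map = {
            Chem.BondType.SINGLE: 1,
            Chem.BondType.DOUBLE: 2,
            Chem.BondType.TRIPLE: 3,
            Chem.BondType.AROMATIC: "ar",
        }
        out = []
        for b in self.rdmol.GetBonds():
            out.append(
                (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_map[b.GetBondType()])
            )
        return tuple(out)

    @property
    def n_heavy_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def n_fragments(self) -> int:
        return len(Chem.GetMolFrags(self.rdmol))

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)


@dataclass(frozen=True)
class ParseResult:
    molecules: tuple[Molecule, ...]
    rejects: tuple[RejectedRecord, ...]


@dataclass(frozen=True)
class PropertyProfile:
    """The six filter descriptors plus masses and formula for one molecule."""

    mw_average: float
    mw_monoisotopic: float
    hbd: int
    hba: int
    rotatable_bonds: int
    ring_count: int
    aromatic_ring_count: int
    formula: Formula


def _mol_from_smiles(smiles: str) -> Chem.Mol | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        # a uniform perception pass; records that cannot kekulize are rejects
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def parse_smiles(smiles: str, mol_id: str = "") -> Molecule:
    """Parse a single SMILES string, raising :class:`ParseError` on failure."""
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return Molecule(id=mol_id or smiles, rdmol=mol, source_text=smiles)


def parse_structures(text: str, fmt: str = "smiles") -> ParseResult:
    """Parse a SMILES or SDF payload into molecules plus a rejects report.

    SMILES payloads are one record per line, an optional identifier after
    whitespace; blank lines and ``#`` comments are skipped. SDF payloads are
    V2000 multi-record files; the record's title line (or its ordinal) is the
    identifier and the "line number" of a reject is the record ordinal.
    Unparseable records are collected, never silently dropped.
    """
    if not text or not text.strip():
        raise ParseError("empty structure payload")
    if fmt not in ("smiles", "sdf"):
        raise ParseError(f"unknown format tag: {fmt!r}")

    molecules: list[Molecule] = []
    rejects: list[RejectedRecord] = []

    if fmt == "smiles":
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"record_{lineno}"
            mol = _mol_from_smiles(smiles)
            if mol is None:
                rejects.append(RejectedRecord(lineno, raw, "unparseable_smiles"))
            else:
                molecules.append(Molecule(id=mol_id, rdmol=mol, source_text=raw))
    else:
        supplier = Chem.SDMolSupplier()
        supplier.SetData(text, sanitize=True)
        for ordinal, mol in enumerate(supplier, start=1):
            if mol is None:
                rejects.append(
                    RejectedRecord(ordinal, f"sdf record {ordinal}", "unparseable_sdf")
                )
                continue
            name = (mol.GetProp("_Name") if mol.HasProp("_Name") else "").strip()
            molecules.append(
                Molecule(
                    id=name or f"record_{ordinal}",
                    rdmol=mol,
                    source_text=f"sdf record {ordinal}",
                )
            )
    return ParseResult(tuple(molecules), tuple(rejects))


def molecular_formula(m: Molecule) -> Formula:
    """Element counts including implicit hydrogens, plus net formal charge."""
    counts: dict[str, int] = {}
    charge = 0
    n_h = 0
    for atom in m.rdmol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        n_h += atom.GetTotalNumHs()
        charge += atom.GetFormalCharge()
    if n_h:
        counts["H"] = counts.get("H", 0) + n_h
    return Formula(counts, charge)


def _mass(f: Formula, table: Mapping[str, float]) -> float:
    total = 0.0
    for el, n in f.counts.items():
        if el not in table:
            raise KeyError(f"no tabulated mass for element {el!r}")
        total += n * table[el]
    # an ion's mass differs from the neutral sum by the electron count
    total -= f.charge * ELECTRON_MASS
    return total


def monoisotopic_mass(f: Formula) -> float:
    """Exact mass: sum of most-abundant-isotope masses (charge-corrected)."""
    return _mass(f, ATOMIC_MASSES["monoisotopic"])


def average_mass(f: Formula) -> float:
    """Average molecular weight from standard atomic weights."""
    return _mass(f, ATOMIC_MASSES["average"])


def _is_amide_cn(bond: Chem.Bond) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for c_atom, n_atom in ((a, b), (b, a)):
        if c_atom.GetSymbol() == "C" and n_atom.GetSymbol() == "N":
            for nb in c_atom.GetBonds():
                other = nb.GetOtherAtom(c_atom)
                if (
                    other.GetSymbol() == "O"
                    and nb.GetBondType() == Chem.BondType.DOUBLE
                ):
                    return True
    return False


def _rotatable_bond_count(mol: Chem.Mol) -> int:
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() < 2 or b.GetDegree() < 2:  # terminal heavy atom
            continue
        if _is_amide_cn(bond):
            continue
        n += 1
    return n


def compute_properties(m: Molecule) -> PropertyProfile:
    """The six filter descriptors, masses and formula for one molecule."""
    mol = m.rdmol
    hbd = sum(
        a.GetTotalNumHs() for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O")
    )
    hba = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
    atom_rings = [tuple(r) for r in Chem.GetSSSR(mol)]  # plain SSSR basis
    aromatic_rings = sum(
        1
        for ring in atom_rings
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )
    f = molecular_formula(m)
    return PropertyProfile(
        mw_average=average_mass(f),
        mw_monoisotopic=monoisotopic_mass(f),
        hbd=hbd,
        hba=hba,
        rotatable_bonds=_rotatable_bond_count(mol),
        ring_count=len(atom_rings),
        aromatic_ring_count=aromatic_rings,
        formula=f,
    )


def write_smiles_tsv(molecules: Sequence[Molecule]) -> str:
    """Canonical SMILES + id, one record per line (the library's exchange format)."""
    return "".join(f"{m.to_smiles()}\t{m.id}\n" for m in molecules)


def iter_molecules(result: ParseResult) -> Iterator[Molecule]:
    return iter(result.molecules)
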