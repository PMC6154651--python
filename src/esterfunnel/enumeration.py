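"""Combinatorial 3-O-acylation of the triterpene scaffold.

Each curated mono-carboxylic acid is condensed onto the scaffold's declared
hydroxyl site (the 3β-OH of oleanolic acid in the shipped fixture): the
hydroxyl oxygen is bonded to the acid's carbonyl carbon and one water is
lost. Element-wise formula conservation —

    formula(ester) = formula(scaffold) + formula(acid) − H2O

— is asserted for every product, and electrospray adduct m/z values
([M−H]−, [M+H]+, [M+Na]+, singly charged) are predicted from the monoisotopic
mass. The scaffold fixture declares the esterification site by an atom-map
label rather than by automatic site perception, so the chemistry is exactly
one documented transform.

Acids with zero or more than one free COOH cannot be esterified unambiguously
and are routed to a rejects report; other nucleophilic groups on an acid are
deliberately ignored (side-reactivity is chemistry, not enumeration).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

from rdkit import Chem

from .chem_core import (
    ATOMIC_MASSES,
    ELECTRON_MASS,
    PROTON_MASS,
    WATER,
    Formula,
    Molecule,
    average_mass,
    molecular_formula,
    monoisotopic_mass,
)

__all__ = [
    "ScaffoldSite",
    "EsterProduct",
    "AdductSpec",
    "ADDUCTS",
    "EsterificationError",
    "load_default_scaffold",
    "esterify",
    "enumerate_library",
    "predict_adduct_mz",
]

_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")


class EsterificationError(ValueError):
    """Raised when an acid cannot be condensed onto the scaffold site."""


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ESI adduct: observed m/z = M + delta."""

    label: str
    delta: float
    charge_sign: int


ADDUCTS: Mapping[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
    "[M+H]+": AdductSpec("[M+H]+", +PROTON_MASS, +1),
    "[M+Na]+": AdductSpec(
        "[M+Na]+", ATOMIC_MASSES["monoisotopic"]["Na"] - ELECTRON_MASS, +1
    ),
}


@dataclass(frozen=True)
class ScaffoldSite:
    """A scaffold plus the atom index of its esterifiable hydroxyl oxygen."""

    scaffold: Molecule
    site: int

    def __post_init__(self) -> None:
        atom = self.scaffold.rdmol.GetAtomWithIdx(self.site)
        if atom.GetSymbol() != "O" or atom.GetTotalNumHs() != 1:
            raise ValueError("site atom must be a hydroxyl oxygen (one H)")
        heavy = [n for n in atom.GetNeighbors()]
        if len(heavy) != 1 or heavy[0].GetSymbol() != "C":
            raise ValueError("site oxygen must have a single bond to carbon")


@dataclass(frozen=True)
class EsterProduct:
    product: Molecule
    scaffold_id: str
    acid_id: str
    formula: Formula
    mw_average: float
    mw_monoisotopic: float
    adduct_mz: Mapping[str, float]


def load_default_scaffold() -> ScaffoldSite:
    """Load the oleanolic-acid fixture; atom map 1 marks the 3β-OH oxygen."""
    text = resources.files("esterfunnel.data").joinpath("oa_scaffold.smi").read_text()
    smiles, name = text.split()
    mol = Chem.MolFromSmiles(smiles)
    site = None
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum() == 1:
            site = atom.GetIdx()
        atom.SetAtomMapNum(0)
    if site is None:
        raise ValueError("scaffold fixture declares no esterification site")
    scaffold = Molecule(id=name, rdmol=mol, source_text=smiles)
    return ScaffoldSite(scaffold=scaffold, site=site)


def _eligible_cooh(acid: Molecule) -> list[tuple[int, int, int]]:
    return list(acid.rdmol.GetSubstructMatches(_CARBOXYLIC_ACID))


def esterify(site: ScaffoldSite, acid: Molecule) -> EsterProduct:
    """Condense one acid onto the scaffold hydroxyl, losing one water."""
    matches = _eligible_cooh(acid)
    if len(matches) != 1:
        raise EsterificationError(
            f"acid {acid.id!r}: {len(matches)} eligible carboxylic-acid groups "
            "(exactly one required)"
        )
    carbonyl_c, _carbonyl_o, hydroxyl_o = matches[0]

    combined = Chem.RWMol(Chem.CombineMols(site.scaffold.rdmol, acid.rdmol))
    offset = site.scaffold.rdmol.GetNumAtoms()
    site_o = combined.GetAtomWithIdx(site.site)
    site_o.SetNumExplicitHs(0)
    site_o.SetNoImplicit(False)
    combined.AddBond(site.site, offset + carbonyl_c, Chem.BondType.SINGLE)
    combined.RemoveAtom(offset + hydroxyl_o)  # leaves as part of the water
    product_mol = combined.GetMol()
    Chem.SanitizeMol(product_mol)
    if len(Chem.GetMolFrags(product_mol)) != 1:
        raise EsterificationError(f"acid {acid.id!r}: product not connected")

    product = Molecule(
        id=f"{site.scaffold.id}-3-O-{acid.id}",
        rdmol=product_mol,
        source_text=f"{site.scaffold.id} + {acid.id} - H2O",
    )
    f = molecular_formula(product)
    expected = (
        molecular_formula(site.scaffold) + molecular_formula(acid) - WATER
    )
    if f.counts != expected.counts or f.charge != expected.charge:
        raise EsterificationError(
            f"acid {acid.id!r}: formula conservation violated ({f} != {expected})"
        )
    mono = monoisotopic_mass(f)
    return EsterProduct(
        product=product,
        scaffold_id=site.scaffold.id,
        acid_id=acid.id,
        formula=f,
        mw_average=average_mass(f),
        mw_monoisotopic=mono,
        adduct_mz={label: mono + a.delta for label, a in ADDUCTS.items()},
    )


def enumerate_library(
    site: ScaffoldSite, acids: Sequence[Molecule]
) -> tuple[list[EsterProduct], list[tuple[str, str]]]:
    """One ester per acid, input order preserved; failures become rejects.

    Returns ``(products, rejects)`` where each reject is ``(acid_id, reason)``.
    """
    products: list[EsterProduct] = []
    rejects: list[tuple[str, str]] = []
    for acid in acids:
        try:
            products.append(esterify(site, acid))
        except EsterificationError as exc:
            rejects.append((acid.id, str(exc)))
    return products, rejects


def predict_adduct_mz(p: EsterProduct, adduct: str | AdductSpec) -> float:
    """m/z of a singly charged adduct of the product's monoisotopic mass."""
    if isinstance(adduct, str):
        if adduct not in ADDUCTS:
            raise KeyError(f"unknown adduct label {adduct!r}")
        adduct = ADDUCTS[adduct]
    return p.mw_monoisotopic + adduct.delta


def products_to_csv(products: Sequence[EsterProduct]) -> str:
    """CSV table: acid id, formula, masses, and per-adduct m/z."""
    labels = list(ADDUCTS)
    header = "acid_id,formula,mw_average,mw_monoisotopic," + ",".join(
        f"mz_{label}" for label in labels
    )
    lines = [header]
    for p in products:
        mzs = ",".join(f"{p.adduct_mz[label]:.4f}" for label in labels)
        lines.append(
            f"{p.acid_id},{p.formula},{p.mw_average:.4f},{p.mw_monoisotopic:.4f},{mzs}"
        )
    return "\n".join(lines) + "\n"
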