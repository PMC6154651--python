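"""Seeded generator of mono-carboxylic-acid libraries with ground-truth labels.

The proprietary commercial acid directory the original funnel drew on cannot
be redistributed, so every pipeline stage is exercised against libraries built
here instead. Records are assembled from a fragment grammar — a COOH head plus
catalogued ring/chain/heteroatom bodies — so that each record is chemically
valid and its descriptor labels are knowable at construction time. Labels
(formula, the six filter descriptors, structural-alert names, salt and
COOH-count flags) are annotated in the catalogue by hand from the package's
documented descriptor conventions, *not* computed by calling the descriptor
or curation code; the test suite recomputes every label through
``chem_core``/``curation`` and requires exact agreement, which keeps the two
routes honest against each other.

Spike-ins are exact, not stochastic: an alert rate of 0.1 at n = 100 yields
exactly 10 records carrying that alert and nothing else. All randomness
(which catalogue body realizes each slot, and the final shuffle) flows from
one root generator, so a fixed seed reproduces the library byte-for-byte.
The generator emulates the funnel's *structure* — controllable pass rates and
motif spikes — not the commercial database's actual chemical distribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem_core import ATOMIC_MASSES
from .curation import FilterCriteria, FunnelReport, FunnelStage
from collections import Counter

__all__ = [
    "LibrarySpec",
    "LabelledRecord",
    "generate_library",
    "funnel_truth",
    "records_to_smi",
    "records_to_labels_tsv",
    "ALERT_NAMES",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _formula_mw(formula: str) -> float:
    """Average MW from a Hill-order formula string (trailing +/- = charge)."""
    charge = 0
    if formula.endswith("+") or formula.endswith("-"):
        charge = 1 if formula.endswith("+") else -1
        formula = formula[:-1]
    mw = 0.0
    for el, num in _FORMULA_TOKEN.findall(formula):
        if el:
            mw += ATOMIC_MASSES["average"][el] * (int(num) if num else 1)
    return mw - charge * ATOMIC_MASSES["electron_mass"]


@dataclass(frozen=True)
class LabelledRecord:
    """One generated acid with its construction-time ground truth."""

    smiles: str
    id: str
    formula: str
    mw_average: float
    hbd: int
    hba: int
    rotatable_bonds: int
    ring_count: int
    aromatic_ring_count: int
    alerts: tuple[str, ...]
    is_salt: bool
    n_cooh: int

    def property_violations(self, c: FilterCriteria) -> tuple[str, ...]:
        v = []
        if self.mw_average > c.mw_max:
            v.append("mw_max")
        if self.hbd > c.hbd_max:
            v.append("hbd_max")
        if self.hba > c.hba_max:
            v.append("hba_max")
        if self.rotatable_bonds > c.rotatable_max:
            v.append("rotatable_max")
        if self.ring_count > c.ring_max:
            v.append("ring_max")
        if self.aromatic_ring_count > c.aromatic_ring_max:
            v.append("aromatic_ring_max")
        return tuple(v)

    def passes_properties(self, c: FilterCriteria) -> bool:
        return not self.property_violations(c)


# ---------------------------------------------------------------------------
# Fragment catalogue. Each entry: (smiles, name, formula, hbd, hba,
# rotatable, rings, aromatic_rings), descriptor values hand-counted under the
# package conventions (HBD = H on N/O; HBA = N+O; rotatable = acyclic single
# bonds between non-terminal heavy atoms, amide C–N excluded; rings = SSSR).
# ---------------------------------------------------------------------------

_Entry = tuple[str, str, str, int, int, int, int, int]

_PASS_FIXED: tuple[_Entry, ...] = (
    ("CC(=O)O", "acetic", "C2H4O2", 1, 2, 0, 0, 0),
    ("CC(C)C(=O)O", "isobutyric", "C4H8O2", 1, 2, 1, 0, 0),
    ("CC(C)(C)C(=O)O", "pivalic", "C5H10O2", 1, 2, 1, 0, 0),
    ("CC(C)CC(=O)O", "isovaleric", "C5H10O2", 1, 2, 2, 0, 0),
    ("CC(O)C(=O)O", "lactic", "C3H6O3", 2, 3, 1, 0, 0),
    ("CC(N)C(=O)O", "alanine", "C3H7NO2", 3, 3, 1, 0, 0),
    ("CN(C)CC(=O)O", "dimethylglycine", "C4H9NO2", 1, 3, 2, 0, 0),
    ("OC(=O)CCl", "chloroacetic", "C2H3ClO2", 1, 2, 1, 0, 0),
    ("OC(=O)CC(F)(F)F", "trifluoropropanoic", "C3H3F3O2", 1, 2, 2, 0, 0),
    ("OC(=O)c1ccccc1", "benzoic", "C7H6O2", 1, 2, 1, 1, 1),
    ("Cc1ccc(cc1)C(=O)O", "p_toluic", "C8H8O2", 1, 2, 1, 1, 1),
    ("OC(=O)c1ccc(F)cc1", "fluorobenzoic_4", "C7H5FO2", 1, 2, 1, 1, 1),
    ("OC(=O)c1ccc(Cl)cc1", "chlorobenzoic_4", "C7H5ClO2", 1, 2, 1, 1, 1),
    ("COc1ccc(cc1)C(=O)O", "anisic_4", "C8H8O3", 1, 3, 2, 1, 1),
    ("OC(=O)c1ccc(O)cc1", "hydroxybenzoic_4", "C7H6O3", 2, 3, 1, 1, 1),
    ("Nc1ccc(cc1)C(=O)O", "aminobenzoic_4", "C7H7NO2", 3, 3, 1, 1, 1),
    ("OC(=O)c1ccc(cc1)C#N", "cyanobenzoic_4", "C8H5NO2", 1, 3, 2, 1, 1),
    ("OC(=O)Cc1ccccc1", "phenylacetic", "C8H8O2", 1, 2, 2, 1, 1),
    ("OC(=O)CCc1ccccc1", "phenylpropanoic_3", "C9H10O2", 1, 2, 3, 1, 1),
    ("OC(=O)C=Cc1ccccc1", "cinnamic", "C9H8O2", 1, 2, 2, 1, 1),
    ("OC(=O)c1cccnc1", "nicotinic", "C6H5NO2", 1, 3, 1, 1, 1),
    ("OC(=O)c1ccncc1", "isonicotinic", "C6H5NO2", 1, 3, 1, 1, 1),
    ("OC(=O)c1ccco1", "furoic_2", "C5H4O3", 1, 3, 1, 1, 1),
    ("OC(=O)c1cccs1", "thiophene_2_carboxylic", "C5H4O2S", 1, 2, 1, 1, 1),
    ("OC(=O)c1cnccn1", "pyrazine_2_carboxylic", "C5H4N2O2", 1, 4, 1, 1, 1),
    ("Cn1cccc1C(=O)O", "methylpyrrole_2_carboxylic", "C6H7NO2", 1, 3, 1, 1, 1),
    ("OC(=O)C1CCCCC1", "cyclohexanecarboxylic", "C7H12O2", 1, 2, 1, 1, 0),
    ("OC(=O)C1CC1", "cyclopropanecarboxylic", "C4H6O2", 1, 2, 1, 1, 0),
    ("OC(=O)C1CCCO1", "thf_2_carboxylic", "C5H8O3", 1, 3, 1, 1, 0),
    ("OC(=O)C1CCNCC1", "isonipecotic", "C6H11NO2", 2, 3, 1, 1, 0),
    ("CN1CCC(CC1)C(=O)O", "methylpiperidine_4_carboxylic", "C7H13NO2", 1, 3, 1, 1, 0),
    ("OC(=O)c1ccc2ccccc2c1", "naphthoic_2", "C11H8O2", 1, 2, 1, 2, 2),
    ("OC(=O)Cc1c[nH]c2ccccc12", "indole_3_acetic", "C10H9NO2", 2, 3, 2, 2, 2),
    ("OC(=O)c1cc2ccccc2o1", "benzofuran_2_carboxylic", "C9H6O3", 1, 3, 1, 2, 2),
    ("OC(=O)c1ccc2ccccc2n1", "quinoline_2_carboxylic", "C10H7NO2", 1, 3, 1, 2, 2),
    ("CC(=O)CCC(=O)O", "levulinic", "C5H8O3", 1, 3, 3, 0, 0),
    ("CC(=O)C(=O)O", "pyruvic", "C3H4O3", 1, 3, 1, 0, 0),
    ("CC(=O)NCC(=O)O", "n_acetylglycine", "C4H7NO3", 2, 4, 2, 0, 0),
    ("CC=CC=CC(=O)O", "sorbic", "C6H8O2", 1, 2, 2, 0, 0),
    ("CSCCC(=O)O", "methylthiopropanoic_3", "C4H8O2S", 1, 2, 3, 0, 0),
    ("OC(=O)C1CC2CCC1C2", "norbornane_2_carboxylic", "C8H12O2", 1, 2, 1, 2, 0),
)

_FAIL_FIXED: tuple[_Entry, ...] = (
    ("OC(=O)c1ccc(Oc2ccccc2)cc1", "phenoxybenzoic_4", "C13H10O3", 1, 3, 3, 2, 2),
    ("CCCCCCc1ccc(cc1)C(=O)O", "hexylbenzoic_4", "C13H18O2", 1, 2, 6, 1, 1),
    ("OCC(O)C(O)C(O)C(=O)O", "tetrahydroxypentanoic", "C5H10O6", 5, 6, 4, 0, 0),
    ("Nc1ccc(cc1N)C(=O)O", "diaminobenzoic_3_4", "C7H8N2O2", 5, 4, 1, 1, 1),
    ("COCCOCCOCCOCCOCCOCCOCC(=O)O", "peg7_acid", "C15H30O9", 1, 9, 20, 0, 0),
    ("COCCCCCCCC(=O)O", "methoxyoctanoic_8", "C9H18O3", 1, 3, 8, 0, 0),
    ("OC(=O)C12CC3CC(C1)CC(C2)C3", "adamantane_1_carboxylic", "C11H16O2", 1, 2, 1, 3, 0),
    ("OC(=O)c1c2ccccc2cc2ccccc12", "anthracene_9_carboxylic", "C15H10O2", 1, 2, 1, 3, 3),
    ("CCCCCCCCCC(C)C(=O)O", "methylundecanoic_2", "C12H24O2", 1, 2, 9, 0, 0),
    ("NC(CCC(N)=O)C(=O)O", "glutamine", "C5H10N2O3", 5, 5, 4, 0, 0),
)

# One property-passing carrier per alert, bearing exactly that alert.
_ALERT_SPIKES: Mapping[str, _Entry] = {
    "epoxide": ("OC(=O)C1CO1", "glycidic", "C3H4O3", 1, 3, 1, 1, 0),
    "aziridine": ("OC(=O)C1CN1", "aziridine_2_carboxylic", "C3H5NO2", 2, 3, 1, 1, 0),
    "disulfide": ("OC(=O)CSSC", "methyldisulfanyl_acetic", "C3H6O2S2", 1, 2, 3, 0, 0),
    "nitrogen_oxide": (
        "OC(=O)c1ccc[n+]([O-])c1", "nicotinic_n_oxide", "C6H5NO3", 1, 4, 1, 1, 1,
    ),
    "azo": ("OC(=O)CN=NC", "methylazo_acetic", "C3H6N2O2", 1, 4, 2, 0, 0),
    "beta_lactam": (
        "OC(=O)C1CC(=O)N1", "oxoazetidine_2_carboxylic", "C4H5NO3", 2, 4, 1, 1, 0,
    ),
    "aminonitrile": ("OC(=O)C(N)C#N", "amino_cyanoacetic", "C3H4N2O2", 3, 4, 2, 0, 0),
    "thionitrile": ("OC(=O)CSC#N", "thiocyanatoacetic", "C3H3NO2S", 1, 3, 3, 0, 0),
    "long_chain_fatty_acid": ("CCCCCCCCC(=O)O", "nonanoic", "C9H18O2", 1, 2, 7, 0, 0),
    "gem_dicarboxylic": ("OC(=O)C(C)C(=O)O", "methylmalonic", "C4H6O4", 2, 4, 2, 0, 0),
    "quaternary_ammonium": (
        "C[N+](C)(C)CC(=O)O", "betaine_cation", "C5H12NO2+", 1, 3, 2, 0, 0,
    ),
    "boron_silicon_selenium": (
        "C[Si](C)(C)CCC(=O)O", "trimethylsilylpropanoic", "C6H14O2Si", 1, 2, 3, 0, 0,
    ),
}

ALERT_NAMES = tuple(_ALERT_SPIKES)

# Non-gem di-acids: pass curation, but cannot be esterified unambiguously.
_DIACID_SPIKES: tuple[_Entry, ...] = (
    ("OC(=O)CCC(=O)O", "succinic", "C4H6O4", 2, 4, 3, 0, 0),
    ("OC(=O)CCCC(=O)O", "glutaric", "C5H8O4", 2, 4, 4, 0, 0),
    ("OC(=O)CCCCC(=O)O", "adipic", "C6H10O4", 2, 4, 5, 0, 0),
)

# Counter-ion records, rejected whole at validation.
_SALT_SPIKES: tuple[tuple[str, str], ...] = (
    ("Cl.NCC(=O)O", "glycine_hydrochloride"),
    ("[Na+].[O-]C(=O)c1ccccc1", "sodium_benzoate"),
    ("Cl.CNCC(=O)O", "sarcosine_hydrochloride"),
    ("[Na+].CC(=O)[O-]", "sodium_acetate"),
)


def _chain_families() -> list[_Entry]:
    """Parametric homologue families with closed-form descriptor labels."""
    out: list[_Entry] = []
    for m in range(1, 6):  # CH3(CH2)mCOOH
        out.append(
            (
                "C" * (m + 1) + "C(=O)O",
                f"alkanoic_c{m + 2}",
                f"C{m + 2}H{2 * m + 4}O2",
                1, 2, m, 0, 0,
            )
        )
    for m in range(2, 6):  # HO(CH2)mCOOH
        out.append(
            (
                "OC" + "C" * (m - 1) + "C(=O)O",
                f"omega_hydroxy_c{m + 1}",
                f"C{m + 1}H{2 * m + 2}O3",
                2, 3, m, 0, 0,
            )
        )
    for m in range(2, 6):  # H2N(CH2)mCOOH
        out.append(
            (
                "NC" + "C" * (m - 1) + "C(=O)O",
                f"omega_amino_c{m + 1}",
                f"C{m + 1}H{2 * m + 3}NO2",
                3, 3, m, 0, 0,
            )
        )
    for m in range(1, 6):  # CH3O(CH2)mCOOH
        out.append(
            (
                "COC" + "C" * (m - 1) + "C(=O)O",
                f"omega_methoxy_c{m + 1}",
                f"C{m + 2}H{2 * m + 4}O3",
                1, 3, m + 1, 0, 0,
            )
        )
    for m in range(2, 6):  # Cl(CH2)mCOOH
        out.append(
            (
                "ClC" + "C" * (m - 1) + "C(=O)O",
                f"omega_chloro_c{m + 1}",
                f"C{m + 1}H{2 * m + 1}ClO2",
                1, 2, m, 0, 0,
            )
        )
    return out


_SUBSTITUENTS: Mapping[str, tuple[str, Mapping[str, int], int, int, int]] = {
    # smiles fragment, formula delta (replacing one ring H), Δhbd, Δhba, Δrot
    "H": ("", {}, 0, 0, 0),
    "F": ("F", {"F": 1, "H": -1}, 0, 0, 0),
    "Cl": ("Cl", {"Cl": 1, "H": -1}, 0, 0, 0),
    "Me": ("C", {"C": 1, "H": 2}, 0, 0, 0),
    "OMe": ("OC", {"C": 1, "H": 2, "O": 1}, 0, 1, 1),
    "OH": ("O", {"O": 1}, 1, 1, 0),
}


def _render_formula(counts: Mapping[str, int]) -> str:
    parts = []
    for el in ("C", "H"):
        if counts.get(el):
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
    for el in sorted(k for k in counts if k not in ("C", "H") and counts[k]):
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def _aryl_families() -> list[_Entry]:
    """3-X-4-Y-substituted benzoic and phenylacetic acids, labels composed."""
    cores = (
        ("OC(=O)c1ccc({Y})c({X})c1", "benzoic", {"C": 7, "H": 6, "O": 2}, 1, 2, 1),
        ("OC(=O)Cc1ccc({Y})c({X})c1", "phenylacetic", {"C": 8, "H": 8, "O": 2}, 1, 2, 2),
    )
    out: list[_Entry] = []
    for template, core_name, base_counts, hbd, hba, rot in cores:
        for xn, (xs, xd, xhbd, xhba, xrot) in _SUBSTITUENTS.items():
            for yn, (ys, yd, yhbd, yhba, yrot) in _SUBSTITUENTS.items():
                if xn == "H" and yn == "H":
                    continue  # the unsubstituted parents are fixed entries
                counts = dict(base_counts)
                for delta in (xd, yd):
                    for el, dn in delta.items():
                        counts[el] = counts.get(el, 0) + dn
                smiles = template.format(X=xs, Y=ys).replace("()", "")
                out.append(
                    (
                        smiles,
                        f"{core_name}_3{xn}_4{yn}".lower(),
                        _render_formula(counts),
                        hbd + xhbd + yhbd,
                        hba + xhba + yhba,
                        rot + xrot + yrot,
                        1,
                        1,
                    )
                )
    return out


def _passes_default(entry: _Entry) -> bool:
    """Rejection sampling within the grammar: keep default-criteria passers."""
    _smiles, _name, formula, hbd, hba, rot, rings, arom = entry
    c = FilterCriteria()
    return (
        _formula_mw(formula) <= c.mw_max
        and hbd <= c.hbd_max
        and hba <= c.hba_max
        and rot <= c.rotatable_max
        and rings <= c.ring_max
        and arom <= c.aromatic_ring_max
    )


_PASS_POOL: tuple[_Entry, ...] = tuple(
    entry
    for entry in _PASS_FIXED + tuple(_chain_families()) + tuple(_aryl_families())
    if _passes_default(entry)
)


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for one synthetic library: size, seed, pass share, spike rates.

    ``fraction_property_pass`` is the share of the whole library satisfying
    the drug-likeness criteria; spiked motifs (alerts, di-acids) are built
    property-passing, so they count toward that share. Realized spike counts
    are exact: ``round(rate × n)`` records each, never approximate. Default
    rates mirror the funnel this generator emulates: roughly 17.5% of records
    survive the property pass, of which roughly a quarter then fall to the
    alert/salt curation.
    """

    n: int
    seed: int
    fraction_property_pass: float = 0.175
    alert_rates: Mapping[str, float] = field(
        default_factory=lambda: {name: 0.003 for name in ALERT_NAMES}
    )
    salt_rate: float = 0.01
    diacid_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        rates = [self.fraction_property_pass, self.salt_rate, self.diacid_rate]
        rates += list(self.alert_rates.values())
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        unknown = set(self.alert_rates) - set(ALERT_NAMES)
        if unknown:
            raise ValueError(f"unknown alert names: {sorted(unknown)}")


def _record(entry: _Entry, idx: int, alerts=(), is_salt=False, n_cooh=1) -> LabelledRecord:
    smiles, name, formula, hbd, hba, rot, rings, arom = entry
    return LabelledRecord(
        smiles=smiles,
        id=f"acid_{idx:05d}_{name}",
        formula=formula,
        mw_average=_formula_mw(formula),
        hbd=hbd,
        hba=hba,
        rotatable_bonds=rot,
        ring_count=rings,
        aromatic_ring_count=arom,
        alerts=tuple(alerts),
        is_salt=is_salt,
        n_cooh=n_cooh,
    )


def generate_library(spec: LibrarySpec) -> list[LabelledRecord]:
    """Assemble exactly ``spec.n`` labelled records, deterministically."""
    n = spec.n
    n_salt = round(spec.salt_rate * n)
    n_diacid = round(spec.diacid_rate * n)
    n_alert = {name: round(rate * n) for name, rate in spec.alert_rates.items()}
    n_pass_total = round(spec.fraction_property_pass * n)
    n_spiked_pass = n_diacid + sum(n_alert.values())
    n_clean_pass = n_pass_total - n_spiked_pass
    n_fail = n - n_salt - n_pass_total
    if n_clean_pass < 0:
        raise ValueError(
            "unsatisfiable spec: spiked motifs exceed the property-pass share"
        )
    if n_fail < 0:
        raise ValueError("unsatisfiable spec: rates sum past the library size")

    rng = np.random.default_rng(spec.seed)
    drafts: list[tuple] = []  # (entry, alerts, is_salt, n_cooh)
    for _ in range(n_clean_pass):
        entry = _PASS_POOL[int(rng.integers(len(_PASS_POOL)))]
        drafts.append((entry, (), False, 1))
    for _ in range(n_fail):
        entry = _FAIL_FIXED[int(rng.integers(len(_FAIL_FIXED)))]
        drafts.append((entry, (), False, 1))
    for name in ALERT_NAMES:
        entry = _ALERT_SPIKES.get(name)
        for _ in range(n_alert.get(name, 0)):
            n_cooh = 2 if name == "gem_dicarboxylic" else 1
            drafts.append((entry, (name,), False, n_cooh))
    for _ in range(n_diacid):
        entry = _DIACID_SPIKES[int(rng.integers(len(_DIACID_SPIKES)))]
        drafts.append((entry, (), False, 2))
    for _ in range(n_salt):
        smiles, name = _SALT_SPIKES[int(rng.integers(len(_SALT_SPIKES)))]
        drafts.append(((smiles, name, "", 0, 0, 0, 0, 0), (), True, 0))

    order = rng.permutation(len(drafts))
    records = []
    for idx, slot in enumerate(order):
        entry, alerts, is_salt, n_cooh = drafts[slot]
        if is_salt:
            smiles, name = entry[0], entry[1]
            records.append(
                LabelledRecord(
                    smiles=smiles,
                    id=f"acid_{idx:05d}_{name}",
                    formula="",
                    mw_average=0.0,  # descriptors are undefined for salts
                    hbd=0,
                    hba=0,
                    rotatable_bonds=0,
                    ring_count=0,
                    aromatic_ring_count=0,
                    alerts=(),
                    is_salt=True,
                    n_cooh=n_cooh,
                )
            )
        else:
            records.append(_record(entry, idx, alerts, False, n_cooh))
    return records


def funnel_truth(
    records: Sequence[LabelledRecord],
    criteria: FilterCriteria | None = None,
    alert_names: Sequence[str] | None = None,
) -> FunnelReport:
    """Expected funnel report computed from labels alone.

    Mirrors the pipeline's stage order (validate → drug-likeness → alerts) so
    a realized :class:`~esterfunnel.curation.FunnelReport` can be compared
    stage by stage against this one.
    """
    criteria = criteria or FilterCriteria()
    report = FunnelReport()

    salts = [r for r in records if r.is_salt]
    no_acid = [r for r in records if not r.is_salt and r.n_cooh == 0]
    stage0 = Counter()
    if salts:
        stage0["salt"] = len(salts)
    if no_acid:
        stage0["not_carboxylic_acid"] = len(no_acid)
    valid = [r for r in records if not r.is_salt and r.n_cooh > 0]
    report.add(FunnelStage("validate_acid", len(records), len(valid), stage0))

    stage1 = Counter()
    survivors1 = []
    for r in valid:
        v = r.property_violations(criteria)
        if v:
            stage1.update(v)
        else:
            survivors1.append(r)
    report.add(FunnelStage("druglike_filter", len(valid), len(survivors1), stage1))

    watched = set(alert_names) if alert_names is not None else set(ALERT_NAMES)
    stage2 = Counter()
    survivors2 = []
    for r in survivors1:
        hits = tuple(a for a in r.alerts if a in watched)
        if hits:
            stage2.update(hits)
        else:
            survivors2.append(r)
    report.add(
        FunnelStage("structural_alerts", len(survivors1), len(survivors2), stage2)
    )
    return report


def records_to_smi(records: Sequence[LabelledRecord]) -> str:
    return "".join(f"{r.smiles}\t{r.id}\n" for r in records)


def records_to_labels_tsv(records: Sequence[LabelledRecord]) -> str:
    header = (
        "id\tsmiles\tformula\tmw_average\thbd\thba\trotatable_bonds\t"
        "ring_count\taromatic_ring_count\talerts\tis_salt\tn_cooh"
    )
    lines = [header]
    for r in records:
        mw = "" if r.is_salt else f"{r.mw_average:.4f}"
        lines.append(
            f"{r.id}\t{r.smiles}\t{r.formula}\t{mw}\t{r.hbd}\t{r.hba}\t"
            f"{r.rotatable_bonds}\t{r.ring_count}\t{r.aromatic_ring_count}\t"
            f"{';'.join(r.alerts)}\t{int(r.is_salt)}\t{r.n_cooh}"
        )
    return "\n".join(lines) + "\n"
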