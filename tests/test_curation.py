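"""Drug-likeness thresholds, structural alerts, and the curation funnel."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esterfunnel.chem_core import Molecule, parse_smiles
from esterfunnel.curation import (
    FilterCriteria,
    Rejection,
    apply_alerts,
    apply_druglike_filter,
    load_alert_catalogue,
    strip_and_validate_acid,
    validate_library,
)

ALERTS = load_alert_catalogue()


class TestValidation:
    def test_salt_rejected_whole(self):
        out = strip_and_validate_acid(parse_smiles("[Na+].[O-]C(=O)c1ccccc1", "na_benzoate"))
        assert isinstance(out, Rejection) and out.reasons == ("salt",)

    def test_plain_acid_accepted(self):
        out = strip_and_validate_acid(parse_smiles("OC(=O)c1ccccc1", "benzoic"))
        assert isinstance(out, Molecule)

    def test_non_acid_rejected(self):
        out = strip_and_validate_acid(parse_smiles("c1ccccc1", "benzene"))
        assert isinstance(out, Rejection)
        assert out.reasons == ("not_carboxylic_acid",)

    def test_funnel_stage_counts(self):
        mols = [
            parse_smiles(s, str(i))
            for i, s in enumerate(["CC(=O)O", "Cl.NCC(=O)O", "CCO"])
        ]
        survivors, rejects, stage = validate_library(mols)
        assert (stage.n_in, stage.n_out) == (3, 1)
        assert stage.rejections == {"salt": 1, "not_carboxylic_acid": 1}
        assert len(survivors) + len(rejects) == 3


class TestDruglikeFilter:
    def test_overweight_acid_rejected_under_mw_cap(self):
        # 214 u phenoxybenzoic acid exceeds the 200 u building-block cap
        heavy = parse_smiles("OC(=O)c1ccc(Oc2ccccc2)cc1", "heavy")
        survivors, rejects, stage = apply_druglike_filter([heavy])
        assert survivors == []
        assert rejects[0].reasons == ("mw_max",)

    def test_benzoic_acid_survives_all_six(self):
        survivors, _, _ = apply_druglike_filter([parse_smiles("OC(=O)c1ccccc1", "b")])
        assert len(survivors) == 1

    def test_multirule_violator_tallied_under_every_rule(self):
        # anthracene-9-carboxylic: too heavy, too many rings, too many aromatic
        bad = parse_smiles("OC(=O)c1c2ccccc2cc2ccccc12", "anthracenic")
        _, rejects, stage = apply_druglike_filter([bad])
        assert set(rejects[0].reasons) == {"mw_max", "ring_max", "aromatic_ring_max"}
        assert sum(stage.rejections.values()) == 3  # one record, three tallies

    def test_idempotence(self):
        mols = [
            parse_smiles(s, str(i))
            for i, s in enumerate(
                ["CC(=O)O", "OC(=O)c1ccccc1", "COCCCCCCCC(=O)O", "NC(CCC(N)=O)C(=O)O"]
            )
        ]
        once, _, _ = apply_druglike_filter(mols)
        twice, _, stage = apply_druglike_filter(once)
        assert [m.id for m in twice] == [m.id for m in once]
        assert sum(stage.rejections.values()) == 0

    @given(
        data=st.tuples(
            st.floats(min_value=50, max_value=400),
            st.integers(min_value=0, max_value=6),
            st.integers(min_value=0, max_value=10),
            st.integers(min_value=0, max_value=10),
            st.integers(min_value=0, max_value=4),
            st.integers(min_value=0, max_value=4),
            st.floats(min_value=0, max_value=1),
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotonicity_tightening_never_adds_survivors(self, data):
        """Tightening any thresholds can only shrink the survivor set."""
        mw, hbd, hba, rot, rings, arom, shrink = data
        loose = FilterCriteria(mw, hbd, hba, rot, rings, arom)
        tight = FilterCriteria(
            mw * shrink,
            int(hbd * shrink),
            int(hba * shrink),
            int(rot * shrink),
            int(rings * shrink),
            int(arom * shrink),
        )
        mols = _panel_molecules()
        survivors_loose, _, _ = apply_druglike_filter(mols, loose)
        survivors_tight, _, _ = apply_druglike_filter(mols, tight)
        assert {m.id for m in survivors_tight} <= {m.id for m in survivors_loose}

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            FilterCriteria(mw_max=-1)


def _panel_molecules():
    smiles = [
        "CC(=O)O", "OC(=O)c1ccccc1", "NCC(=O)O", "OC(=O)c1ccc(O)cc1",
        "CCCCCCCCC(=O)O", "OC(=O)c1ccc2ccccc2c1", "COCCCCCCCC(=O)O",
        "OC(=O)C12CC3CC(C1)CC(C2)C3", "OCC(O)C(O)C(O)C(=O)O",
        "OC(=O)c1c2ccccc2cc2ccccc12",
    ]
    return [parse_smiles(s, f"panel_{i}") for i, s in enumerate(smiles)]


# ---------------------------------------------------------------------------
# Brute-force alert oracle: independent graph-walk predicates over the
# Molecule atom/bond views, written without SMARTS, checked against the
# catalogue patterns on a mixed positive/negative panel.
# ---------------------------------------------------------------------------


def _graph(m: Molecule):
    atoms = m.atoms
    adjacency: dict[int, dict[int, object]] = {i: {} for i in range(len(atoms))}
    for i, j, order in m.bonds:
        adjacency[i][j] = order
        adjacency[j][i] = order
    return atoms, adjacency


def _carbonyl_carbons(atoms, adj):
    out = []
    for i, (el, *_rest) in enumerate(atoms):
        if el == "C" and any(
            atoms[j][0] == "O" and order == 2 for j, order in adj[i].items()
        ):
            out.append(i)
    return out


def _cooh_carbons(atoms, adj):
    out = []
    for i in _carbonyl_carbons(atoms, adj):
        for j, order in adj[i].items():
            if atoms[j][0] == "O" and order == 1 and atoms[j][3] == 1:
                out.append(i)
    return out


def brute_epoxide(m):
    atoms, adj = _graph(m)
    return _three_ring_with(atoms, adj, "O")


def brute_aziridine(m):
    atoms, adj = _graph(m)
    return _three_ring_with(atoms, adj, "N")


def _three_ring_with(atoms, adj, hetero):
    for i in range(len(atoms)):
        if atoms[i][0] != hetero:
            continue
        neighbours = [j for j in adj[i]]
        for a in neighbours:
            for b in neighbours:
                if a < b and b in adj[a] and atoms[a][0] == atoms[b][0] == "C":
                    return True
    return False


def brute_disulfide(m):
    atoms, adj = _graph(m)
    return any(
        atoms[i][0] == "S" and atoms[j][0] == "S"
        for i in adj
        for j in adj[i]
    )


def brute_nitrogen_oxide(m):
    atoms, adj = _graph(m)
    for i, (el, charge, *_r) in enumerate(atoms):
        if el != "N":
            continue
        for j, order in adj[i].items():
            if atoms[j][0] == "O":
                if charge == 1 and atoms[j][1] == -1 and len(adj[j]) == 1:
                    return True
                if order == 2:
                    return True
    return False


def brute_azo(m):
    atoms, adj = _graph(m)
    for i in adj:
        for j, order in adj[i].items():
            if i < j and order == 2 and atoms[i][0] == atoms[j][0] == "N":
                if any(atoms[x][0] == "C" for x in adj[i] if x != j) and any(
                    atoms[x][0] == "C" for x in adj[j] if x != i
                ):
                    return True
    return False


def brute_beta_lactam(m):
    atoms, adj = _graph(m)
    for c in _carbonyl_carbons(atoms, adj):
        for n in adj[c]:
            if atoms[n][0] != "N":
                continue
            # close a 4-ring c-n-x-y-c
            for x in adj[n]:
                if x == c:
                    continue
                for y in adj[x]:
                    if y not in (n, c) and c in adj[y]:
                        return True
    return False


def brute_aminonitrile(m):
    atoms, adj = _graph(m)
    carbonyls = set(_carbonyl_carbons(atoms, adj))
    for c2 in adj:  # nitrile carbon
        if atoms[c2][0] != "C":
            continue
        nitrile_n = [j for j, order in adj[c2].items() if order == 3 and atoms[j][0] == "N"]
        if not nitrile_n:
            continue
        for c1 in adj[c2]:
            if atoms[c1][0] != "C" or any(o != 1 for o in adj[c1].values()):
                continue  # the carrier carbon must be sp3
            for n in adj[c1]:
                if (
                    atoms[n][0] == "N"
                    and n not in nitrile_n
                    and all(o == 1 for o in adj[n].values())
                    and not (set(adj[n]) & carbonyls)
                ):
                    return True
    return False


def brute_thionitrile(m):
    atoms, adj = _graph(m)
    for s in adj:
        if atoms[s][0] != "S":
            continue
        for c in adj[s]:
            if atoms[c][0] == "C" and any(
                o == 3 and atoms[j][0] == "N" for j, o in adj[c].items()
            ):
                return True
    return False


def brute_long_chain(m):
    atoms, adj = _graph(m)
    for c in _cooh_carbons(atoms, adj):
        for start in adj[c]:
            chain = [c, start]
            while True:
                tip = chain[-1]
                el, _charge, aromatic, n_h = atoms[tip]
                if el != "C" or aromatic or any(o != 1 for o in adj[tip].values()):
                    break
                position = len(chain) - 1  # chain carbons walked so far
                if position < 8 and n_h != 2:
                    break
                if position >= 8 and n_h >= 2:
                    return True
                nxt = [x for x in adj[tip] if x != chain[-2] and atoms[x][0] == "C"]
                if len(nxt) != 1:
                    break
                chain.append(nxt[0])
    return False


def brute_gem_dicarboxylic(m):
    atoms, adj = _graph(m)
    cooh = set(_cooh_carbons(atoms, adj))
    for i in adj:
        if atoms[i][0] == "C" and all(o == 1 for o in adj[i].values()):
            if len(cooh & set(adj[i])) >= 2:
                return True
    return False


def brute_quaternary_ammonium(m):
    atoms, adj = _graph(m)
    for i, (el, charge, _arom, n_h) in enumerate(atoms):
        if el == "N" and charge == 1 and len(adj[i]) + n_h == 4:
            if not any(atoms[j][0] == "O" and atoms[j][1] == -1 for j in adj[i]):
                return True
    return False


def brute_heteroelement(m):
    return any(a[0] in ("B", "Si", "Se") for a in m.atoms)


BRUTE = {
    "epoxide": brute_epoxide,
    "aziridine": brute_aziridine,
    "disulfide": brute_disulfide,
    "nitrogen_oxide": brute_nitrogen_oxide,
    "azo": brute_azo,
    "beta_lactam": brute_beta_lactam,
    "aminonitrile": brute_aminonitrile,
    "thionitrile": brute_thionitrile,
    "long_chain_fatty_acid": brute_long_chain,
    "gem_dicarboxylic": brute_gem_dicarboxylic,
    "quaternary_ammonium": brute_quaternary_ammonium,
    "boron_silicon_selenium": brute_heteroelement,
}

ALERT_PANEL = [
    "OC(=O)C1CO1",            # epoxide (glycidic acid)
    "OC(=O)C1CN1",            # aziridine
    "OC(=O)CSSC",             # disulfide
    "OC(=O)c1ccc[n+]([O-])c1",  # pyridine N-oxide
    "OC(=O)c1ccc(cc1)[N+](=O)[O-]",  # nitro: also a nitrogen oxide
    "OC(=O)CN=NC",            # azo
    "OC(=O)C1CC(=O)N1",       # beta-lactam
    "OC(=O)C(N)C#N",          # aminonitrile
    "OC(=O)CSC#N",            # thionitrile
    "CCCCCCCCC(=O)O",         # nonanoic: long-chain fatty acid
    "CCCCCCCC(=O)O",          # octanoic: one carbon short of the alert
    "CCCCCCC(C)C(=O)O",       # branched at C2: not an unbranched chain
    "OC(=O)CC(=O)O",          # malonic: gem-dicarboxylic
    "OC(=O)C(C)C(=O)O",       # methylmalonic: gem-dicarboxylic
    "OC(=O)CCC(=O)O",         # succinic: NOT gem
    "C[N+](C)(C)CC(=O)O",     # betaine: quaternary ammonium
    "C[Si](C)(C)CCC(=O)O",    # silicon
    "OB(O)c1ccc(cc1)C(=O)O",  # boron
    "C[Se]CC(=O)O",           # selenium
    "OC(=O)c1ccccc1",         # benzoic: clean
    "CC(=O)O",                # acetic: clean
    "NCC(=O)O",               # glycine: amine but no nitrile
    "CC(=O)NCC(=O)O",         # acyclic amide: not a beta-lactam
    "N#Cc1ccccc1",            # aryl nitrile alone: no amino/thio partner
    "CSCCC(=O)O",             # thioether without nitrile
    "OC(=O)C1CCCO1",          # oxolane: O in 5-ring, not an epoxide
    "OC(=O)C1CCNCC1",         # piperidine: N in 6-ring, not aziridine
    "Cn1cccc1C(=O)O",         # neutral aromatic N: not an N-oxide
    "OC(=O)CCc1ccccc1",       # clean aryl
    "CC(C)(C)C(=O)O",         # clean branched
]


class TestAlerts:
    @pytest.mark.parametrize("smiles, expected", [
        ("OC(=O)C1CO1", ("epoxide",)),
        ("OC(=O)CC(=O)O", ("gem_dicarboxylic",)),
        ("CCCCCCCCCCCCCCCCCC(=O)O", ("long_chain_fatty_acid",)),
        ("OC(=O)c1ccccc1", ()),
    ])
    def test_named_examples(self, smiles, expected):
        m = parse_smiles(smiles)
        hits = tuple(a.name for a in ALERTS if a.matches(m))
        assert hits == expected

    @pytest.mark.parametrize("alert", ALERTS, ids=[a.name for a in ALERTS])
    def test_catalogue_agrees_with_brute_force_matcher(self, alert):
        """Each SMARTS pattern equals its hand-written graph predicate."""
        brute = BRUTE[alert.name]
        for smiles in ALERT_PANEL:
            m = parse_smiles(smiles)
            assert alert.matches(m) == brute(m), f"{alert.name} on {smiles}"

    def test_apply_alerts_records_matched_names(self):
        mols = [
            parse_smiles("OC(=O)C1CO1", "glycidic"),
            parse_smiles("OC(=O)CC(=O)O", "malonic"),
            parse_smiles("OC(=O)c1ccccc1", "benzoic"),
        ]
        survivors, rejects, stage = apply_alerts(mols, ALERTS)
        assert [m.id for m in survivors] == ["benzoic"]
        assert {r.molecule_id: r.reasons for r in rejects} == {
            "glycidic": ("epoxide",),
            "malonic": ("gem_dicarboxylic",),
        }
        assert stage.rejections == {"epoxide": 1, "gem_dicarboxylic": 1}

    def test_alert_names_unique_and_compiled(self):
        names = [a.name for a in ALERTS]
        assert len(names) == len(set(names))
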