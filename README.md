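# esterfunnel

Diversity-driven design of triterpene 3-*O*-ester screening libraries.

## The problem

Oleanolic acid (OA, C30H48O3) is a pentacyclic triterpene bearing a 3β-hydroxyl
and a C-28 carboxylic acid. Acylating the 3β-OH with small carboxylic acids
yields 3-*O*-ester derivatives that can modulate the bile-acid nuclear
receptor FXR. Designing such a library from a commercial acid catalogue is a
funnel: tens of thousands of candidate acids must be reduced to a few hundred
diverse, drug-like, chemically tractable building blocks before virtual
screening. `esterfunnel` implements that funnel as a reusable, tested
pipeline:

1. **Curation** — single-fragment mono-acids only (salts dropped whole);
   customized drug-likeness thresholds for building blocks that will inherit
   a 456 u scaffold (MW ≤ 200, HBD ≤ 4, HBA ≤ 8, rotatable bonds ≤ 7,
   rings ≤ 2, aromatic rings ≤ 2); a structural-alert catalogue removing
   reactive/unstable groups (epoxide, aziridine, disulfide, nitrogen oxides,
   azo, β-lactam, amino-/thionitrile) and non-druglike chemotypes (long-chain
   fatty acids, *gem*-dicarboxylic acids, quaternary ammonium, B/Si/Se).
2. **Diversity selection** — functional-class circular fingerprints of
   diameter 4 (radius-2 Morgan-style hashing over pharmacophoric atom
   classes), Tanimoto similarity T = c/(a+b−c), and partitioning into *k*
   clusters (MaxMin seeding + nearest-medoid assignment in 1−T space) with
   one representative drawn per cluster under a fixed seed.
3. **Enumeration** — condensation of each representative onto the declared
   3β-OH site with exact bookkeeping,
   `formula(ester) = formula(scaffold) + formula(acid) − H2O`,
   and ESI adduct *m/z* prediction ([M−H]−, [M+H]+, [M+Na]+).
4. **Ranking** — ingestion and ranking of externally produced docking scores
   (pKi), with a positive-control check; the docking engine itself is out of
   scope and recorded only as provenance.

Because the original source catalogue is proprietary, the package ships a
seeded synthetic acid-library generator (`synthetic_data`) whose records
carry construction-time ground-truth labels, so every funnel stage has exact
expected counts and the whole pipeline is testable offline.

## Worked example

The numbered drivers under `analysis/` run the full study on a simulated
4000-acid library and write their tables under `results/analysis/`:

```bash
python analysis/01_simulate_library.py
python analysis/02_curate_funnel.py
python analysis/03_cluster_select.py
python analysis/04_enumerate_esters.py
python analysis/05_rank_scores.py
```

The curation driver prints the funnel:

```
stage            n_in   n_out  rule_tallies
validate_acid    4000   3960   salt=40
druglike_filter  3960   700    aromatic_ring_max=333;hba_max=322;hbd_max=952;mw_max=1631;ring_max=674;rotatable_max=993
structural_alerts 700   556    aminonitrile=12;aziridine=12;azo=12;...
realized funnel equals label-derived expectation: True
```

i.e. 4000 records → 3960 after salt removal → 700 drug-like → 556 after
alerts, and the realized counts (including every per-rule tally) equal the
generator's label-derived expectation exactly. Clustering then yields 285
non-empty clusters and 285 representatives, and enumeration prints

```
269 esters from 285 representatives, 16 rejects
anchor ester C40H53NO5: [M-H]- 626.4, [M+H]+ 628.4, [M+Na]+ 650.4
```

(the 16 rejects are non-*gem* di-acids, which survive curation but cannot be
esterified unambiguously; the anchor is the 3-phenylisoxazole-5-carboxylate
ester of OA, whose deprotonated ion computes to *m/z* 626.4). The ranking
driver orders an example five-ligand docking table and confirms the positive
control outranks the library (`control check: pass`).

A single command runs the same funnel end to end with a manifest:

```bash
esterfunnel run --seed 2 --out-dir run_out
```

## Layout

- `src/esterfunnel/` — the library: `chem_core` (parsing, formulas, masses,
  descriptors), `curation`, `diversity`, `enumeration`, `screening_rank`,
  `synthetic_data`, `pipeline`, `cli`.
- `src/esterfunnel/data/` — pinned atomic-mass table, structural-alert
  catalogue (editable SMARTS TSV), fingerprint class definitions, and the OA
  scaffold fixture with its esterification site declared by atom map.
- `analysis/` — the numbered study drivers.
- `docs/methods.md` — model, conventions, parameters, and limitations.
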