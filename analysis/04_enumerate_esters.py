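#!/usr/bin/env python
"""Condense every representative acid onto the scaffold 3β-OH.

Each ester's formula and masses obey formula(scaffold) + formula(acid) − H2O
exactly; ESI adduct m/z values ([M−H]−, [M+H]+, [M+Na]+) are predicted from
the monoisotopic mass. As a sanity anchor the 3-phenylisoxazole-5-carboxylate
ester (C40H53NO5) is printed — its deprotonated ion computes to 626.4.

Reads results/analysis/{curated.smi,representatives.txt}; writes esters.csv
and esters.smi.
"""

from pathlib import Path

from esterfunnel.chem_core import parse_smiles, parse_structures, write_smiles_tsv
from esterfunnel.enumeration import (
    enumerate_library,
    esterify,
    load_default_scaffold,
    products_to_csv,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    parsed = parse_structures((OUT / "curated.smi").read_text(), "smiles")
    by_id = {m.id: m for m in parsed.molecules}
    rep_ids = (OUT / "representatives.txt").read_text().split()
    site = load_default_scaffold()

    products, rejects = enumerate_library(site, [by_id[i] for i in rep_ids])
    (OUT / "esters.csv").write_text(products_to_csv(products))
    (OUT / "esters.smi").write_text(
        write_smiles_tsv([p.product for p in products])
    )
    print(f"{len(products)} esters from {len(rep_ids)} representatives, "
          f"{len(rejects)} rejects")
    for acid_id, reason in rejects:
        print(f"  reject {acid_id}: {reason}")

    anchor = esterify(
        site, parse_smiles("OC(=O)c1cc(-c2ccccc2)no1", "phenylisoxazole_5_carboxylic")
    )
    print(
        f"anchor ester {anchor.formula}: "
        f"[M-H]- {anchor.adduct_mz['[M-H]-']:.1f}, "
        f"[M+H]+ {anchor.adduct_mz['[M+H]+']:.1f}, "
        f"[M+Na]+ {anchor.adduct_mz['[M+Na]+']:.1f}"
    )


if __name__ == "__main__":
    main()
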