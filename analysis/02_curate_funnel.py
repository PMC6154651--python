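#!/usr/bin/env python
"""Run the two-pass curation funnel over the simulated library.

Validates salts/acid groups, applies the customized drug-likeness thresholds
(MW ≤ 200, HBD ≤ 4, HBA ≤ 8, rotatable ≤ 7, rings ≤ 2, aromatic rings ≤ 2),
then the structural-alert catalogue, and checks the realized funnel against
the generator's label-derived expectation.

Reads results/analysis/library.smi (+ labels via regeneration); writes
curated.smi and funnel.tsv.
"""

from pathlib import Path

from esterfunnel.chem_core import parse_structures, write_smiles_tsv
from esterfunnel.curation import (
    FunnelReport,
    apply_alerts,
    apply_druglike_filter,
    validate_library,
)
from esterfunnel.synthetic_data import LibrarySpec, funnel_truth, generate_library

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED, N = 11, 4000  # must match 01_simulate_library.py


def main() -> None:
    parsed = parse_structures((OUT / "library.smi").read_text(), "smiles")
    print(f"parsed {len(parsed.molecules)} records, {len(parsed.rejects)} rejects")

    funnel = FunnelReport()
    valid, _, s0 = validate_library(list(parsed.molecules))
    funnel.add(s0)
    druglike, _, s1 = apply_druglike_filter(valid)
    funnel.add(s1)
    curated, _, s2 = apply_alerts(druglike)
    funnel.add(s2)

    (OUT / "curated.smi").write_text(write_smiles_tsv(curated))
    (OUT / "funnel.tsv").write_text(funnel.to_tsv())
    print(funnel.to_tsv())

    expected = funnel_truth(generate_library(LibrarySpec(n=N, seed=SEED)))
    agree = all(
        (w.n_in, w.n_out, dict(w.rejections)) == (g.n_in, g.n_out, dict(g.rejections))
        for w, g in zip(expected.stages, funnel.stages)
    )
    print(f"realized funnel equals label-derived expectation: {agree}")
    if not agree:
        raise SystemExit("funnel mismatch — curation and generator disagree")


if __name__ == "__main__":
    main()
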