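#!/usr/bin/env python
"""Diversity-cluster the curated acids and pick one representative each.

Functional-class circular fingerprints (radius 2, 1024 bits) are clustered
into k = 285 groups by MaxMin seeding + nearest-medoid assignment in
Tanimoto-distance space; one acid per cluster is then drawn uniformly under
a fixed seed — the diversity-selection step that shrinks the curated library
to a screening-sized set.

Reads results/analysis/curated.smi; writes clusters.tsv, representatives.txt.
"""

from pathlib import Path

from esterfunnel.chem_core import parse_structures
from esterfunnel.diversity import cluster, fingerprint, select_representatives

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
K = 285
CLUSTER_SEED = 0
PICK_SEED = 7


def main() -> None:
    parsed = parse_structures((OUT / "curated.smi").read_text(), "smiles")
    mols = list(parsed.molecules)
    print(f"fingerprinting {len(mols)} curated acids")
    fps = [fingerprint(m) for m in mols]

    assignment = cluster(fps, k=K, seed=CLUSTER_SEED)
    rep_ids = select_representatives(assignment, seed=PICK_SEED)
    assignment = assignment.with_representatives(rep_ids)

    (OUT / "clusters.tsv").write_text(assignment.to_tsv())
    (OUT / "representatives.txt").write_text("\n".join(rep_ids) + "\n")

    sizes = sorted(
        (len(v) for v in assignment.members_by_cluster().values()), reverse=True
    )
    print(f"{assignment.n_nonempty} non-empty clusters (k={K})")
    print(f"largest clusters: {sizes[:5]}, singletons: {sizes.count(1)}")
    print(f"{len(rep_ids)} representatives -> representatives.txt")


if __name__ == "__main__":
    main()
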