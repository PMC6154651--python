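"""Feature-class circular fingerprints and Tanimoto diversity clustering.

The fingerprint is a functional-class circular fingerprint of diameter 4
(radius 2): Morgan-style iterative environment hashing whose initial atom
invariant is not the element identity but the 6-bit mask of pharmacophoric
classes (H-bond acceptor, H-bond donor, positively ionizable, negatively
ionizable, aromatic, halogen), each class defined by a SMARTS rule shipped in
``data/fcfp_classes.tsv``. Environment hashes from every iteration depth are
folded modulo the bit-vector length. The hash is a pinned 32-bit FNV-1a mix
over sorted (bond-order, neighbour-invariant) tuples, so bit sets are stable
across platforms and atom numberings. Exact bit-compatibility with any
commercial FCFP_4 implementation is a non-goal; the class definitions above
are this package's documented convention.

Diversity selection partitions the library into ``k`` clusters by
maximum-dissimilarity (MaxMin) seeding followed by nearest-medoid assignment
in Tanimoto-distance space, then draws one representative per cluster
uniformly at random under a stated seed. All tie-breaks and the processing
order are canonical in the molecule identifiers, so the partition is a
function of the input *set*, not its order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .chem_core import Molecule

__all__ = [
    "FingerprintSpec",
    "Fingerprint",
    "ClusterAssignment",
    "fingerprint",
    "tanimoto",
    "cluster",
    "select_representatives",
]

logger = logging.getLogger(__name__)

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193
_MASK32 = 0xFFFFFFFF

_BOND_CODE = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}


def _mix(ints: Sequence[int]) -> int:
    """Pinned 32-bit FNV-1a over a stream of integers (4 bytes each)."""
    h = _FNV_OFFSET
    for value in ints:
        for byte in (value & _MASK32).to_bytes(4, "little"):
            h = ((h ^ byte) * _FNV_PRIME) & _MASK32
    return h


def _load_class_queries() -> tuple[tuple[str, Chem.Mol], ...]:
    text = resources.files("esterfunnel.data").joinpath("fcfp_classes.tsv").read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, smarts = line.split("\t")
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"class {name!r}: SMARTS does not compile")
        out.append((name, query))
    return tuple(out)


_CLASS_QUERIES = _load_class_queries()
CLASS_NAMES = tuple(name for name, _ in _CLASS_QUERIES)


@dataclass(frozen=True)
class FingerprintSpec:
    """Radius (bond steps; diameter = 2×radius) and folded length."""

    radius: int = 2
    n_bits: int = 1024
    invariant_scheme: str = "functional-class"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_bits < 1 or (self.n_bits & (self.n_bits - 1)):
            raise ValueError("n_bits must be a power of two")


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset
    molecule_id: str
    spec: FingerprintSpec

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.spec.n_bits for b in self.bits):
            raise ValueError("bit outside [0, n_bits)")

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def to_hex(self) -> str:
        value = 0
        for b in self.bits:
            value |= 1 << b
        return f"{value:0{self.spec.n_bits // 4}x}"


def atom_class_mask(mol: Chem.Mol) -> list[int]:
    """6-bit functional-class mask per atom (bit i = i-th catalogue class)."""
    masks = [0] * mol.GetNumAtoms()
    for bit, (_, query) in enumerate(_CLASS_QUERIES):
        for (idx,) in mol.GetSubstructMatches(query):
            masks[idx] |= 1 << bit
    return masks


def fingerprint(m: Molecule, spec: FingerprintSpec | None = None) -> Fingerprint:
    """Hash circular environments of radius 0..spec.radius into a bit set."""
    spec = spec or FingerprintSpec()
    mol = m.rdmol
    masks = atom_class_mask(mol)
    env = [_mix((0, mask)) for mask in masks]
    hashes = list(env)
    neighbours = [
        [
            (_BOND_CODE[b.GetBondType()], b.GetOtherAtomIdx(a.GetIdx()))
            for b in a.GetBonds()
        ]
        for a in mol.GetAtoms()
    ]
    for r in range(1, spec.radius + 1):
        new_env = []
        for idx in range(mol.GetNumAtoms()):
            parts = [r, env[idx]]
            for code, h in sorted(
                (code, env[other]) for code, other in neighbours[idx]
            ):
                parts.extend((code, h))
            new_env.append(_mix(parts))
        env = new_env
        hashes.extend(env)
    bits = frozenset(h % spec.n_bits for h in hashes)
    return Fingerprint(bits=bits, molecule_id=m.id, spec=spec)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """T = |A∩B| / |A∪B|; two empty bit sets are defined as identical (1.0)."""
    if a.spec != b.spec:
        raise ValueError("fingerprint spec mismatch")
    if not a.bits and not b.bits:
        return 1.0
    inter = len(a.bits & b.bits)
    union = len(a.bits) + len(b.bits) - inter
    return inter / union


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of a fingerprint set with one flagged representative each.

    ``assignments`` maps molecule id → cluster index in ``[0, k)``;
    ``representatives`` holds exactly one member id per non-empty cluster.
    """

    assignments: Mapping[str, int]
    representatives: frozenset
    k: int
    seed: int
    medoids: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        by_cluster = self.members_by_cluster()
        reps = set(self.representatives)
        for c, members in by_cluster.items():
            inside = reps & set(members)
            if len(inside) != 1:
                raise ValueError(f"cluster {c} has {len(inside)} representatives")

    def members_by_cluster(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for mol_id in sorted(self.assignments):
            out.setdefault(self.assignments[mol_id], []).append(mol_id)
        return out

    @property
    def n_nonempty(self) -> int:
        return len(set(self.assignments.values()))

    def with_representatives(self, reps: Sequence[str]) -> "ClusterAssignment":
        return replace(self, representatives=frozenset(reps))

    def to_tsv(self) -> str:
        lines = ["molecule_id\tcluster\tis_representative"]
        for mol_id in sorted(self.assignments):
            rep = int(mol_id in self.representatives)
            lines.append(f"{mol_id}\t{self.assignments[mol_id]}\t{rep}")
        return "\n".join(lines) + "\n"


def _pack(fps: Sequence[Fingerprint]) -> np.ndarray:
    n_bits = fps[0].spec.n_bits
    X = np.zeros((len(fps), n_bits), dtype=np.uint16)
    for row, fp in enumerate(fps):
        if fp.bits:
            X[row, sorted(fp.bits)] = 1
    return X


def _distance_rows(X: np.ndarray, pop: np.ndarray, idx: int) -> np.ndarray:
    """1 − Tanimoto of every row against row ``idx`` (empty∩empty → 0)."""
    inter = X @ X[idx]
    union = pop + pop[idx] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return 1.0 - sim


def cluster(
    fps: Sequence[Fingerprint],
    k: int | None = None,
    seed: int = 0,
    threshold: float | None = None,
) -> ClusterAssignment:
    """Partition fingerprints into clusters in Tanimoto-distance space.

    k-mode (default): MaxMin seeding picks ``k`` medoids — the first drawn by
    the seeded RNG, each further one maximizing its minimum distance to the
    chosen set — then every point joins its nearest medoid (medoids stay in
    their own cluster; ties go to the lowest cluster index). Exactly
    ``min(n, k)`` clusters are non-empty. threshold-mode: leader clustering in
    canonical id order — a point within ``threshold`` distance of an existing
    leader joins its nearest leader, otherwise founds a new cluster.
    """
    if not fps:
        raise ValueError("no fingerprints to cluster")
    if (k is None) == (threshold is None):
        raise ValueError("specify exactly one of k or threshold")
    spec = fps[0].spec
    if any(fp.spec != spec for fp in fps):
        raise ValueError("fingerprint spec mismatch within input")
    ids = [fp.molecule_id for fp in fps]
    if len(set(ids)) != len(ids):
        raise ValueError("molecule ids must be unique")

    # canonical processing order: sorted ids, so the partition is a function
    # of the input set rather than its ordering
    order = sorted(range(len(fps)), key=lambda i: ids[i])
    fps = [fps[i] for i in order]
    ids = [ids[i] for i in order]
    n = len(fps)
    X = _pack(fps)
    pop = X.sum(axis=1)

    if threshold is not None:
        leaders: list[int] = []
        labels = np.empty(n, dtype=int)
        for i in range(n):
            if leaders:
                d = np.array(
                    [_distance_rows(X, pop, lead)[i] for lead in leaders]
                )
                best = int(np.argmin(d))
                if d[best] <= threshold:
                    labels[i] = best
                    continue
            leaders.append(i)
            labels[i] = len(leaders) - 1
        medoid_idx = leaders
        k_eff = len(leaders)
    else:
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > n:
            logger.warning("k=%d exceeds n=%d; every molecule is a singleton", k, n)
        k_eff = min(k, n)
        rng = np.random.default_rng(seed)
        first = int(rng.integers(n))
        selected = [first]
        min_dist = _distance_rows(X, pop, first)
        min_dist[first] = -1.0
        for _ in range(k_eff - 1):
            nxt = int(np.argmax(min_dist))  # first max = lowest canonical id
            selected.append(nxt)
            d = _distance_rows(X, pop, nxt)
            min_dist = np.minimum(min_dist, d)
            min_dist[nxt] = -1.0
        medoid_idx = selected
        M = X[medoid_idx]
        inter = X @ M.T
        union = pop[:, None] + pop[medoid_idx][None, :] - inter
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
        labels = np.argmin(1.0 - sim, axis=1)
        for c, i in enumerate(medoid_idx):
            labels[i] = c  # a medoid anchors its own cluster

    assignments = {ids[i]: int(labels[i]) for i in range(n)}
    medoid_ids = tuple(ids[i] for i in medoid_idx)
    return ClusterAssignment(
        assignments=assignments,
        representatives=frozenset(medoid_ids),
        k=k if k is not None else k_eff,
        seed=seed,
        medoids=medoid_ids,
    )


def select_representatives(ca: ClusterAssignment, seed: int) -> list[str]:
    """Draw one member per non-empty cluster uniformly, ordered by cluster.

    A single seeded RNG walks the clusters in index order over their sorted
    member lists, so the draw is reproducible and independent of input order.
    """
    rng = np.random.default_rng(seed)
    reps: list[str] = []
    for c, members in sorted(ca.members_by_cluster().items()):
        reps.append(members[int(rng.integers(len(members)))])
    return reps
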