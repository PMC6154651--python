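# Methods

## Scope and model

`esterfunnel` models diversity-oriented design of a 3-*O*-ester library on an
oleanolic-acid (OA) scaffold as four composable stages over a carboxylic-acid
building-block library: curation (validity + drug-likeness + structural
alerts), diversity selection (fingerprint clustering + one representative per
cluster), combinatorial esterification with exact mass bookkeeping, and
ranking of externally produced docking scores. The docking computation
itself, binding-mode analysis, synthesis chemistry, and any biological assay
are outside the package: docking is an adapter contract (structures out,
score CSV in, configuration recorded verbatim as provenance).

All chemistry is 2D. Stereochemistry is parsed but ignored by every
descriptor and fingerprint. Aromaticity and ring perception are delegated to
RDKit under its default sanitization; records that fail sanitization
(including kekulization failures) are routed to a rejects report, never
silently dropped.

## Descriptor conventions (`chem_core`)

The six filter descriptors are computed by explicit graph walks with pinned
conventions, because filter outcomes must be exactly reproducible:

- **HBD** — count of hydrogens on N or O (Lipinski donor convention).
- **HBA** — count of N plus O atoms (Lipinski acceptor convention).
- **Rotatable bonds** — non-ring single bonds whose two ends are both
  non-terminal heavy atoms (heavy degree ≥ 2), excluding amide C–N. Note the
  convention counts bonds to non-terminal sp carbons (e.g. Ar–C≡N) because no
  linearity exception is made.
- **Rings** — the size of the smallest set of smallest rings (plain SSSR,
  e.g. 3 for adamantane, not RDKit's symmetrized count of 4).
- **Aromatic rings** — SSSR rings whose atoms are all aromatic.

Masses come from a pinned isotope/atomic-weight table
(`data/atomic_masses.json`): monoisotopic = most-abundant-isotope sum,
average = standard-atomic-weight sum, both charge-corrected by the electron
mass. Pinning makes every mass (and thus every MW-filter decision and m/z)
bit-stable across platforms and library versions.

## Curation (`curation`)

Stage order is validation → drug-likeness → alerts. Multi-fragment records
are rejected whole as salts (reason `salt`) rather than desalted: a
counter-ion form duplicates its parent acid, so keeping the stripped parent
would double-count a building block. Survivors must contain at least one
free COOH (`C(=O)OH`).

Default thresholds (`FilterCriteria`): MW ≤ 200 u, HBD ≤ 4, HBA ≤ 8,
rotatable ≤ 7, rings ≤ 2, aromatic rings ≤ 2 — customized rule-of-5-style
bounds for acids that will each inherit a 456 u triterpene scaffold upon
esterification (a 500 u cap on the final ester would leave almost no acid
head-room, hence the cap on the acid instead).

The alert catalogue (`data/alerts.tsv`) is an editable TSV of named SMARTS
patterns in two categories, reactive/unstable and non-druglike. Decisions
where the category names alone underdetermine a pattern:

- **Long-chain fatty acid** — defined as an unbranched sp3 chain of ≥ 8
  carbons terminating in the COOH (first seven strictly CH2). Nonanoic acid
  triggers it; octanoic and 2-methyl-branched analogues do not.
- **gem-dicarboxylic** — two COOH groups on one sp3 carbon (malonic-type);
  linear di-acids such as succinic deliberately do not match.
- **Nitrogen oxides** — N⁺–O⁻ or N=O; this covers N-oxides and nitro groups,
  both nitrogen oxides.
- **B/Si/Se** — an element scan (`element:B,Si,Se`), not a pattern.
- **Ion-exchange resins** — not expressible on small molecules; covered by
  the quaternary-ammonium alert (no polymer records exist in the inputs).

A record tripping several rules is counted once in survivor arithmetic but
tallied under every rule, so funnel tallies are diagnostic and may sum past
`n_in − n_out`.

## Fingerprints and clustering (`diversity`)

The fingerprint is a functional-class circular fingerprint of diameter 4:
radius-2 Morgan-style iteration whose initial atom invariant is the 6-bit
mask of pharmacophoric classes — H-bond acceptor, H-bond donor, positively
ionizable, negatively ionizable, aromatic, halogen — each defined by a SMARTS
rule in `data/fcfp_classes.tsv`. Environment hashes are produced by a pinned
32-bit FNV-1a mix over the iteration depth, the centre invariant, and the
sorted (bond-order, neighbour-invariant) pairs, and all depths 0..radius are
folded modulo `n_bits` (default 1024, power of two enforced). Sorting
neighbour tuples makes bit sets invariant under atom renumbering;
deduplication of equivalent environments by atom set is *not* performed, so
the bit set is a superset encoding — acceptable because only Tanimoto
comparisons consume it. Bit-compatibility with commercial FCFP_4
implementations is a non-goal; the test suite instead checks that similarity
orderings correlate with RDKit's feature-Morgan fingerprint.

Tanimoto similarity is c/(a+b−c) on bit sets; two empty fingerprints are
defined as identical (T = 1). 1−T is a metric, property-tested on random
triples.

Clustering is deterministic diversity partitioning:

- **k-mode (default)** — MaxMin seeding: the first medoid is drawn by the
  seeded RNG; each further medoid maximizes its minimum distance to the
  chosen set, ties broken by lowest canonical id. Every point then joins its
  nearest medoid (ties to the lowest cluster index), except that a medoid
  always anchors its own cluster — this guarantees exactly min(n, k)
  non-empty clusters even when the input contains duplicate structures.
  k is a configuration input, defaulting to the 285 used throughout the
  analysis scripts.
- **threshold-mode** — leader clustering in canonical id order with a
  Tanimoto-distance threshold, for when a similarity cutoff rather than a
  cluster count is the natural control. Exactly one of k/threshold must be
  given; k-mode is the default elsewhere in the package because a requested
  cluster count is the reproducible contract.

All processing is in canonical (sorted-id) order, so the partition is a
function of the input *set*: shuffling the input changes nothing, which is
property-tested. `k > n` degrades to singletons with a logged warning.

Representative selection draws one member per non-empty cluster uniformly:
a single RNG seeded with the stated seed walks clusters in index order over
sorted member lists. Uniformity is tested by a 1000-seed sweep over a
two-member cluster (binomial tolerance).

## Esterification (`enumeration`)

The scaffold fixture (`data/oa_scaffold.smi`) declares the esterifiable
3β-OH by an atom-map label; no automatic site perception is attempted. The
transform bonds the hydroxyl oxygen to the acid's carbonyl carbon and deletes
the acid's hydroxyl oxygen (net loss of H2O). Acids must carry exactly one
free COOH: zero or several (non-*gem* di-acids survive curation) is an error
naming the acid, routed to a rejects report during library enumeration.
Other nucleophilic groups on an acid are ignored — side-reactivity is
synthesis chemistry, not enumeration.

Formula conservation,
`formula(ester) = formula(scaffold) + formula(acid) − H2O`, is asserted
inside `esterify` for every product (monoisotopic agreement to 1e-6 u).
Adduct m/z assumes singly charged ions: [M−H]− at −1.007276 u, [M+H]+ at
+1.007276 u, [M+Na]+ at +22.989221 u (Na minus one electron). Predictions
are monoisotopic; average masses are also emitted in the product table for
diagnostics, since low-resolution ESI values straddle the two at one decimal
place.

## Synthetic library generator (`synthetic_data`)

The generator replaces the proprietary source catalogue with seeded,
labelled libraries. Records are assembled from a fragment grammar: a COOH
head plus catalogued bodies — fixed entries (simple aliphatic, benzoic,
heteroaromatic, alicyclic and fused-ring acids), parametric homologue chains
(alkyl, ω-hydroxy/amino/methoxy/chloro), and 3-X-4-Y-disubstituted
benzoic/phenylacetic combinatorics — yielding ~130 distinct property-passing
chemotypes plus dedicated fail, alert-spike, di-acid and salt entries.

Every catalogue entry carries descriptor labels annotated *by hand* from the
package's stated conventions (or composed by closed-form increments for the
parametric families); the generator never calls the descriptor or curation
code. The test suite recomputes every label through `chem_core`/`curation`
and requires exact agreement — a dual-route check that keeps both sides
honest. Candidate pool entries are rejection-filtered against the default
criteria at module load, so the pass pool is pass-only by construction.

Contracts: exactly n records; spike counts are exact
(`round(rate × n)` each); `fraction_property_pass` is the share of the whole
library passing the default thresholds (spiked motifs are built passing and
count toward it); infeasible rate combinations raise. Defaults emulate the
emulated funnel's shape: 17.5% property pass, 0.3% per alert, 1% salts,
0.5% di-acids. Salt records carry no descriptor labels (they are rejected
before descriptors apply).

What the generator does **not** emulate: the real catalogue's chemical
distribution and scale (34k+ records are supported, not default), tautomers,
stereochemistry, and — because the distinct-chemotype pool is finite —
large libraries contain exact duplicates, which real catalogues rarely do.
Duplicates are handled explicitly by the clustering contract (medoids anchor
their own clusters), and a consequence visible in the worked example is that
duplicate di-acids can found several clusters and surface as enumeration
rejects. Passing tests on synthetic data therefore demonstrate the
*machinery* (counts, conservation, determinism, label agreement), not
real-catalogue survivor rates, which also depended on manual curation calls
that cannot be reconstructed.

## Pipeline and seeds (`pipeline`, `cli`)

One root seed fans out as
`numpy.random.SeedSequence(root).generate_state(3) mod 2**31` to the
synthetic-library, clustering, and representative-selection stages, in that
order, so stages can be rerun independently from the manifest. All artifacts
are plain text without timestamps; rerunning a manifest reproduces them
byte-identically, which is tested. The CLI (`esterfunnel
simulate|filter|cluster|pick|enumerate|rank|run`) is a thin layer over the
library; exit codes are 0/1/2 for ok/user error/internal error.

## Problem sizes

The shipped analyses and tests run at desk scale, chosen to exercise every
contract while keeping the suite fast: 4000-record libraries in the analysis
drivers, 500 for funnel-agreement checks, 1000 fingerprints with k = 285 for
the diversity cascade, 10^4 random triples for the metric property, and
100 permutations × 20 molecules for renumbering invariance. All scale
linearly (clustering is O(nk) distance evaluations on packed bit matrices).

## Known limitations

- Absolute survivor counts of the original commercial-catalogue funnel are
  not reproducible even in principle (proprietary data, undocumented
  descriptor definitions in the original software, manual curation); the
  package treats them as structural anchors only.
- The fingerprint's class SMARTS are deliberately simple, documented rules;
  they are not a validated pharmacophore model.
- pKa/ionization is not modelled; the negatively-ionizable class and the
  COOH validity check use neutral-form patterns.
- Esterification handles exactly one transform (3-O-acylation); protecting
  groups, competing nucleophiles and yields are out of scope.
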