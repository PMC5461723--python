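# Methods

This note documents the models, conventions and numerical choices behind
`sulfopan`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinates and records

All public coordinates are 1-based inclusive (GFF3 convention); strand is
`+`/`-`. Protein sequences use the 20 standard residues plus `X`; a single
terminal `*` is stripped on input. `X` scores 0 against every residue, so
ambiguous positions neither reward nor penalise an alignment. Protein
lengths always come from the sequences themselves, never from optional
columns of a hit table — the dual-coverage filter needs authoritative
denominators.

## Pairwise alignment and E-values

The native aligner is an exact Smith–Waterman with affine gaps
(BLOSUM62; gap of length L costs `open + L·extend` with open 11, extend 1).
Scores convert to bits as `bit = (λ·raw − ln K)/ln 2` with the standard
gapped-BLOSUM62 constants λ = 0.267, K = 0.041, and
`E = m·n·2^(−bit)` over the plain m×n residue search space, without
edge-effect or compositional corrections. This E-value scale is consistent
and documented, not engine-parity: the pipeline's 10⁻²⁰ cut-off is so far
from the noise floor that the uncorrected scale classifies matches
identically in practice.

Coverage of each sequence is the number of its residues inside the local
alignment (gap columns excluded) divided by its full length. Percent
identity and percent similarity (positive-scoring columns) are both
computed over all alignment columns and reported side by side, since
comparative figures conventionally quote one or the other.

Ties between co-optimal alignments are broken deterministically: highest
score, then the end cell with the smallest (query end, subject end), then a
fixed state-preference order during traceback (substitution before gap in
subject before gap in query). Determinism, not a canonical "best" shape, is
the goal; co-optimal alternatives score identically by construction. One
consequence: for unrelated sequences with several co-optimal noise
alignments, the alignment chosen for (a, b) need not be the transpose of
the one chosen for (b, a) — scores are always symmetric, coverage fractions
swap whenever the optimum is unique (the biologically relevant case).

Three backends emit identical hit records: the native aligner, NCBI BLAST+
(`blastp` with the extra `ppos` column so percent similarity is populated),
and the importer for any 12-column tabular hit file. The native aligner is
O(mn) per pair in Python (≈ 50–100 ms for two 400-residue proteins), so
datasets beyond a few hundred proteins should use the BLAST+ backend; the
match filter downstream is identical either way. Imported 12-column tables
lack a positives column, so percent similarity is NaN for that route.

## Pan-proteome partitioning

A hit passes the match criterion when `E < max_evalue` (default 10⁻²⁰) and
both coverage fractions are ≥ `min_coverage_both` (default 0.65); self-hits
are excluded. The filter is monotone in both thresholds.

Presence of a focal protein in another genome means at least one filtered
hit in either search direction; paralogous multiplicity collapses to one
presence bit (multiplicity stays available in the hit table). Prevalence
counts the focal genome itself, so "present in all genomes" is prevalence
N. The category bands for prevalence p are:

| category  | band                        | default, N = 14 |
|-----------|-----------------------------|-----------------|
| unique    | p = 1                       | 1               |
| rare      | 2 ≤ p < softcore_min        | 2–8             |
| soft-core | softcore_min ≤ p < N        | 9–13            |
| core      | p = N                       | 14              |

`softcore_min` defaults to ⌈9N/14⌉. A prevalence exactly at the soft-core
threshold is soft-core, which makes the "extended core" (core + soft-core)
well defined; the boundary is configurable.

Pairwise sharing is directional: the count of A's proteins with a filtered
hit in B over A's proteome size, and vice versa. The two directions differ
in the presence of paralogs and are always reported separately, never
averaged. The sharing network has one node per genome and one edge per pair
with nonzero sharing; the scalar edge weight is the larger directional
count (a drawing convenience), with both counts and both percentages kept
as edge attributes.

Matrix clustering uses complete-linkage agglomeration on Euclidean
distances between the boolean genome columns, with columns pre-sorted
lexicographically so ties break identically across runs. Only the distance
is a scientific commitment; the linkage is a documented fixed choice.

## Cluster synteny

Homologs are reciprocal best hits (RBH) computed per genome pair over the
whole filtered hit table (not restricted to the cluster), then intersected
with the cluster genes; this avoids spurious locally-best matches. Best
hits rank by bit score, then lower E-value, then lexicographic subject id.

"Same genomic region" is operationalised as the largest chain of homologs
on one contig whose consecutive inter-gene gaps are ≤ `max_locus_gap`
(default 10 kb, configurable); a homolog outside that chain is reported as
relocated (`co_located = False`). `order_index` is the homolog's rank by
start coordinate within the chain. Relative strand compares the homolog's
strand to the reference gene's. Mapping a cluster onto its own genome
short-circuits to the exact identity column (100% identity, same strand,
order preserved) rather than relying on self-hits, which the match filter
removes.

## Phylogenetics

Maximum-likelihood tree inference is deliberately out of scope: the
pipeline's congruence statements are topological, so neighbor joining on
corrected distances supports the same Robinson–Foulds comparisons at a
fraction of the cost, and is exact on additive matrices. This is a
stand-in, documented as such, not a parity claim.

- **Progressive alignment**: 3-mer count distances feed a UPGMA guide
  tree; profiles merge by global profile–profile alignment (Gotoh, affine
  gaps, end gaps penalised, expected-score column substitution). With two
  sequences this reduces exactly to pairwise global alignment.
- **Distances**: p-distance with pairwise deletion of gapped columns
  (robust to ragged concatenations with missing slots); Poisson correction
  `−ln(1−p)` with p capped at 0.95 (distance ≈ 3.0) so saturated pairs
  keep NJ defined. A pair with zero comparable columns is an error.
- **Neighbor joining**: standard Q-criterion agglomeration; ties break on
  the lexicographically smallest label pair; negative branch-length
  estimates are clamped to zero with the deficit shifted to the sister
  edge, preserving the path length through the joined pair. On additive
  input the reconstruction reproduces all pairwise distances to machine
  precision.
- **Bootstrap**: columns resampled with replacement; support of an
  internal edge is the fraction of replicate trees containing its
  bipartition, written as a decimal on the node. Reproducible from the
  seed. The conventional production setting is 1000 replicates; tests use
  ~100, which bounds the Monte-Carlo standard error of a support near 0.5
  at about 0.05.
- **Robinson–Foulds**: symmetric difference of internal bipartitions,
  normalised by 2(n−3).
- **Concatenation**: per-taxon ordered homolog slots are concatenated into
  poly-proteins; a missing slot becomes a gap-only placeholder of the
  slot's aligned length (which is why slot members must be pre-aligned
  when any member is missing).

The module also provides simulation helpers for its own validation: random
unrooted topologies by sequential edge splitting with uniform branch
lengths, their additive path-length matrices, and a minimal
Poisson-substitution sequence evolver (per branch of length b, each site
substitutes with probability 1−e^(−b) to a uniform different residue).
These support consistency tests, not realistic sequence evolution.

## Motif scanning

The motif is an input: an IUPAC consensus (converted to a position weight
matrix with probability 1−ε on the allowed bases, ε = 0.01) or an explicit
4×L matrix; scores are log₂-odds against a uniform background (configurable).
The default threshold is 80% of the maximum attainable score.

Offsets follow promoter-table convention: position of the motif's 3'-most
base on the coding strand, with −1 the base immediately before the start
codon, reported negative — a motif "at −46" ends 46 bp upstream. Scanning
is coding-strand only over a `window` (default 300 bp) upstream of the
start codon, reverse-complemented for minus-strand genes. The best-scoring
placement above threshold wins (ties prefer the placement closest to the
start codon); class is `+` if it lies within `proximal_cutoff` (default
150 bp), `?` if above threshold only beyond it, `−` otherwise. The
defaults place typical archaeal proximal sites (tens of bp upstream) in
`+` and clearly distal occurrences (≈ −250 and beyond) in `?`; both knobs
are configurable because the proximal/distal boundary is a judgement call,
not a measured constant. A truncated window at a contig edge is scanned
over the available span and flagged.

## Synthetic data generator

The generator emulates the statistical structure a pan-proteome comparison
measures — not biology. Per family, a random ancestral protein (length
uniform on 200–600 aa by default) is mutated independently per member
genome: substitution sites are Binomial(L, 1−identity), replacements
uniform over the other 19 residues, no indels. Substitution-only
divergence keeps coverage fractions at 1 and makes recovery guarantees
analyzable; an indel option is future work. Unique genes are fresh random
sequences. Soft-core and rare families always include the focal genome so
the focal proteome carries exactly the planted category counts; the
remaining members are sampled uniformly, with prevalence drawn uniformly
from the category's band.

Genes are back-translated with uniform synonymous codons (standard code,
TAA stop) and placed on one contig per genome: each gene block carries its
own promoter spacer (uniform 150–400 bp, auto-extended when a planted
motif needs more room) on the coding-strand-upstream side and a short pad
on the other. Cluster genes are appended contiguously in planted order;
relocated genes move behind a 50 kb neutral gap (far beyond the 10 kb
co-location threshold). Planted motifs are written into the promoter
spacer at the exact construction offset, reverse-complemented for
minus-strand genes. Everything derives from one mandatory seed;
regeneration is byte-identical.

What the simulator does **not** emulate: indels and length variation
within families, paralog expansion, compositional bias, codon usage,
operonic transcription, HGT, or realistic phylogenetic correlation between
family members (members are conditionally independent given the
ancestor). Passing recovery tests therefore demonstrates correctness of
the pipeline's bookkeeping and thresholds under clean conditions, not
robustness to every artefact of real annotations.

Default study conditions (14 genomes; 100 core, 40 soft-core, 60 rare,
30 unique-per-genome families; 85% within-family identity; lengths
200–600 aa) are chosen so that family members are unambiguously detectable
under the default match criterion (pairwise identity between members is
≈ 72%, giving E-values many orders below 10⁻²⁰ at these lengths) while
random cross-family pairs never approach it — so exact category recovery
is the correct expectation, and any miss indicates a pipeline defect.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run: the full 14-genome study
through the BLAST+ backend (~2500 proteins, a few minutes on one CPU);
an 8-genome synteny study with a planted 10-gene cluster, one inversion
and one relocation; 50 random additive 6-taxon matrices for NJ exactness;
100 replicates of 8-taxon protein-vs-marker congruence at low divergence
(300-residue proteins vs a 1200-residue marker); bootstrap determinism at
100 replicates; and a 20-promoter motif screen with 13 proximal plantings
and one distal. These sizes keep a full validation run within minutes
while leaving each check statistically meaningful.

## Known limitations

- The native aligner is exact but slow in Python; genome-scale runs
  depend on BLAST+ being installed.
- E-values use fixed Karlin–Altschul constants; scores from imported hit
  tables are taken at face value, so mixing backends within one run is
  not recommended.
- NJ topology is a distance method: on real, non-additive data it is a
  stand-in for likelihood inference and its bootstrap supports should be
  read accordingly.
- The RBH definition resolves score ties deterministically rather than
  discarding tied pairs; with highly similar paralogs the chosen ortholog
  can be arbitrary (though stable across runs).
- Motif scanning reports the single best placement per promoter; the
  count of additional above-threshold placements is recorded but their
  positions are not.
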