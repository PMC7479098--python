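# Methods

This note documents the models, algorithmic choices and numerical
conventions behind `metataxa`, and what the synthetic benchmark does and
does not establish about real data.

## Sequence identity

One identity definition is used everywhere (clustering, anchor identity,
generator validation): global alignment with match +1, mismatch −1, gap
open −2, gap extension −1; identity = matches / alignment columns with
columns spanned by terminal gaps excluded. The pair is ordered
canonically before alignment so the function is exactly symmetric.

All synthetic sequences within a run are collinear (the generator and the
read error model are substitution-only; indel error models are out of
scope), so on pipeline data the optimal alignment of any pair at
near-threshold divergence is gapless. Clustering and the bimera check
therefore expose an `assume_ungapped` fast path (vectorized Hamming
comparisons) that is decision-equivalent to the aligner near the 98.7%
threshold; the equivalence is asserted in the test suite, and the default
code path for arbitrary (possibly indel-bearing) input is the full
aligner.

## Synthetic reference taxonomy

Sequences evolve from one ancestral ~1,443-nt sequence along the
six-rank taxonomy; each edge applies one round of i.i.d. substitutions at
a per-rank probability (phylum 0.030, class 0.015, order 0.020, family
0.040, genus 0.036, species 0.0225, outgroup 0.12). The rates were derived
analytically — using the per-round Jukes–Cantor eigenvalue 1 − 4r/3 — so
that sibling species land inside the congeneric identity band
(92–98.7%) and genera of one family inside the confamilial band (86–92%),
both straddling the 98.7% species threshold. Band realization is
stochastic; a generated database is validated against the bands and
resampled deterministically (sub-seeded) on a miss, so the constructor
only rejects parameter sets that fail repeatedly.

Planted novel genera branch from the *midpoint of a family's stem edge*
rather than from the crown radiation. A crown-radiating novel genus would
attach at a zero-length polytomy and its rank would be decided by a
tie-break; a stem lineage attaches strictly inside an edge, basal to the
family crown, making "potential new genus" decidable. Planted novel
species are ordinary crown species withheld from the emitted reference
database (at most one per genus, so every genus keeps an anchor).

## Community model

Per sample, each taxon is present with a tier-specific Bernoulli
occupancy (low 0.03, medium 0.35, high 0.9) and, when present, receives a
log-normal weight (σ = 1; log-mean 0 / ln 3 / ln 8 by tier); weights are
normalized to a composition. Two community types are planted:

* each type has one **dominant** taxon — always present in its own type
  with log-mean ln 80 and σ = 0.5 (dominants are consistently high; that
  is what defines a community type), present at occupancy 0.15 and
  log-mean ln 2 in the other type;
* each type has a **guild** of eight taxa boosted in its own type
  (occupancy 1.0 high-tier / 0.6 medium-tier, log-mean +1) and suppressed
  in the other (occupancy 0.1 / 0.05, log-mean −1) — the co-varying
  complexes that accompany enterotype-like structure.

The planted prevalence-tier label of a taxon is the band of its expected
overall prevalence under the type mixture, so typed occupancy and tier
ground truth stay mutually consistent. Guild sizes and boosts were set at
design time so that the planted two-type structure is decisively
recoverable by the compositional layer, as the pipeline's validation
demands; with these settings Ward clustering recovers the types with
adjusted Rand index 1.0 across seeds and silhouettes around 0.4.

Reads are drawn multinomially at a configurable fixed depth (default
2,000/sample) and copy their source with i.i.d. substitutions at 0.159%
per base. Chimeras (off by default) are two-parent splices at a uniform
breakpoint in [300, 1,200].

What the generator does **not** emulate: indels and quality scores, PCR
and primer bias, 16S copy-number variation, intra-species sequence
diversity (one type strain per species), rank-imbalanced real taxonomies,
and continuous (gradient) community variation — planted types are
discrete. Passing the benchmark therefore shows the pipeline's logic is
correct under its stated assumptions, not that it is robust to every
artifact of real amplicon data.

## Reads to OTUs

Quality control drops reads containing non-ACGT symbols, trims to the
1-based positional window (10, 1,490) and bounds post-trim length to
[1,000, 1,600]. Reference sequences are trimmed with the same window so
the entire analysis shares one coordinate system.

The bimera check scans two-parent splits on a 50-nt breakpoint grid
against the (trimmed) reference set and flags a read when the best split
beats its best single-parent identity by ≥ 0.02. Setting the margin to 1
disables it.

Greedy centroid clustering processes unique sequences in decreasing read
multiplicity (ties: lexicographically smaller sequence first); a sequence
joins the first centroid at identity ≥ 0.987 (inclusive comparison — a
config flag switches to strict) or founds a new centroid. OTU
representatives are the highest-multiplicity member sequences, ties again
lexicographic.

## Reference tree and placement

References are aligned progressively (UPGMA guide tree from pairwise
identities; profile–profile Needleman–Wunsch with the same affine costs
as the identity definition). When all references share one length the
reference alignment is the trivial gapless stack. Queries are aligned to
the *finished* reference profile one at a time; query residues that would
require new all-reference-gap columns are dropped and counted — such
columns cannot pass the gappy-column filter and dropping them keeps the
reference coordinate system identical for every query.

The conservational filter keeps a column when its modal residue frequency
among non-gap entries is ≥ 0.30 **and** its non-gap fraction is ≥ 0.5;
the second clause defines conservation for gappy columns, which the
classical 30% filter leaves unspecified. Distances are Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3), computed on masked, mutually non-gap columns;
p ≥ 0.75 raises a saturation error naming the offending pair (never
triggered at the generator's divergence bands).

Neighbor joining is the canonical Saitou–Nei algorithm with ties broken
by the smallest index pair; negative branch lengths are clamped to zero
and the tree is rooted by splitting the outgroup's pendant edge. The
implementation reconstructs additive matrices exactly and is
cross-checked against an independent implementation in the tests. A
`max_nj_taxa` guard warns on large inputs; at the package's desk scale
(tens to a few hundred taxa) the full O(n³) join is run directly rather
than subdividing the tree into clade-wise subproblems.

Each query is inserted on the edge minimizing the least-squares added
distance to all current leaves (attachment position and pendant length
solved in closed form with box constraints), in decreasing OTU size;
earlier insertions are visible to later ones. Insertion records enough
state that removing a query restores the previous tree byte-for-byte.

## OPU delineation and categorization

The smallest anchored clade of a query is the minimal ancestor containing
at least one reference leaf. Queries belong to one OPU exactly when their
smallest anchored clades contain the **same set of reference leaves**:
clades that coincide, or nest around the same references (two OTUs
stacked on one type strain's terminal edge), merge; clades anchored to
different or larger reference sets stay separate. This reference-set rule
is the package's formalization of the manual tree-inspection step of
classical OPU work; it is validated against brute-force clade enumeration
on random trees.

Categories, evaluated on reference leaves only (query leaves never vote):

1. anchor is a type strain and identity > 0.987 (strict) → classified
   species, with the anchor's full lineage;
2. else, all clade references share one genus → potential new species in
   that genus;
3. else → potential new taxon; the new rank is one below the lowest rank
   at which all clade references agree, and the assigned lineage is
   resolved to that agreeing rank.

The anchor is the clade's maximum-identity type strain when one is
present, otherwise its maximum-identity reference. OPUs are SLPs; the
SLP × sample table counts every retained read exactly once (enforced).

## Prevalence and roles

Presence is count ≥ 1 by default (`min_count` configurable). Strata:
low < 10%, 10% ≤ medium ≤ 60%, high > 60% — the 60% boundary is medium.
Group-level relative abundances are reported both pooled across all reads
and as means of per-sample percentages, since the two summaries differ
whenever depth varies. Role annotation matches classified SLPs by exact
species name; unknown names in a role list warn rather than fail.

## Compositional statistics

Zeros are replaced per sample by δ = 0.65/total on the proportion scale
(a standard count-zero-multiplicative choice), with non-zero proportions
multiplicatively shrunk so rows still sum to one. CLR is ln x minus the
row mean of ln x; the Aitchison distance is Euclidean on CLR rows.

Sample typing uses Ward linkage in the ward.D2 convention (squared
distances inside the Lance–Williams update, heights on the distance
scale; verified against R's `hclust(method="ward.D2")`), cut at k = 2 by
default, with silhouettes from the same distance matrix (defined as 0 in
the degenerate all-singleton case). PCoA is classical metric scaling; on
Aitchison distances it reproduces CLR PCA scores up to sign, and negative
eigenvalue mass beyond 5% raises a warning.

perMANOVA uses the between/within sums-of-squared-distances pseudo-F,
seeded label permutations, and the +1-corrected p-value
(1 + #{F\* ≥ F}) / (1 + n\_perm); with several factors the p-values are
BH-adjusted as one family. Under label-free nulls its measured type-I
error at α = 0.05 is ≈ 0.04–0.06.

Differential abundance draws 256 Dirichlet(counts + ½) posterior
compositions per sample, CLR-transforms each instance, and runs Welch's t
and the Wilcoxon rank-sum test per SLP and instance; p-values are
averaged over instances and BH-adjusted per test family. The effect size
is the median over instances of (median CLR difference between groups) /
(the larger within-group IQR), reported as second minus first group in
sorted label order. An SLP is flagged when both adjusted p-values are
below 0.05 or |effect| ≥ 1 (the two-test agreement mirrors how such
results are usually reported). Instance-averaged p-values are mildly
conservative when posterior jitter is comparable to between-sample
variation; under the package's null model (one base composition,
per-sample log-normal σ = 1 biological noise, multinomial depth 2,000)
the measured per-test type-I error is ≈ 0.035.

Proportionality is ρ(x, y) = 1 − var(x − y)/(var x + var y) on CLR
columns; zero-variance SLPs yield missing values. ρ can be computed from
point CLR values or from the Dirichlet-expected CLR matrix — both are
exposed, since "expected ρ" is ambiguous in common usage; the network
layer accepts either. Edges require ρ > 0.3 or < −0.3; modules come from
greedy modularity maximization on |ρ| weights and Q is reported for the
non-isolated subgraph.

## Problem sizes and numerical conventions

The validation benchmark runs 40 samples at depth 2,000 over a 72-species
reference taxonomy (two phyla, four families, twelve genera) with 10
withheld novel species, 4 stem-genus novel genera and one outgroup;
calibration simulations use 1,000 replicates with 20 samples (perMANOVA)
or 10 + 10 samples × 20 SLPs (differential abundance). These sizes keep
the complete suite and the reproduction script to a few minutes on one
CPU while leaving every recovery margin wide.

All stochastic operations take explicit integer seeds; pipeline stages
derive independent sub-seeds from one master seed. Deterministic
tie-breaks are documented at each operation (lexicographic sequences,
smallest index pairs, first preorder edge). Floating-point guards: an
ε = 10⁻¹² tolerance at the inclusive clustering threshold, branch-length
clamping at zero, and a 10⁻¹² preference margin in least-squares edge
selection.

## Known limitations

* Identity-based anchoring assumes one 16S per species and no
  intra-species variation; real type-strain databases violate both.
* The bimera check is reference-based and misses chimeras of two unknown
  parents.
* Placement inserts queries greedily; a joint (re-optimizing) placement
  could differ on pathological trees.
* The discrete two-type community model cannot say how the typing layer
  behaves on gradient-like cohorts, where silhouettes are far lower.
* Dirichlet-MC p-values inherit the conservatism discussed above; effect
  sizes are the more stable quantity, as their reliance on them here
  reflects.
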