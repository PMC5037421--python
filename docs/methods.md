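# Methods

## Model and pipeline

`lcsalign` aligns a set of k protein sequences in four stages.

**Stage I — pairwise similarities.**  For each pair the longest common
subsequence (LCS) length is computed; the indel distance
|A| + |B| − 2·LCS is the number of gaps in a match-only alignment of the
pair, and dist = indel/LCS is the dissimilarity used downstream.  Two
degenerate cases need conventions: identical sequences get dist 0, and
disjoint pairs (LCS 0) get the finite sentinel |A| + |B| + 1, which is
strictly larger than any attainable distance and keeps the clustering
total order well defined.  The production LCS routine is bit-parallel
(the Allison–Dix/Crochemore word recurrence
V′ = (V + (V & M)) | (V & ~M) over 64-bit words with explicit carry
propagation); a textbook DP implementation is kept in the package as its
reference oracle and both are asserted equal on large random batches.

**Stage II — guide tree.**  Single linkage via the SLINK pointer
representation is the default: distance rows are consumed one at a time
and immediately discarded, so peak memory beyond the current row is O(k).
The pointer representation (π, λ) is converted to a binary dendrogram by
processing objects in ascending (λ, index) order; exact ties therefore
break toward the smaller sequence index, and the child with the smaller
minimum leaf index goes left.  Both choices are arbitrary but fixed, which
makes every run reproducible.  UPGMA (O(k²) memory, for comparison),
chained/caterpillar trees and Newick import are also provided.  Only the
merge order of a tree is consumed by stage III; heights are retained for
inspection.  Branch lengths of imported trees are ignored for the same
reason, and multifurcations are rejected rather than resolved silently.

**Stage III — progressive profile merging.**  A profile stores its rows in
a gapped representation: the residue codes (terminated by a guard code),
the count of gaps immediately before each residue (the guard slot counts
trailing gaps), and a heap-ordered prefix-sum tree over the per-slot
column weights 1 + no_gaps[j].  The tree is sized to the next power of two
of the slot count, with each leaf covering two slots; its root equals the
realized width, and residue↔column queries descend it in O(log n).
Per-column occurrence counters over 32 slots (25 residue codes — the 20
standard amino acids plus B, Z, X, U, O — and the four gap-type codes)
summarize the profile; unknown input letters map to X with a warning.

Profile pairs are aligned by a three-state affine DP over columns,
maximizing the summed cross-pair score.  Match scores come from one
matrix product of the two counter tables through the 32×32 pair-score
table; inserting a gap column into X against Y's column j costs
k₁ · (residues in Y's column j) · penalty.  Gap columns in the first/last
DP row or column band are priced with terminal penalties, others with
internal ones.  Direct transitions between the two insertion states are
allowed, because gap-type correction (below) can make a double gap column
profitable, unlike in the classic affine model.  Specialized
sequence–sequence and profile–sequence variants skip the counter algebra
but share the DP kernel, so their results are bit-identical to the
general routine.

**Gap typing and correction.**  Four gap types exist: terminal open/
extension (T_o, T_e) for runs touching either end of a row, internal
open/extension (G_o, G_e) otherwise; the first (leftmost) gap of every
maximal run is the open.  When a gap column is inserted, six situations
decide the inserted type and a possible retype of the neighboring gap:
an open immediately to the right hands its open status to the inserted
gap (terminal S1, internal S4 — this prevents two opens in a row); a gap
on the left makes the insertion an extension of that run (terminal S2/S6,
internal S3); otherwise the insertion opens a new run, terminal at either
row end, internal between residues (S5).  Because typing is fully
determined by run structure, column counters can always be recomputed
from scratch, and the incremental updates are tested against that
recount after arbitrary insertion sequences.

Correction breaks the DP's optimality assumptions, so the reported score
of every merge is recomputed as the model score of the realized merged
profile; a counter logs how often it differs from the DP's internal
value.  The model score of an alignment is the sum over unordered row
pairs and columns: matrix score for residue pairs, the typed (scaled)
penalty for residue-vs-gap, zero for gap-vs-gap.

**Penalty scaling.**  All four penalties are multiplied by
scaler(k) = 1 for k ≤ g_l, else 1 + log₂(k/g_l)/g_d, with g_l = 45 and
g_d = 7.  The constants and the intent (suppressing the widening of very
large alignments) are fixed; the closed form of the growth term is this
package's choice — it is continuous at g_l, non-decreasing, and
configurable (`-gsl`, `-gsd`).  Default magnitudes G_o = −14.85,
G_e = −1.25, T_o = T_e = −0.66 (substitution-matrix units) are tunables
exposed on the CLI (`-go`, `-ge`, `-tgo`, `-tge`), chosen so that
extensions never cost more than opens and terminal gaps stay cheap.

**Stage IV — refinement.**  Up to 100 proposals (configurable): pick a
gap-containing column uniformly at random, split rows by gap presence in
it, drop columns that became all-gap within each part, realign the two
parts, and accept only a strictly higher model score (strictness prevents
cycling through equal-score states).  Iterations count proposals, not
acceptances.  The stage is gated to k ≤ 1000 in auto mode; the seeded
generator (default seed 0) makes default runs reproducible, and different
seeds may legitimately produce different (never worse-scoring) output.

## Substitution matrix

The builtin matrix is MIQS, transcribed as a 20×20 block; scores for
B, Z, X, U, O are filled by averaging the corresponding standard residues
(B = mean of N and D, Z = mean of Q and E, U = C, O = K, X = mean over
all twenty), rounded to one decimal.  Scores are used raw (floating
point, no integer rescaling).  User matrices load from NCBI/EMBOSS-style
text tables; asymmetry is a hard error, and a diagonal that fails to
dominate only logs a warning since nothing in the model requires it.

## Synthetic families

The generator emulates a star phylogeny: one random ancestor over the 20
standard residues, k independent descendants with per-site substitutions
(uniform over the 19 alternatives) and geometric-length insertions/
deletions (capped, default 5).  Because the indel history is known, the
true multiple alignment comes with the family; insertions in different
descendants are not homologous and occupy separate column blocks.  What
this deliberately leaves out: rate heterogeneity across sites,
substitution preferences (no matrix bias in generation), and tree-shaped
descent (an optional chained mode exercises harder cases in tests).
Passing the recovery tests therefore shows the pipeline reassembles a
known homology under idealized divergence — it says nothing about
structurally constrained real families, which is what the SP/TC scoring
against external references is for.

## Numerical and design notes

- Ties in the DP break in the fixed order MATCH > GAP_IN_Y > GAP_IN_X
  (and open-from-match over open-from-the-other-gap-state), making every
  alignment deterministic for fixed inputs.
- Distance ties in clustering break toward the smaller pair index.
- Results are independent of the worker count: `-t` only partitions the
  j-range of each distance row; assembly is order-preserving.
- Column indices are 0-based; insertion "at column c" means before the
  column currently at c; intervals are half-open.
- The guard slot participates in the prefix-sum tree with weight equal to
  the trailing-gap count, so the root always equals the realized width.
- All-gap rows and all-gap alignment columns are invalid inputs/outputs
  and are rejected at construction.
- Scores are float64 throughout; DP equality checks in tests use exact
  comparison where both sides perform identical arithmetic and a 1e-6
  relative band where a recomputation path differs.

## Problem sizes in the test and acceptance runs

The suite exercises sequences up to length 300 (LCS), distance matrices
up to k = 100 (linkage oracles), profile DPs up to a few hundred columns,
and full pipelines on families of 5–20 sequences with 40–120-residue
ancestors; the acceptance script runs five 15-sequence families of
ancestor length 120, 1000 LCS oracle pairs and 300 Gotoh oracle pairs.
These sizes were chosen so a complete run stays in the tens of seconds
while every code path — word-boundary LCS cases, terminal and internal
gap runs, retyping during merges, refinement acceptance — is reached.

## Known limitations

- The progressive stage is serial; only stage I distance rows use the
  worker pool.  Parallel merging of independent subtrees would preserve
  results but is not implemented.
- Gap correction makes the DP a heuristic: the reported (realized) score
  can fall below the DP's internal bound, and no optimality guarantee
  survives correction — by design, matching the method being modeled.
- Nucleotide input, FASTQ and compressed files are out of scope.
- The SLINK conversion assumes distinct-or-tied heights resolve by leaf
  index; other tie conventions yield topologically different but
  equally valid single-linkage trees.
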