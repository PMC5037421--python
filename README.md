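# lcsalign

Progressive multiple sequence alignment for protein families, built for the
regime where families hold thousands of members and quadratic-memory
aligners stop being practical.  The design combines four ideas:

1. **LCS similarities.**  The pairwise similarity of sequences *A* and *B*
   is the length of their longest common subsequence normalized by the
   indel distance,

   sim(A, B) = LCS(A, B) / (|A| + |B| − 2·LCS(A, B)),

   computed bit-parallel: 64 cells of the implicit DP matrix per machine
   word, so a pair costs ⌈min(|A|,|B|)/64⌉ words per row.  Clustering
   consumes the monotone inverse dist = indel/LCS.

2. **Incremental single-linkage guide tree.**  The SLINK pointer
   representation consumes distance rows as they are produced, so stages I
   and II together need only O(k) memory beyond the current row.  UPGMA,
   caterpillar (chained) trees and imported Newick trees are available as
   alternatives, with the Sackin index and reference-coverage statistics
   for comparing their shapes.

3. **Gapped profiles with a four-type affine gap model.**  An aligned row
   is stored without gap characters: residue codes plus a per-residue gap
   counter and a heap-ordered prefix-sum tree ("dynamic position
   statistics") that maps residues to columns in O(log n).  Inserting a
   gap column touches one counter and one tree path per member — rows are
   moved into merged profiles, never copied.  Gaps are priced by an affine
   model with distinct terminal penalties (T_o, T_e) and internal
   penalties (G_o, G_e); inserted gaps and their neighbors are re-typed by
   six correction rules so open penalties are not overcounted, and all
   four penalties scale with family size by
   1 + log₂(k/g_l)/g_d for k > g_l (defaults g_l = 45, g_d = 7).

4. **Column-oriented iterative refinement.**  A random gap-containing
   column splits the alignment into two subprofiles, which are realigned;
   the proposal is kept only if the sum-of-pairs model score strictly
   improves (100 proposals by default, gated to k ≤ 1000).

## Worked example

```bash
lcsalign simulate fam.fa --truth truth.fa -k 12 --root-len 100 \
    --sub-rate 0.08 --indel-rate 0.02 -seed 42
lcsalign -v align fam.fa aligned.fa -gt-export tree.nwk
lcsalign score --ref truth.fa aligned.fa
```

prints

```
INFO lcsalign.pipeline: guide tree built in 0.00s
INFO lcsalign.pipeline: progressive stage done in 1.34s (width 120)
INFO lcsalign.pipeline: refinement done in 0.38s (2 accepted proposals)
INFO lcsalign: wrote aligned.fa (k=12, width=120)
SP	TC
0.980071	0.821138
```

The simulated family of 12 sequences diverged from a 100-residue ancestor
(8% substitutions, 2% indel events per site).  The aligner recovers 98.0%
of the truly homologous residue pairs (SP) and reproduces 82.1% of the
true columns exactly (TC).  Refinement accepted two of its proposals, each
strictly raising the sum-of-pairs model score.  Tree-shape statistics for
the same family:

```
$ lcsalign tree-stats fam.fa --refs seq0000,seq0003 --mc-trials 200
k	12
sackin_raw	77
sackin_normalized	6.416666666666667
covering_fraction	0.6666666666666666
mc_covering_fraction	0.7116666666666666
```

The single-linkage tree is strongly imbalanced (normalized Sackin 6.42
against 3.58 for a perfectly balanced tree of 12 leaves), and the two
chosen reference sequences sit in a smaller subtree (0.67) than random
pairs do on average (0.71).

The same pipeline is available as a library:

```python
from lcsalign import align_sequences, read_fasta
result = align_sequences(read_fasta("fam.fa"))
result.alignment.rows  # aligned rows, input order
```

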