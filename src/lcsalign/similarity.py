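"""Stage I: LCS-based pairwise similarities and the distance-row stream.

The similarity of two sequences A and B is the length of their longest
common subsequence (the maximal number of perfectly matching columns),
normalized by the indel distance |A| + |B| - 2*LCS, i.e. the number of gaps
in a match-only alignment.  Clustering consumes the monotone inverse,
dist = indel / LCS.

Two LCS routines are provided: a plain dynamic-programming reference and a
bit-parallel variant that evaluates w = 64 DP cells per machine word.  The
bit-parallel recurrence maintains, per DP column, a bit vector V whose zero
bits mark the rows where the LCS counter has incremented:

    U  = V & M[c]                (match positions for symbol c)
    V' = (V + U) | (V & ~M[c])   (carry ripples through runs of ones)

with V initialized to all ones over min(|A|, |B|) bits; the LCS length is
the number of zero bits at the end.  Addition carries are propagated across
64-bit words explicitly, so ceil(min(|A|,|B|)/64) words are processed per
row of the implicit DP matrix.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from lcsalign._kernels import lcs_dp_matrix
from lcsalign.alphabet import N_RESIDUES
from lcsalign.seqio import Sequence, SequenceSet

WORD_SIZE = 64
_WORD_MASK = (1 << WORD_SIZE) - 1


@dataclass
class PairStats:
    """LCS length, indel distance, similarity and distance of one pair."""

    lcs: int
    indel: int
    sim: float
    dist: float


def lcs_dp(a: Sequence, b: Sequence) -> int:
    """LCS length by the textbook DP rule; oracle for the bit-parallel path."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("sequences must be nonempty")
    return int(lcs_dp_matrix(a.codes.astype(np.int64), b.codes.astype(np.int64)))


def _match_masks(codes: np.ndarray, nwords: int) -> list[list[int]]:
    """Per-symbol bit masks over the sequence positions, split into 64-bit
    words (word t covers positions [64t, 64t+64))."""
    masks = [[0] * nwords for _ in range(N_RESIDUES)]
    for pos, c in enumerate(codes):
        masks[int(c)][pos >> 6] |= 1 << (pos & 63)
    return masks


def lcs_bitparallel(a: Sequence, b: Sequence) -> int:
    """Bit-parallel LCS length; identical to :func:`lcs_dp` on every input."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("sequences must be nonempty")
    # build bit vectors over the shorter sequence
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    m = len(short)
    nwords = (m + WORD_SIZE - 1) // WORD_SIZE
    masks = _match_masks(short.codes, nwords)
    # V starts as all ones over m bits (padded bits in the top word stay 1
    # and never receive a match, so they remain ones)
    V = [_WORD_MASK] * nwords
    for c in long_.codes:
        mask_c = masks[int(c)]
        carry = 0
        for t in range(nwords):
            v = V[t]
            u = v & mask_c[t]
            s = v + u + carry
            carry = s >> WORD_SIZE
            V[t] = (s & _WORD_MASK) | (v & ~mask_c[t] & _WORD_MASK)
    zeros = 0
    for t in range(nwords):
        hi = min(WORD_SIZE, m - t * WORD_SIZE)
        word = V[t]
        for bit in range(hi):
            if not (word >> bit) & 1:
                zeros += 1
    return zeros


def pair_stats(a: Sequence, b: Sequence, lcs: int | None = None) -> PairStats:
    """Fill LCS, indel distance, similarity and distance for one pair.

    Degenerate cases: identical sequences (indel 0) get dist 0 and an
    infinite similarity; disjoint sequences (LCS 0) get sim 0 and the finite
    sentinel distance |A| + |B| + 1, larger than any attainable value.
    """
    if lcs is None:
        lcs = lcs_bitparallel(a, b)
    indel = len(a) + len(b) - 2 * lcs
    if indel == 0:
        return PairStats(lcs, 0, math.inf, 0.0)
    if lcs == 0:
        return PairStats(lcs, indel, 0.0, float(len(a) + len(b) + 1))
    return PairStats(lcs, indel, lcs / indel, indel / lcs)


def _distance_row(seqs: list[Sequence], i: int, threads: int = 1) -> np.ndarray:
    row = np.empty(i, dtype=np.float64)
    if threads <= 1 or i < 8:
        for j in range(i):
            row[j] = pair_stats(seqs[i], seqs[j]).dist
        return row
    chunks = np.array_split(np.arange(i), threads)
    def work(idx):
        return [(int(j), pair_stats(seqs[i], seqs[j]).dist) for j in idx]
    with ThreadPoolExecutor(max_workers=threads) as ex:
        for part in ex.map(work, chunks):
            for j, d in part:
                row[j] = d
    return row


def distance_rows(seqset: SequenceSet, threads: int = 1) -> Iterator[np.ndarray]:
    """Yield distance rows d(i, j) for j < i, one row at a time.

    The consumer (SLINK) holds only the current row, so peak memory stays
    O(k).  Values are deterministic and independent of ``threads``; the
    worker pool only partitions the j-range of each row.
    """
    if seqset.k < 2:
        raise ValueError("need at least 2 sequences")
    seqs = seqset.sequences
    for i in range(seqset.k):
        yield _distance_row(seqs, i, threads)


def full_distance_matrix(seqset: SequenceSet, threads: int = 1) -> np.ndarray:
    """Materialize the symmetric k x k distance matrix (small k only)."""
    k = seqset.k
    if k > 5000:
        raise ValueError("refusing to materialize a matrix for k > 5000")
    d = np.zeros((k, k))
    for i, row in enumerate(distance_rows(seqset, threads)):
        d[i, :i] = row
        d[:i, i] = row
    return d
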