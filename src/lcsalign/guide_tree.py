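"""Stage II: guide trees — SLINK, UPGMA, chained, Newick, balance statistics.

The progressive stage only consumes the merge order, so heights are kept for
inspection but carry no weight downstream.  SLINK is the default: it
consumes the distance rows incrementally through the classic pointer
representation (pi, lambda), so peak memory beyond the current row is O(k).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence as TypingSequence, Union

import numpy as np
from Bio import Phylo

from lcsalign.seqio import SequenceSet


@dataclass
class GuideTree:
    """A rooted binary tree over sequence indices 0..k-1.

    Nodes 0..k-1 are leaves; nodes k..2k-2 are internal merges in creation
    order; the root is node 2k-2.  ``left``/``right`` are -1 for leaves.
    """

    k: int
    left: np.ndarray
    right: np.ndarray
    height: np.ndarray

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=np.int64)
        self.right = np.asarray(self.right, dtype=np.int64)
        self.height = np.asarray(self.height, dtype=np.float64)
        n = 2 * self.k - 1
        if not (len(self.left) == len(self.right) == len(self.height) == n):
            raise ValueError("tree arrays must have 2k-1 entries")

    @property
    def root(self) -> int:
        return 2 * self.k - 2

    def is_leaf(self, node: int) -> bool:
        return node < self.k

    def postorder(self) -> Iterator[int]:
        """Iterative post-order traversal (children before parents)."""
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if self.is_leaf(node):
                yield node
                continue
            if expanded:
                yield node
            else:
                stack.append((node, True))
                stack.append((int(self.right[node]), False))
                stack.append((int(self.left[node]), False))

    def merges(self) -> Iterator[tuple[int, int, int]]:
        """Yield (node, left, right) for internal nodes in post-order."""
        for node in self.postorder():
            if not self.is_leaf(node):
                yield node, int(self.left[node]), int(self.right[node])

    def leaves_under(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if self.is_leaf(n):
                out.append(n)
            else:
                stack.append(int(self.right[n]))
                stack.append(int(self.left[n]))
        return sorted(out)

    def leaf_depths(self) -> np.ndarray:
        """Depth of every leaf (root at depth 0)."""
        depths = np.zeros(2 * self.k - 1, dtype=np.int64)
        order = list(self.postorder())[::-1]  # parents before children
        for node in order:
            if not self.is_leaf(node):
                depths[self.left[node]] = depths[node] + 1
                depths[self.right[node]] = depths[node] + 1
        return depths[: self.k]


def _tree_from_merge_list(
    k: int, merge_list: list[tuple[int, int, float]]
) -> GuideTree:
    """Build the array representation from (cluster_a, cluster_b, height)
    merges over current cluster roots, ordered by merge time.  Child order
    is normalized so the cluster holding the smaller minimum leaf index goes
    left (determinism)."""
    n = 2 * k - 1
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    height = np.zeros(n, dtype=np.float64)
    min_leaf = {i: i for i in range(k)}
    nxt = k
    for a, b, h in merge_list:
        if min_leaf[a] > min_leaf[b]:
            a, b = b, a
        left[nxt], right[nxt], height[nxt] = a, b, h
        min_leaf[nxt] = min(min_leaf[a], min_leaf[b])
        nxt += 1
    if nxt != n:
        raise ValueError("merge list does not produce a full binary tree")
    return GuideTree(k, left, right, height)


def slink_tree(rows: Iterable[np.ndarray], k: int) -> GuideTree:
    """Single-linkage dendrogram from a stream of distance rows.

    Implements the pointer-representation algorithm: arrays pi (pointer to
    the next larger object in the cluster hierarchy) and lam (the merge
    height at which the pointer applies) are updated in O(i) per row, with
    only the current row held in memory.  The pointer representation is then
    converted to a binary dendrogram by processing objects in ascending
    (lambda, index) order, so exact ties break toward the smaller sequence
    index.
    """
    if k < 2:
        raise ValueError("need at least 2 sequences")
    pi = np.zeros(k, dtype=np.int64)
    lam = np.full(k, math.inf)
    M = np.empty(k)
    it = iter(rows)
    for i in range(k):
        row = np.asarray(next(it), dtype=np.float64)
        if len(row) != i:
            raise ValueError(f"row {i} has length {len(row)}, expected {i}")
        pi[i] = i
        lam[i] = math.inf
        M[:i] = row
        for j in range(i):
            if lam[j] >= M[j]:
                if M[pi[j]] > lam[j]:
                    M[pi[j]] = lam[j]
                lam[j] = M[j]
                pi[j] = i
            else:
                if M[pi[j]] > M[j]:
                    M[pi[j]] = M[j]
        for j in range(i):
            if lam[j] >= lam[pi[j]]:
                pi[j] = i
    # convert pointer representation to a dendrogram
    order = sorted(range(k - 1), key=lambda j: (lam[j], j))
    cluster = list(range(k))  # current cluster root per representative

    def find(x: int) -> int:
        while cluster[x] != x:
            cluster[x] = cluster[cluster[x]]
            x = cluster[x]
        return x

    roots = {i: i for i in range(k)}  # representative -> tree node
    merge_list = []
    for j in order:
        ra, rb = find(j), find(int(pi[j]))
        merge_list.append((roots[ra], roots[rb], float(lam[j])))
        cluster[ra] = rb
        roots[rb] = k + len(merge_list) - 1  # node id of this merge
    return _tree_from_merge_list(k, merge_list)


def upgma_tree(rows: Iterable[np.ndarray], k: int) -> GuideTree:
    """Average-linkage (UPGMA) dendrogram; materializes the full matrix
    (documented O(k^2) space).  Ties break toward smaller cluster indices."""
    if k < 2:
        raise ValueError("need at least 2 sequences")
    d = np.full((k, k), math.inf)
    for i, row in enumerate(rows):
        row = np.asarray(row, dtype=np.float64)
        if len(row) != i:
            raise ValueError(f"row {i} has length {len(row)}, expected {i}")
        d[i, :i] = row
        d[:i, i] = row
    active = list(range(k))
    sizes = {i: 1 for i in range(k)}
    node_of = {i: i for i in range(k)}
    dist = {(min(i, j), max(i, j)): d[i, j] for i in range(k) for j in range(i)}
    merge_list = []
    while len(active) > 1:
        best = min(
            ((dist[(min(a, b), max(a, b))], a, b)
             for ai, a in enumerate(active) for b in active[ai + 1:]),
            key=lambda t: (t[0], min(t[1], t[2]), max(t[1], t[2])),
        )
        h, a, b = best
        merge_list.append((node_of[a], node_of[b], float(h)))
        new = min(a, b)
        other = max(a, b)
        for c in active:
            if c in (a, b):
                continue
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            val = (sizes[a] * dist[key_a] + sizes[b] * dist[key_b]) / (
                sizes[a] + sizes[b]
            )
            dist[(min(new, c), max(new, c))] = val
        sizes[new] = sizes[a] + sizes[b]
        node_of[new] = k + len(merge_list) - 1
        active.remove(other)
    return _tree_from_merge_list(k, merge_list)


def chained_tree(k: int, order: Union[TypingSequence[int], int, None] = None) -> GuideTree:
    """Caterpillar tree ((..((s1,s2),s3)..),sk) over ``order``.

    ``order`` may be an explicit permutation, an RNG seed (int) for a random
    permutation, or None for identity order.  Heights equal merge rank.
    """
    if isinstance(order, (int, np.integer)):
        perm = np.random.default_rng(int(order)).permutation(k)
    elif order is None:
        perm = np.arange(k)
    else:
        perm = np.asarray(order, dtype=np.int64)
        if sorted(perm.tolist()) != list(range(k)):
            raise ValueError("order is not a permutation of 0..k-1")
    n = 2 * k - 1
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    height = np.zeros(n, dtype=np.float64)
    cur = int(perm[0])
    for rank in range(1, k):
        node = k + rank - 1
        left[node], right[node], height[node] = cur, int(perm[rank]), float(rank)
        cur = node
    return GuideTree(k, left, right, height)


# ---------------------------------------------------------------------------
# Newick import/export


def _newick_string(tree: GuideTree, labels: TypingSequence[str]) -> str:
    parts = [""] * (2 * tree.k - 1)
    for node in tree.postorder():
        if tree.is_leaf(node):
            parts[node] = labels[node]
        else:
            parts[node] = f"({parts[tree.left[node]]},{parts[tree.right[node]]})"
    return parts[tree.root] + ";"


def write_newick(
    tree: GuideTree, labels: TypingSequence[str], path: Union[str, Path]
) -> None:
    Path(path).write_text(_newick_string(tree, labels) + "\n")


def parse_newick(
    source: Union[str, Path], labels: TypingSequence[str]
) -> GuideTree:
    """Import a strictly binary Newick tree whose leaf labels are a
    bijection with ``labels`` (sanitized sequence ids).  Branch lengths are
    ignored; only the merge order matters downstream."""
    try:
        is_file = Path(str(source)).exists()
    except OSError:
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    clado = Phylo.read(io.StringIO(text), "newick")
    idx = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    left = np.full(2 * k - 1, -1, dtype=np.int64)
    right = np.full(2 * k - 1, -1, dtype=np.int64)
    height = np.zeros(2 * k - 1, dtype=np.float64)
    counter = [k]
    seen: set[int] = set()

    def build(clade) -> int:
        children = clade.clades
        if not children:
            name = clade.name
            if name is None or name not in idx:
                raise ValueError(f"unknown leaf label {name!r} in Newick tree")
            leaf = idx[name]
            if leaf in seen:
                raise ValueError(f"duplicate leaf label {name!r}")
            seen.add(leaf)
            return leaf
        if len(children) != 2:
            raise ValueError(
                f"non-binary node with {len(children)} children is not supported"
            )
        a = build(children[0])
        b = build(children[1])
        node = counter[0]
        counter[0] += 1
        left[node], right[node] = a, b
        height[node] = float(node - k + 1)
        return node

    root = build(clado.root)
    if len(seen) != k:
        missing = sorted(set(labels) - {labels[i] for i in seen})
        raise ValueError(f"leaf labels missing from Newick tree: {missing}")
    if root != 2 * k - 2:
        raise ValueError("tree does not cover all sequences")
    return GuideTree(k, left, right, height)


# ---------------------------------------------------------------------------
# Tree statistics


def sackin_index(tree: GuideTree) -> tuple[int, float]:
    """Sum of leaf depths (root depth 0) and its k-normalized value."""
    depths = tree.leaf_depths()
    raw = int(depths.sum())
    return raw, raw / tree.k


def covering_fraction(tree: GuideTree, ref_leaves: Iterable[int]) -> float:
    """Leaf count of the smallest subtree containing all reference leaves,
    divided by k."""
    refs = set(int(r) for r in ref_leaves)
    if not refs:
        raise ValueError("empty reference subset")
    if not refs.issubset(range(tree.k)):
        raise ValueError("unknown leaf index in reference subset")
    # descend from the root while a single child still contains all refs
    node = tree.root
    while not tree.is_leaf(node):
        lset = set(tree.leaves_under(int(tree.left[node])))
        if refs.issubset(lset):
            node = int(tree.left[node])
            continue
        rset = set(tree.leaves_under(int(tree.right[node])))
        if refs.issubset(rset):
            node = int(tree.right[node])
            continue
        break
    return len(tree.leaves_under(node)) / tree.k


def mc_covering_fraction(
    tree: GuideTree, m: int, trials: int = 1000, seed: int = 0
) -> float:
    """Mean covering fraction of ``trials`` uniformly random size-m leaf
    subsets (the Monte-Carlo baseline for the reference coverage)."""
    if not (1 <= m <= tree.k):
        raise ValueError("subset size out of range")
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(trials):
        subset = rng.choice(tree.k, size=m, replace=False)
        total += covering_fraction(tree, subset)
    return total / trials


def tree_from_sequences(
    seqset: SequenceSet, method: str = "sl", threads: int = 1, seed: int = 0
) -> GuideTree:
    """Build a guide tree from unaligned sequences by the named method."""
    from lcsalign.similarity import distance_rows

    if method == "sl":
        return slink_tree(distance_rows(seqset, threads), seqset.k)
    if method == "upgma":
        return upgma_tree(distance_rows(seqset, threads), seqset.k)
    if method == "chained":
        return chained_tree(seqset.k, seed)
    raise ValueError(f"unknown guide tree method {method!r}")
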