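"""Synthetic protein families with a known true alignment.

A random ancestral sequence over the 20 standard residues is mutated
independently into k descendants (a star phylogeny): each surviving site
substitutes with probability ``sub_rate``; at each site, with probability
``indel_rate``, an indel event deletes or inserts a geometric-length block
(capped at ``max_indel``).  The indel history induces the true multiple
alignment: insertions in different descendants are not homologous, so each
occupies its own block of columns.  The generator is deterministic per
seed and is the fixture source for every test tier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lcsalign.alphabet import GAP_CHAR, STANDARD_RESIDUES
from lcsalign.seqio import Alignment, Sequence, SequenceSet


@dataclass
class Family:
    sequences: SequenceSet
    truth: Alignment


def _geometric_capped(rng: np.random.Generator, cap: int, p: float = 0.5) -> int:
    return int(min(cap, rng.geometric(p)))


def generate_family(
    k: int = 10,
    root_len: int = 120,
    sub_rate: float = 0.05,
    indel_rate: float = 0.01,
    max_indel: int = 5,
    seed: int = 0,
) -> Family:
    """Generate k descendants of a random ancestor plus the true alignment."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if root_len < 1:
        raise ValueError("root_len must be >= 1")
    if not (0 <= sub_rate <= 1 and 0 <= indel_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(STANDARD_RESIDUES))
    root = rng.integers(0, 20, size=root_len)

    kept = np.zeros((k, root_len), dtype=bool)
    letters = np.empty((k, root_len), dtype="U1")
    inserts: list[list[str]] = []  # per descendant, insertion before site i (and end)
    for d in range(k):
        while True:
            keep = np.ones(root_len, dtype=bool)
            ins = [""] * (root_len + 1)
            i = 0
            while i < root_len:
                if rng.random() < indel_rate:
                    length = _geometric_capped(rng, max_indel)
                    if rng.random() < 0.5:
                        keep[i : i + length] = False
                        i += length
                        continue
                    ins[i] = "".join(rng.choice(aa, size=length))
                i += 1
            if keep.any() or any(ins):
                break  # descendant keeps at least one residue
        subs = rng.random(root_len) < sub_rate
        lets = aa[root].copy()
        for i in np.nonzero(subs)[0]:
            choices = [c for c in STANDARD_RESIDUES if c != lets[i]]
            lets[i] = choices[rng.integers(0, 19)]
        kept[d] = keep
        letters[d] = lets
        inserts.append(ins)

    ids = [f"seq{d:04d}" for d in range(k)]
    truth_rows = ["" for _ in range(k)]
    for site in range(root_len + 1):
        # insertion block: one column set per descendant with an insertion
        for d in range(k):
            block = inserts[d][site]
            if block:
                for dd in range(k):
                    truth_rows[dd] += block if dd == d else GAP_CHAR * len(block)
        if site < root_len:
            col_has_residue = kept[:, site].any()
            if not col_has_residue:
                continue  # deleted in every descendant: no column
            for d in range(k):
                truth_rows[d] += letters[d][site] if kept[d][site] else GAP_CHAR
    seqs = SequenceSet(
        [
            Sequence.from_string(
                ids[d], truth_rows[d].replace(GAP_CHAR, ""), ids[d]
            )
            for d in range(k)
        ]
    )
    return Family(seqs, Alignment(list(ids), truth_rows))
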