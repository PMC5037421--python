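"""Alignment objective (model score) and SP/TC benchmark scores.

The model score is the sum, over all unordered sequence pairs, of the
pairwise score of the realized rows: matched residues score by the
substitution matrix, a residue against a gap scores that gap's (scaled)
typed penalty, and gap-gap columns contribute nothing.  Gap types come from
a from-scratch classification of each row: the first gap of every maximal
run is an open, terminal when the run touches either row end.

With per-column slot counts c over the 32-symbol extended alphabet and the
pair table P, each column contributes (c' P c - sum_s c_s P_ss) / 2, which
counts every unordered pair once.
"""

from __future__ import annotations

import numpy as np

from lcsalign.alphabet import GAP_CHARS, N_SLOTS
from lcsalign.gap_model import GapModel, pair_score_table
from lcsalign.profile import Profile, gapped_from_string
from lcsalign.seqio import Alignment
from lcsalign.substitution import SubstitutionMatrix


def _column_counts(typed: np.ndarray) -> np.ndarray:
    """(width, 32) slot counts from a (k, width) typed-code matrix."""
    width = typed.shape[1]
    counts = np.zeros((width, N_SLOTS), dtype=np.int64)
    cols = np.tile(np.arange(width), typed.shape[0])
    np.add.at(counts, (cols, typed.astype(np.int64).ravel()), 1)
    return counts


def score_from_counts(counts: np.ndarray, table: np.ndarray) -> float:
    """Sum-of-pairs score of an alignment given per-column slot counts."""
    c = counts.astype(np.float64)
    quad = np.einsum("js,st,jt->", c, table, c)
    diag = c @ np.diag(table)
    return float((quad - diag.sum()) / 2.0)


def model_score_typed(typed: np.ndarray, table: np.ndarray) -> float:
    return score_from_counts(_column_counts(typed), table)


def model_score(
    aln: Alignment, matrix: SubstitutionMatrix, model: GapModel
) -> float:
    """Model score of an alignment with from-scratch gap typing."""
    table = pair_score_table(matrix, model)
    typed = np.vstack(
        [gapped_from_string(row).typed_columns() for row in aln.rows]
    )
    return model_score_typed(typed, table)


def profile_score(profile: Profile, table: np.ndarray) -> float:
    """Model score of a profile, straight from its column counters."""
    return score_from_counts(profile.counters, table)


# ---------------------------------------------------------------------------
# SP / TC against a reference alignment


def _residue_columns(rows: list[str]) -> list[np.ndarray]:
    """Per row, the alignment column of each residue (gaps skipped)."""
    out = []
    for row in rows:
        cols = np.array(
            [j for j, ch in enumerate(row) if ch not in GAP_CHARS], dtype=np.int64
        )
        out.append(cols)
    return out


def sp_tc(test: Alignment, ref: Alignment) -> tuple[float, float]:
    """Sum-of-pairs and total-column fractions of ``test`` against ``ref``.

    SP is the fraction of residue pairs co-aligned in the reference that
    share a column in the test alignment; TC the fraction of reference
    columns whose residue content reappears as a single test column (the
    test column must pair the same residues and no others among the shared
    rows).  Reference columns or pairs involving gaps are skipped.
    """
    test_index = {sid: i for i, sid in enumerate(test.ids)}
    missing = [sid for sid in ref.ids if sid not in test_index]
    if missing:
        raise ValueError(f"reference ids missing from test alignment: {missing}")
    rows_t = [test.rows[test_index[sid]] for sid in ref.ids]
    for sid, rt, rr in zip(ref.ids, rows_t, ref.rows):
        st = "".join(ch for ch in rt if ch not in GAP_CHARS)
        sr = "".join(ch for ch in rr if ch not in GAP_CHARS)
        if st != sr:
            raise ValueError(f"residues of {sid!r} differ between test and reference")
    ref_cols = _residue_columns(ref.rows)
    test_cols = _residue_columns(rows_t)
    k = len(ref.rows)
    # map: row, ref column -> test column of the residue shown there
    ref_to_test = []
    for r in range(k):
        m = np.full(ref.width, -1, dtype=np.int64)
        m[ref_cols[r]] = test_cols[r]
        ref_to_test.append(m)
    ref_to_test = np.vstack(ref_to_test)  # (k, ref.width), -1 where gap

    pairs_total = 0
    pairs_hit = 0
    tc_hit = 0
    tc_total = 0
    occupied = ref_to_test >= 0
    # which test columns hold residues of rows NOT in the ref column
    for j in range(ref.width):
        members = np.nonzero(occupied[:, j])[0]
        if len(members) == 0:
            continue  # all-gap reference column: skipped
        tc_total += 1
        tcols = ref_to_test[members, j]
        # SP: unordered pairs sharing a test column
        if len(members) >= 2:
            pairs_total += len(members) * (len(members) - 1) // 2
            _, counts = np.unique(tcols, return_counts=True)
            pairs_hit += int((counts * (counts - 1) // 2).sum())
        # TC: single test column, and no other shared row has a residue there
        if len(np.unique(tcols)) == 1:
            t = int(tcols[0])
            others = np.setdiff1d(np.arange(k), members)
            if all(rows_t[o][t] in GAP_CHARS for o in others):
                tc_hit += 1
    sp = pairs_hit / pairs_total if pairs_total else 1.0
    tc = tc_hit / tc_total if tc_total else 1.0
    return sp, tc
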