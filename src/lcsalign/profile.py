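"""Gapped sequence representation and the in-place profile structure.

An aligned row is stored without gap characters: an array of residue codes
terminated by a guard code, a parallel array counting the gaps immediately
before each symbol (the guard slot counts trailing gaps), and a
heap-ordered prefix-sum tree (the dynamic position statistics, ``dps``)
over the per-slot column weights 1 + no_gaps[j] (the guard weighs only its
gap count).  The dps root equals the profile width, and residue<->column
lookups descend the tree in O(log n).

A profile is a set of gapped sequences plus per-column occurrence counters
over 32 slots: 25 residue codes and the four gap-type codes.  Gap types are
implied by run structure (the first gap of every maximal run is an open,
terminal if the run touches either end of the row), so counters can always
be recomputed from scratch; the incremental updates below keep them exact.

Inserting a gap column is O(log n) per member: only the gap counter and the
dps path are touched, no symbol is copied.  Merging moves member rows into
the output profile, which is what keeps the progressive stage linear in the
number of residues rather than in k times the profile width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence as TypingSequence

import numpy as np

from lcsalign import alphabet
from lcsalign.alphabet import (
    GAP_CHAR,
    GAP_CHARS,
    GAP_GE,
    GAP_GO,
    GAP_TE,
    GAP_TO,
    GAP_TYPES,
    GUARD,
    N_RESIDUES,
    N_SLOTS,
)
from lcsalign.seqio import Sequence

GAP = -1  # sentinel returned by column_to_position for gap columns


def _next_pow2(x: int) -> int:
    p = 1
    while p < x:
        p *= 2
    return p


class GappedSequence:
    """One aligned row stored as symbols + gap counters + dps tree."""

    __slots__ = ("symbols", "no_gaps", "dps", "_nleaves")

    def __init__(self, codes: np.ndarray, no_gaps: np.ndarray):
        n = len(codes)
        if n < 1:
            raise ValueError("a gapped sequence needs at least one residue")
        self.symbols = np.empty(n + 1, dtype=np.int8)
        self.symbols[:n] = codes
        self.symbols[n] = GUARD
        self.no_gaps = np.asarray(no_gaps, dtype=np.int64).copy()
        if len(self.no_gaps) != n + 1:
            raise ValueError("no_gaps must have one slot per symbol plus the guard")
        self._build_dps()

    # -- structure ---------------------------------------------------------

    @property
    def n(self) -> int:
        """Number of residues (guard excluded)."""
        return len(self.symbols) - 1

    @property
    def width(self) -> int:
        return int(self.dps[1])

    def _slot_weight(self, j: int) -> int:
        if j < self.n:
            return 1 + int(self.no_gaps[j])
        if j == self.n:
            return int(self.no_gaps[j])
        return 0

    def _build_dps(self) -> None:
        nslots = self.n + 1
        p = max(2, _next_pow2(nslots))
        self._nleaves = p // 2
        self.dps = np.zeros(p, dtype=np.int64)
        for j in range(nslots):
            self.dps[self._nleaves + j // 2] += self._slot_weight(j)
        for i in range(self._nleaves - 1, 0, -1):
            self.dps[i] = self.dps[2 * i] + self.dps[2 * i + 1]

    def _dps_add(self, slot: int, delta: int) -> None:
        i = self._nleaves + slot // 2
        while i >= 1:
            self.dps[i] += delta
            i //= 2

    def _prefix_weight(self, slot: int) -> int:
        """Sum of slot weights strictly before ``slot`` via the tree."""
        total = 0
        # full leaves before the leaf containing `slot`
        leaf = self._nleaves + slot // 2
        i = leaf
        while i > 1:
            if i % 2 == 1:
                total += int(self.dps[i - 1])
            i //= 2
        if slot % 2 == 1:
            total += self._slot_weight(slot - 1)
        return total

    # -- queries -----------------------------------------------------------

    def locate(self, col: int) -> tuple[int, int]:
        """Map a column to (slot, offset): offset < no_gaps[slot] is a gap
        of the run before the slot's symbol; offset == no_gaps[slot] is the
        symbol itself (never for the guard slot)."""
        if not (0 <= col < self.width):
            raise IndexError(f"column {col} out of range [0, {self.width})")
        c = col
        i = 1
        while i < self._nleaves:
            if c < self.dps[2 * i]:
                i = 2 * i
            else:
                c -= int(self.dps[2 * i])
                i = 2 * i + 1
        j0 = 2 * (i - self._nleaves)
        w0 = self._slot_weight(j0)
        if c < w0:
            return j0, c
        return j0 + 1, c - w0

    def column_to_position(self, col: int) -> int:
        """Residue slot shown in ``col``, or the GAP sentinel."""
        slot, offset = self.locate(col)
        if slot == self.n or offset < self.no_gaps[slot]:
            return GAP
        return slot

    def position_to_column(self, slot: int) -> int:
        """Column of residue ``slot`` (O(log n))."""
        if not (0 <= slot < self.n):
            raise IndexError(f"residue slot {slot} out of range [0, {self.n})")
        return self._prefix_weight(slot) + int(self.no_gaps[slot])

    def gap_type_at(self, col: int) -> int:
        """Gap-type code of the gap displayed at ``col`` (must be a gap).

        The first (leftmost) gap of a maximal run is an open; the run is
        terminal when it precedes the first residue or follows the last.
        """
        slot, offset = self.locate(col)
        if slot < self.n and offset == self.no_gaps[slot]:
            raise ValueError(f"column {col} holds a residue, not a gap")
        terminal = slot == 0 or slot == self.n
        if offset == 0:
            return GAP_TO if terminal else GAP_GO
        return GAP_TE if terminal else GAP_GE

    def symbol_at(self, col: int) -> int:
        """Extended-alphabet code shown at ``col`` (residue or gap type)."""
        pos = self.column_to_position(col)
        return self.gap_type_at(col) if pos == GAP else int(self.symbols[pos])

    # -- mutation ----------------------------------------------------------

    def classify_insertion(self, col: int) -> tuple[int, tuple[int, int] | None]:
        """Type of a gap inserted before ``col`` plus an optional retype.

        Returns (inserted_type, retype) where retype is (column, new_type)
        in pre-insertion coordinates, or None.  Covers the six correction
        situations: an open immediately right of the insertion hands its
        open status to the inserted gap (terminal S1, internal S4); a gap on
        the left makes the insertion an extension of that run (terminal
        S2/S6, internal S3); otherwise the insertion starts a new run,
        terminal at either row end, internal between residues (S5).
        """
        width = self.width
        if not (0 <= col <= width):
            raise IndexError(f"insertion point {col} out of range [0, {width}]")
        right = None if col == width else self.symbol_at(col)
        if right == GAP_TO:
            return GAP_TO, (col, GAP_TE)
        if right == GAP_GO:
            return GAP_GO, (col, GAP_GE)
        left = None if col == 0 else self.symbol_at(col - 1)
        if left in (GAP_TO, GAP_TE):
            return GAP_TE, None
        if left in (GAP_GO, GAP_GE):
            return GAP_GE, None
        if col == 0 or col == width:
            return GAP_TO, None
        return GAP_GO, None

    def insert_gap(self, col: int) -> tuple[int, tuple[int, int] | None]:
        """Insert one gap before ``col``; returns the classification that
        now applies (retype coordinates are pre-insertion)."""
        typed = self.classify_insertion(col)
        if col == self.width:
            slot = self.n
        else:
            slot, _ = self.locate(col)
        self.no_gaps[slot] += 1
        self._dps_add(slot, 1)
        return typed

    # -- conversions -------------------------------------------------------

    def realize(self) -> str:
        parts = []
        for j in range(self.n):
            parts.append(GAP_CHAR * int(self.no_gaps[j]))
            parts.append(alphabet.RESIDUES[self.symbols[j]])
        parts.append(GAP_CHAR * int(self.no_gaps[self.n]))
        return "".join(parts)

    def typed_columns(self) -> np.ndarray:
        """Extended-alphabet code per column (residues and typed gaps)."""
        out = np.empty(self.width, dtype=np.int8)
        c = 0
        for j in range(self.n + 1):
            g = int(self.no_gaps[j])
            terminal = j == 0 or j == self.n
            for off in range(g):
                if off == 0:
                    out[c] = GAP_TO if terminal else GAP_GO
                else:
                    out[c] = GAP_TE if terminal else GAP_GE
                c += 1
            if j < self.n:
                out[c] = self.symbols[j]
                c += 1
        return out

    def residues(self) -> np.ndarray:
        return self.symbols[:-1].copy()


def gapped_from_string(row: str) -> GappedSequence:
    """Build the gapped representation from an aligned row string."""
    codes, gaps, pending = [], [], 0
    for ch in row:
        if ch in GAP_CHARS:
            pending += 1
        else:
            codes.append(alphabet.encode_residue(ch))
            gaps.append(pending)
            pending = 0
    if not codes:
        raise ValueError("row contains no residues")
    gaps.append(pending)  # guard slot: trailing gaps
    return GappedSequence(np.array(codes, dtype=np.int8), np.array(gaps))


def gapped_from_sequence(seq: Sequence) -> GappedSequence:
    return GappedSequence(seq.codes, np.zeros(len(seq) + 1, dtype=np.int64))


# ---------------------------------------------------------------------------


class Profile:
    """A set of gapped rows plus per-column 32-slot occurrence counters."""

    __slots__ = ("members", "member_ids", "counters")

    def __init__(
        self,
        members: list[GappedSequence],
        member_ids: list[int],
        counters: np.ndarray | None = None,
    ):
        if not members:
            raise ValueError("profile needs at least one member")
        widths = {m.width for m in members}
        if len(widths) != 1:
            raise ValueError(f"member widths differ: {sorted(widths)}")
        self.members = members
        self.member_ids = member_ids
        if counters is None:
            counters = self._recount()
        self.counters = counters

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def width(self) -> int:
        return self.members[0].width

    def _recount(self) -> np.ndarray:
        counters = np.zeros((self.width, N_SLOTS), dtype=np.int64)
        cols = np.arange(self.width)
        for m in self.members:
            np.add.at(counters, (cols, m.typed_columns().astype(np.int64)), 1)
        return counters

    def residue_counts(self) -> np.ndarray:
        """Number of residue symbols per column."""
        return self.counters[:, :N_RESIDUES].sum(axis=1)

    def check(self) -> None:
        """Assert counter/realization consistency (tests and debugging)."""
        if self.counters.shape != (self.width, N_SLOTS):
            raise AssertionError("counter shape mismatch")
        if not np.array_equal(self.counters, self._recount()):
            raise AssertionError("counters disagree with realized members")
        if (self.counters.sum(axis=1) != self.k).any():
            raise AssertionError("column counts do not sum to k")

    def insert_gap_columns(self, col: int, count: int) -> None:
        """Insert ``count`` all-gap columns before ``col``, in place.

        Every member's gap counter and dps path are updated; no symbols are
        copied.  Counter columns for the inserted block and its right
        neighbor (which correction rules may retype) are recomputed from the
        members' run structure.
        """
        if count <= 0:
            return
        if not (0 <= col <= self.width):
            raise IndexError(f"insertion point {col} out of range")
        old_width = self.width
        self.counters = np.insert(
            self.counters, col, np.zeros((count, N_SLOTS), dtype=np.int64), axis=0
        )
        for m in self.members:
            for _ in range(count):
                m.insert_gap(col)
        # refresh the inserted block and, when a neighbor open was retyped,
        # the column right after it
        hi = min(col + count + 1, old_width + count)
        for j in range(col, hi):
            self.counters[j] = 0
        cols = np.arange(col, hi)
        for m in self.members:
            for j in cols:
                self.counters[j, m.symbol_at(int(j))] += 1

    def realize_rows(self) -> list[str]:
        return [m.realize() for m in self.members]

    def typed_matrix(self) -> np.ndarray:
        """(k, width) matrix of extended-alphabet codes."""
        return np.vstack([m.typed_columns() for m in self.members])


def profile_from_sequence(seq: Sequence, index: int) -> Profile:
    return Profile([gapped_from_sequence(seq)], [index])


def profile_from_rows(
    rows: TypingSequence[str], member_ids: TypingSequence[int] | None = None
) -> Profile:
    members = [gapped_from_string(r) for r in rows]
    ids = list(member_ids) if member_ids is not None else list(range(len(rows)))
    return Profile(members, ids)


# DP column operations
MATCH = 0
GAP_IN_X = 1  # gap column inserted into X, consuming a Y column
GAP_IN_Y = 2  # gap column inserted into Y, consuming an X column


def merge_profiles(x: Profile, y: Profile, ops: Iterable[int]) -> Profile:
    """Merge two profiles under a monotone column matching.

    ``ops`` consume every column of both inputs exactly once; gap columns
    are inserted in place and member rows are moved (not copied) into the
    result.
    """
    ops = list(ops)
    x_ins: list[tuple[int, int]] = []  # (x column, run length)
    y_ins: list[tuple[int, int]] = []
    xi = yi = 0
    i = 0
    while i < len(ops):
        op = ops[i]
        if op == MATCH:
            xi += 1
            yi += 1
            i += 1
        elif op == GAP_IN_X:
            run = 0
            while i < len(ops) and ops[i] == GAP_IN_X:
                run += 1
                yi += 1
                i += 1
            x_ins.append((xi, run))
        elif op == GAP_IN_Y:
            run = 0
            while i < len(ops) and ops[i] == GAP_IN_Y:
                run += 1
                xi += 1
                i += 1
            y_ins.append((yi, run))
        else:
            raise ValueError(f"unknown op {op!r} in matching")
    if xi != x.width or yi != y.width:
        raise ValueError("matching does not consume both profiles exactly")
    for col, run in reversed(x_ins):
        x.insert_gap_columns(col, run)
    for col, run in reversed(y_ins):
        y.insert_gap_columns(col, run)
    if x.width != y.width:
        raise ValueError("matching produced inconsistent widths")
    return Profile(
        x.members + y.members,
        x.member_ids + y.member_ids,
        x.counters + y.counters,
    )
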