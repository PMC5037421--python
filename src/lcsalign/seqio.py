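"""Sequences, sequence sets, alignments, and FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence, Union

import numpy as np
from Bio import SeqIO

from lcsalign import alphabet
from lcsalign.alphabet import GAP_CHAR, GAP_CHARS


@dataclass
class Sequence:
    """A protein sequence over the residue alphabet.

    ``id`` is the sanitized identifier (header truncated at the first
    whitespace); ``description`` keeps the full header for output.
    """

    id: str
    codes: np.ndarray  # int8 residue codes
    description: str = ""

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if len(self.codes) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if ((self.codes < 0) | (self.codes >= alphabet.N_RESIDUES)).any():
            raise ValueError(f"sequence {self.id!r} has invalid residue codes")

    @classmethod
    def from_string(cls, id: str, residues: str, description: str = "") -> "Sequence":
        return cls(id, alphabet.encode(residues), description)

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return alphabet.decode(self.codes)


@dataclass
class SequenceSet:
    """An ordered collection of sequences with unique sanitized ids."""

    sequences: list[Sequence]

    def __post_init__(self):
        ids = [s.id for s in self.sequences]
        seen: dict[str, int] = {}
        for i, sid in enumerate(ids):
            if sid in seen:
                raise ValueError(
                    f"duplicate id {sid!r} at records {seen[sid]} and {i}"
                )
            seen[sid] = i

    @property
    def k(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return self.k

    def __getitem__(self, i: int) -> Sequence:
        return self.sequences[i]

    def __iter__(self):
        return iter(self.sequences)

    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]


@dataclass
class Alignment:
    """A multiple alignment: k equal-width rows over residues and '-'.

    Gap-stripping row i reproduces input sequence i exactly, and no column
    may consist solely of gaps.
    """

    ids: list[str]
    rows: list[str]
    descriptions: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment has no rows")
        w = len(self.rows[0])
        if any(len(r) != w for r in self.rows):
            raise ValueError("alignment rows have unequal widths")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if not self.descriptions:
            self.descriptions = list(self.ids)
        for j in range(w):
            if all(r[j] in GAP_CHARS for r in self.rows):
                raise ValueError(f"column {j} consists solely of gaps")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def k(self) -> int:
        return len(self.rows)

    def stripped(self, i: int) -> str:
        """Row i with gap characters removed."""
        row = self.rows[i]
        return "".join(ch for ch in row if ch not in GAP_CHARS)

    def to_sequence_set(self) -> SequenceSet:
        return SequenceSet(
            [
                Sequence.from_string(self.ids[i], self.stripped(i), self.descriptions[i])
                for i in range(self.k)
            ]
        )


def _sanitize(header_id: str) -> str:
    # Bio.SeqIO already truncates at whitespace for .id; be defensive anyway
    return header_id.split()[0] if header_id.split() else header_id


def read_fasta(path: Union[str, Path]) -> SequenceSet:
    """Read unaligned sequences from FASTA; gap characters are stripped.

    Raises ``ValueError`` on an empty file, duplicate sanitized ids, or a
    zero-length record (the message names the record index).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs = []
    for idx, rec in enumerate(records):
        residues = "".join(
            ch for ch in str(rec.seq).upper() if ch not in GAP_CHARS
        )
        if not residues:
            raise ValueError(f"record {idx} ({rec.id!r}) has no residues")
        seqs.append(Sequence.from_string(_sanitize(rec.id), residues, rec.description))
    return SequenceSet(seqs)


def read_fasta_alignment(path: Union[str, Path]) -> Alignment:
    """Read an aligned FASTA file ('-' or '.' as gap) into an Alignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids, rows, descs = [], [], []
    for rec in records:
        ids.append(_sanitize(rec.id))
        rows.append(str(rec.seq).upper().replace(".", GAP_CHAR))
        descs.append(rec.description)
    return Alignment(ids, rows, descs)


def write_fasta(
    obj: Union[Alignment, SequenceSet],
    path: Union[str, Path],
    width: int = 60,
) -> None:
    """Write an alignment or sequence set as FASTA with line wrapping."""
    if isinstance(obj, Alignment):
        items: Iterable[tuple[str, str]] = zip(obj.descriptions, obj.rows)
    else:
        items = ((s.description or s.id, str(s)) for s in obj)
    with open(path, "w") as fh:
        for header, seq in items:
            fh.write(f">{header}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")


def alignment_from_rows(
    ids: TypingSequence[str],
    rows: TypingSequence[str],
    descriptions: TypingSequence[str] | None = None,
) -> Alignment:
    return Alignment(list(ids), list(rows), list(descriptions or []))
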