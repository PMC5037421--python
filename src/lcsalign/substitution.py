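"""Substitution matrices: the builtin MIQS table and a text-file loader.

MIQS is an amino-acid substitution matrix derived from structure-informed
alignments of distantly related proteins; it performs well when families are
deep and divergent.  The 20x20 block below is transcribed from its source
publication.  Scores for the ambiguity/rare codes B, Z, X, U, O (absent from
the published table) are filled by averaging the corresponding standard
residues: B=mean(N,D), Z=mean(Q,E), U=C, O=K, X=mean over all twenty,
rounded to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import logging

import numpy as np

from lcsalign import alphabet
from lcsalign.alphabet import N_RESIDUES, RESIDUES, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

# rows/cols in order A R N D C Q E G H I L K M F P S T W Y V
_MIQS_20 = np.array(
    [
        [3.2, -1.3, -0.4, -0.4, 1.5, -0.2, -0.4, 0.4, -1.2, -1.3, -1.4, -0.7, -1.0, -2.3, -0.1, 0.8, 0.8, -3.6, -2.4, 0.0],
        [-1.3, 6.2, -0.1, -1.5, -2.7, 1.8, -0.7, -1.9, 0.9, -2.4, -2.5, 3.3, -1.1, -3.3, -1.1, -0.3, -0.2, -2.2, -1.8, -2.3],
        [-0.4, -0.1, 5.1, 2.6, -1.6, 0.9, 0.8, 0.2, 1.0, -3.6, -3.5, 0.7, -2.3, -3.5, -1.4, 0.9, 0.0, -4.5, -1.5, -2.6],
        [-0.4, -1.5, 2.6, 5.7, -3.7, 0.9, 2.7, -0.5, 0.3, -4.5, -4.6, 0.4, -3.3, -5.8, -0.3, 0.3, -0.2, -5.3, -3.9, -3.5],
        [1.5, -2.7, -1.6, -3.7, 11.7, -2.8, -3.2, -1.7, -1.2, 0.2, -2.3, -3.2, 0.1, -2.8, -2.8, 1.0, 0.0, -6.1, -0.7, 1.8],
        [-0.2, 1.8, 0.9, 0.9, -2.8, 3.6, 2.1, -1.6, 1.2, -2.2, -1.9, 1.7, -0.4, -2.4, -0.4, 0.4, 0.1, -5.4, -2.8, -1.8],
        [-0.4, -0.7, 0.8, 2.7, -3.2, 2.1, 3.6, -1.5, -0.2, -3.3, -2.8, 1.2, -2.3, -4.7, 0.0, 0.2, -0.1, -5.8, -2.4, -2.3],
        [0.4, -1.9, 0.2, -0.5, -1.7, -1.6, -1.5, 7.6, -1.6, -5.4, -4.8, -1.7, -3.8, -4.9, -1.6, 0.0, -1.9, -4.8, -4.5, -3.8],
        [-1.2, 0.9, 1.0, 0.3, -1.2, 1.2, -0.2, -1.6, 7.5, -2.2, -1.9, 0.0, -2.1, 0.0, -1.5, 0.0, -0.2, -0.3, 2.2, -2.3],
        [-1.3, -2.4, -3.6, -4.5, 0.2, -2.2, -3.3, -5.4, -2.2, 4.6, 3.1, -2.3, 1.7, 0.7, -2.3, -2.8, -0.8, -0.9, -0.9, 3.3],
        [-1.4, -2.5, -3.5, -4.6, -2.3, -1.9, -2.8, -4.8, -1.9, 3.1, 4.6, -2.4, 3.2, 2.1, -2.8, -2.9, -1.6, -0.2, 0.0, 2.0],
        [-0.7, 3.3, 0.7, 0.4, -3.2, 1.7, 1.2, -1.7, 0.0, -2.3, -2.4, 3.6, -1.1, -3.7, -0.1, 0.0, 0.0, -4.0, -2.3, -2.0],
        [-1.0, -1.1, -2.3, -3.3, 0.1, -0.4, -2.3, -3.8, -2.1, 1.7, 3.2, -1.1, 5.4, 1.4, -2.8, -1.8, -0.8, -0.9, 0.3, 1.4],
        [-2.3, -3.3, -3.5, -5.8, -2.8, -2.4, -4.7, -4.9, 0.0, 0.7, 2.1, -3.7, 1.4, 7.4, -3.7, -2.6, -2.2, 4.2, 5.2, -0.3],
        [-0.1, -1.1, -1.4, -0.3, -2.8, -0.4, 0.0, -1.6, -1.5, -2.3, -2.8, -0.1, -2.8, -3.7, 8.4, -0.1, -0.5, -3.6, -4.5, -2.5],
        [0.8, -0.3, 0.9, 0.3, 1.0, 0.4, 0.2, 0.0, 0.0, -2.8, -2.9, 0.0, -1.8, -2.6, -0.1, 2.2, 1.7, -3.5, -1.5, -1.4],
        [0.8, -0.2, 0.0, -0.2, 0.0, 0.1, -0.1, -1.9, -0.2, -0.8, -1.6, 0.0, -0.8, -2.2, -0.5, 1.7, 2.7, -3.5, -1.9, 0.2],
        [-3.6, -2.2, -4.5, -5.3, -6.1, -5.4, -5.8, -4.8, -0.3, -0.9, -0.2, -4.0, -0.9, 4.2, -3.6, -3.5, -3.5, 14.8, 4.9, -3.3],
        [-2.4, -1.8, -1.5, -3.9, -0.7, -2.8, -2.4, -4.5, 2.2, -0.9, 0.0, -2.3, 0.3, 5.2, -4.5, -1.5, -1.9, 4.9, 8.3, -1.2],
        [0.0, -2.3, -2.6, -3.5, 1.8, -1.8, -2.3, -3.8, -2.3, 3.3, 2.0, -2.0, 1.4, -0.3, -2.5, -1.4, 0.2, -3.3, -1.2, 3.5],
    ]
)

# which standard residues each extra code averages over
_EXTRA_SOURCES = {
    "B": "ND",
    "Z": "QE",
    "X": STANDARD_RESIDUES,
    "U": "C",
    "O": "K",
}


@dataclass
class SubstitutionMatrix:
    """A symmetric residue-residue score table over the 25 residue codes."""

    name: str
    scores: np.ndarray  # (25, 25) float64

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError(
                f"matrix {self.name!r} has shape {self.scores.shape}, "
                f"expected ({N_RESIDUES}, {N_RESIDUES})"
            )
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError(f"matrix {self.name!r} is not symmetric")
        diag_max = self.scores.diagonal().max()
        off = self.scores - np.diag(self.scores.diagonal())
        if off.max() > diag_max:
            logger.warning(
                "matrix %s: an off-diagonal score exceeds the diagonal maximum",
                self.name,
            )

    def score(self, a: str, b: str) -> float:
        return float(
            self.scores[alphabet.encode_residue(a), alphabet.encode_residue(b)]
        )


def _expand_to_full(block: np.ndarray, labels: str) -> np.ndarray:
    """Embed a score block over ``labels`` into the full 25x25 table,
    filling missing codes by the averaging policy."""
    full = np.zeros((N_RESIDUES, N_RESIDUES))
    have = {ch: i for i, ch in enumerate(labels)}
    codes_have = [alphabet.encode_residue(ch) for ch in labels]
    for ch_i, bi in have.items():
        for ch_j, bj in have.items():
            full[alphabet.encode_residue(ch_i), alphabet.encode_residue(ch_j)] = block[bi, bj]
    missing = [ch for ch in RESIDUES if ch not in have]

    def sources(ch: str) -> list[int]:
        srcs = [s for s in _EXTRA_SOURCES.get(ch, STANDARD_RESIDUES) if s in have]
        return [alphabet.encode_residue(s) for s in (srcs or list(have))]

    for ch in missing:
        ci = alphabet.encode_residue(ch)
        for cj in codes_have:
            val = round(float(np.mean([full[s, cj] for s in sources(ch)])), 1)
            full[ci, cj] = full[cj, ci] = val
    # pairs of two missing codes: average over both source sets
    for a_i, ch_i in enumerate(missing):
        for ch_j in missing[a_i:]:
            ci = alphabet.encode_residue(ch_i)
            cj = alphabet.encode_residue(ch_j)
            vals = [full[si, sj] for si in sources(ch_i) for sj in sources(ch_j)]
            v = round(float(np.mean(vals)), 1)
            full[ci, cj] = full[cj, ci] = v
    return full


def _builtin_miqs() -> SubstitutionMatrix:
    return SubstitutionMatrix("MIQS", _expand_to_full(_MIQS_20, STANDARD_RESIDUES))


def _parse_matrix_file(path: Path) -> SubstitutionMatrix:
    """Parse an NCBI/EMBOSS-style whitespace-delimited score table."""
    labels: list[str] = []
    rows: list[tuple[str, list[float]]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if not labels:
            labels = parts
            continue
        row_label, values = parts[0], [float(v) for v in parts[1:]]
        if len(values) != len(labels):
            raise ValueError(
                f"{path}: row {row_label!r} has {len(values)} values, "
                f"expected {len(labels)}"
            )
        rows.append((row_label, values))
    if not labels or not rows:
        raise ValueError(f"{path}: no score table found")
    for lab in labels:
        if lab != "*" and lab.upper() not in RESIDUES:
            raise ValueError(f"{path}: unknown residue label {lab!r}")
    keep = [i for i, lab in enumerate(labels) if lab != "*"]
    labs = "".join(labels[i].upper() for i in keep)
    block = np.array([[rows[i][1][j] for j in keep] for i in range(len(rows)) if labels[i] != "*"])
    if not np.array_equal(block, block.T):
        bad = np.argwhere(block != block.T)[0]
        raise ValueError(
            f"{path}: asymmetric scores for pair "
            f"({labs[bad[0]]}, {labs[bad[1]]})"
        )
    return SubstitutionMatrix(path.stem, _expand_to_full(block, labs))


def load_matrix(source: Union[str, Path] = "MIQS") -> SubstitutionMatrix:
    """Load a substitution matrix by builtin name ("MIQS") or file path."""
    if isinstance(source, str) and source.upper() == "MIQS":
        return _builtin_miqs()
    path = Path(source)
    if not path.exists():
        raise ValueError(f"unknown builtin matrix or missing file: {source}")
    return _parse_matrix_file(path)
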