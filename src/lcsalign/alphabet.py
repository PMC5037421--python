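"""Residue alphabet and symbol codes.

The extended alphabet has 32 slots: 25 residue codes (20 standard amino
acids plus the ambiguity/rare codes B, Z, X, U, O), four gap-type codes
(terminal open/extension, internal open/extension) and a guard code used by
the gapped sequence representation.  Residues are ordered as in common
substitution-matrix files (ARNDCQEGHILKMFPSTWYV) so the vendored matrix rows
read naturally.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = "ARNDCQEGHILKMFPSTWYV"
EXTRA_RESIDUES = "BZXUO"
RESIDUES = STANDARD_RESIDUES + EXTRA_RESIDUES
N_RESIDUES = len(RESIDUES)  # 25

# gap-type codes (follow the residue block)
GAP_TO = 25  # terminal gap open
GAP_TE = 26  # terminal gap extension
GAP_GO = 27  # internal gap open
GAP_GE = 28  # internal gap extension
GUARD = 29
N_SLOTS = 32  # counter layout: 25 residues + 4 gap types + guard + spare

GAP_TYPES = (GAP_TO, GAP_TE, GAP_GO, GAP_GE)
GAP_TYPE_NAMES = {GAP_TO: "To", GAP_TE: "Te", GAP_GO: "Go", GAP_GE: "Ge"}

GAP_CHAR = "-"
GAP_CHARS = "-."

_CODE_OF = {aa: i for i, aa in enumerate(RESIDUES)}
_UNKNOWN = _CODE_OF["X"]


def encode_residue(letter: str) -> int:
    """Map a single residue letter to its code; unknown letters map to X."""
    c = _CODE_OF.get(letter.upper())
    if c is None:
        logger.warning("unknown residue letter %r mapped to X", letter)
        c = _UNKNOWN
    return c


def encode(residues: str) -> np.ndarray:
    """Encode a residue string (no gap characters) to an int8 code array."""
    out = np.empty(len(residues), dtype=np.int8)
    for i, ch in enumerate(residues):
        out[i] = encode_residue(ch)
    return out


def decode(codes) -> str:
    return "".join(RESIDUES[int(c)] for c in codes)


def is_gap_char(ch: str) -> bool:
    return ch in GAP_CHARS
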