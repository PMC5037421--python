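"""Four-type affine gap penalties with set-size scaling.

Gaps are priced by the classic affine scheme, but terminal runs (touching
either end of a row) carry their own open/extension penalties (To, Te)
distinct from internal ones (Go, Ge).  All four penalties are multiplied by
a factor that grows with the number of sequences k, which keeps alignments
of large collections from widening needlessly:

    scaler(k) = 1                          for k <= g_l
                1 + log2(k / g_l) / g_d    otherwise

with constants g_l = 45 and g_d = 7.  The closed form of the growth term is
implementation-defined (only the constants and the intent are fixed); it is
continuous at k = g_l and non-decreasing in k, and both constants are
configurable.

Default penalty magnitudes (Go = -14.85, Ge = -1.25, To = Te = -0.66, in
substitution-matrix units) are tunables of this package, exposed on the
command line, not values with any external authority.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from lcsalign.alphabet import (
    GAP_GE,
    GAP_GO,
    GAP_TE,
    GAP_TO,
    GAP_TYPES,
    N_RESIDUES,
    N_SLOTS,
)
from lcsalign.substitution import SubstitutionMatrix

logger = logging.getLogger(__name__)

DEFAULT_GO = -14.85
DEFAULT_GE = -1.25
DEFAULT_TO = -0.66
DEFAULT_TE = -0.66


def gap_scaler(k: int, g_l: float = 45.0, g_d: float = 7.0) -> float:
    """Set-size scaling factor applied to all four gap penalties."""
    if k < 1 or g_l < 1 or g_d <= 0:
        raise ValueError("require k >= 1, g_l >= 1, g_d > 0")
    if k <= g_l:
        return 1.0
    return 1.0 + math.log2(k / g_l) / g_d


@dataclass(frozen=True)
class GapModel:
    """Penalties (<= 0) for the four gap types plus the scaling constants."""

    go: float = DEFAULT_GO
    ge: float = DEFAULT_GE
    to: float = DEFAULT_TO
    te: float = DEFAULT_TE
    g_l: float = 45.0
    g_d: float = 7.0
    scaler: float = 1.0

    def __post_init__(self):
        if abs(self.ge) > abs(self.go) or abs(self.te) > abs(self.to):
            logger.warning(
                "gap extension magnitude exceeds the matching open penalty"
            )

    def scaled_for(self, k: int) -> "GapModel":
        """A copy with the scaler set for a collection of k sequences."""
        return replace(self, scaler=gap_scaler(k, self.g_l, self.g_d))

    def penalty(self, gap_type: int) -> float:
        """Scaled penalty of one gap-type code."""
        base = {
            GAP_TO: self.to,
            GAP_TE: self.te,
            GAP_GO: self.go,
            GAP_GE: self.ge,
        }.get(gap_type)
        if base is None:
            raise ValueError(f"unknown gap type code {gap_type}")
        return base * self.scaler


def gap_score(gap_type: int, model: GapModel) -> float:
    return model.penalty(gap_type)


def pair_score_table(matrix: SubstitutionMatrix, model: GapModel) -> np.ndarray:
    """32x32 table of per-column pair contributions over the extended
    alphabet: residue-residue from the substitution matrix, residue vs gap
    type the scaled penalty of that type, gap vs gap zero."""
    table = np.zeros((N_SLOTS, N_SLOTS))
    table[:N_RESIDUES, :N_RESIDUES] = matrix.scores
    for g in GAP_TYPES:
        pen = model.penalty(g)
        table[g, :N_RESIDUES] = pen
        table[:N_RESIDUES, g] = pen
    return table


def pair_gap_score(
    a: int, b: int, matrix: SubstitutionMatrix, model: GapModel
) -> float:
    """Score of one column pair over the extended alphabet."""
    a_res = a < N_RESIDUES
    b_res = b < N_RESIDUES
    if not a_res and a not in GAP_TYPES:
        raise ValueError(f"unknown symbol code {a}")
    if not b_res and b not in GAP_TYPES:
        raise ValueError(f"unknown symbol code {b}")
    if a_res and b_res:
        return float(matrix.scores[a, b])
    if a_res != b_res:
        return model.penalty(b if a_res else a)
    return 0.0


# re-exported here because the correction rules conceptually belong to the
# gap model even though they operate on the gapped representation
def classify_inserted_gap(row, col: int):
    """Type of a gap inserted before ``col`` of a gapped row, plus an
    optional (column, new_type) retype of the neighboring gap.

    See :meth:`lcsalign.profile.GappedSequence.classify_insertion` for the
    six correction situations.
    """
    return row.classify_insertion(col)
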