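"""Stage III: profile-profile dynamic programming and the progressive driver.

The DP maximizes the summed cross-pair score between the columns of the two
profiles; within-profile pairs are constants of the matching and do not
affect the argmax.  Gap columns are priced per inserted row against the
residues of the consumed column, with terminal penalties in the first/last
row/column band of the DP matrix.  When the matching is realized, the
correction rules retype inserted and neighboring gaps from the actual run
structure of every member row, which may shift the score away from the DP's
internal value; the reported score is therefore always recomputed from the
realized merge (a warning counter tracks disagreements).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from lcsalign._kernels import affine_profile_dp
from lcsalign.alphabet import GAP_GE, GAP_GO, GAP_TE, GAP_TO
from lcsalign.gap_model import GapModel, pair_score_table
from lcsalign.guide_tree import GuideTree
from lcsalign.profile import (
    GAP_IN_X,
    GAP_IN_Y,
    MATCH,
    Profile,
    merge_profiles,
    profile_from_sequence,
)
from lcsalign.scoring import profile_score
from lcsalign.seqio import Alignment, Sequence, SequenceSet
from lcsalign.substitution import SubstitutionMatrix

logger = logging.getLogger(__name__)

#: number of merges where the realized score differed from the DP's internal
#: prediction (gap-type correction at work); reset freely in tests
correction_mismatches = 0


@dataclass
class DPResult:
    """A monotone column matching, its realized score, and the merge."""

    matching: np.ndarray  # int8 ops: MATCH / GAP_IN_X / GAP_IN_Y
    score: float  # model score of the realized merged profile
    dp_score: float  # the DP's internal prediction of the same quantity
    profile: Profile  # the merged profile (inputs are consumed)

    def counts(self) -> tuple[int, int, int]:
        m = int((self.matching == MATCH).sum())
        gx = int((self.matching == GAP_IN_X).sum())
        gy = int((self.matching == GAP_IN_Y).sum())
        return m, gx, gy


def column_costs(
    y: Profile, matrix: SubstitutionMatrix, model: GapModel
) -> np.ndarray:
    """Per-column, per-symbol alignment costs: table[j, s] is the score of
    aligning every symbol of Y's column j against one occurrence of s."""
    return y.counters @ pair_score_table(matrix, model)


def _match_matrix(
    x: Profile, y: Profile, table: np.ndarray
) -> np.ndarray:
    """Column-vs-column cross scores; (n1, n2)."""
    cost_y = y.counters @ table
    return x.counters @ cost_y.T


def _is_single_gapless(p: Profile) -> bool:
    return p.k == 1 and int(p.members[0].no_gaps.sum()) == 0


def _run_dp(
    x: Profile,
    y: Profile,
    match: np.ndarray,
    matrix: SubstitutionMatrix,
    model: GapModel,
) -> DPResult:
    global correction_mismatches
    table = pair_score_table(matrix, model)
    within = profile_score(x, table) + profile_score(y, table)
    cross, ops = affine_profile_dp(
        np.ascontiguousarray(match, dtype=np.float64),
        x.residue_counts().astype(np.float64),
        y.residue_counts().astype(np.float64),
        float(x.k),
        float(y.k),
        model.penalty(GAP_GO),
        model.penalty(GAP_GE),
        model.penalty(GAP_TO),
        model.penalty(GAP_TE),
    )
    merged = merge_profiles(x, y, ops)
    realized = profile_score(merged, table)
    predicted = float(cross) + within
    if abs(realized - predicted) > 1e-6 * max(1.0, abs(realized)):
        correction_mismatches += 1
        logger.debug(
            "gap correction moved the score: DP %.6f, realized %.6f",
            predicted,
            realized,
        )
    return DPResult(np.asarray(ops), realized, predicted, merged)


def align_profiles(
    x: Profile, y: Profile, matrix: SubstitutionMatrix, model: GapModel
) -> DPResult:
    """Align two profiles; the inputs are consumed into the merged result.

    ``model`` is used as configured (apply :meth:`GapModel.scaled_for`
    beforehand when aligning members of a larger collection).
    """
    table = pair_score_table(matrix, model)
    return _run_dp(x, y, _match_matrix(x, y, table), matrix, model)


def align_seq_seq(
    a: Sequence,
    b: Sequence,
    matrix: SubstitutionMatrix,
    model: GapModel,
    idx_a: int = 0,
    idx_b: int = 1,
) -> DPResult:
    """Specialized variant for two single sequences: the match matrix is a
    direct substitution-matrix lookup, no counters involved."""
    match = matrix.scores[np.ix_(a.codes.astype(np.int64), b.codes.astype(np.int64))]
    x = profile_from_sequence(a, idx_a)
    y = profile_from_sequence(b, idx_b)
    return _run_dp(x, y, match, matrix, model)


def align_profile_seq(
    x: Profile,
    b: Sequence,
    matrix: SubstitutionMatrix,
    model: GapModel,
    idx_b: int,
) -> DPResult:
    """Specialized variant for profile-vs-sequence: one column-cost lookup
    per cell instead of a counter product."""
    cost_x = column_costs(x, matrix, model)
    match = cost_x[:, b.codes.astype(np.int64)]
    y = profile_from_sequence(b, idx_b)
    return _run_dp(x, y, match, matrix, model)


def progressive_align(
    seqset: SequenceSet,
    tree: GuideTree,
    matrix: SubstitutionMatrix,
    model: GapModel,
    audit: list | None = None,
) -> Alignment:
    """Post-order fold of profile alignments over the guide tree.

    ``model`` must already carry the scaler for this collection.  When
    ``audit`` is a list, one (dp_score, realized_score) pair is appended
    per merge.  Output rows follow the input sequence order.
    """
    if tree.k != seqset.k:
        raise ValueError(f"tree has {tree.k} leaves but the set has {seqset.k}")
    profiles: dict[int, Profile] = {}
    for node, left, right in tree.merges():
        px = profiles.pop(left) if left >= seqset.k else None
        py = profiles.pop(right) if right >= seqset.k else None
        if px is None and py is None:
            res = align_seq_seq(
                seqset[left], seqset[right], matrix, model, left, right
            )
        elif py is None:
            res = align_profile_seq(px, seqset[right], matrix, model, right)
        elif px is None:
            # keep x/y roles: a single left leaf becomes a one-row profile
            res = align_profiles(
                profile_from_sequence(seqset[left], left), py, matrix, model
            )
        else:
            res = align_profiles(px, py, matrix, model)
        if audit is not None:
            audit.append((res.dp_score, res.score))
        profiles[node] = res.profile
    final = profiles[tree.root]
    order = np.argsort(final.member_ids)
    rows = final.realize_rows()
    return Alignment(
        [seqset[final.member_ids[i]].id for i in order],
        [rows[i] for i in order],
        [seqset[final.member_ids[i]].description for i in order],
    )
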