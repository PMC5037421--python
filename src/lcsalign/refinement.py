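"""Stage IV: column-oriented iterative refinement.

Each iteration picks, uniformly at random, one column that contains at
least one gap, splits the rows into two subprofiles by gap presence in that
column, drops columns that became all-gap within each part, realigns the
two parts with the profile DP, and accepts the result only when its model
score is strictly higher than the current one (equal-score proposals are
rejected to prevent cycling).  Iterations count proposals, not
acceptances.  Refinement is gated to collections of at most ``k_max``
sequences in auto mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lcsalign.aligner import align_profiles
from lcsalign.alphabet import GAP_CHARS
from lcsalign.gap_model import GapModel
from lcsalign.profile import profile_from_rows
from lcsalign.scoring import model_score
from lcsalign.seqio import Alignment
from lcsalign.substitution import SubstitutionMatrix


@dataclass
class RefineConfig:
    iterations: int = 100
    k_max: int = 1000
    seed: int = 0
    mode: str = "auto"  # auto | on | off

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.mode not in ("auto", "on", "off"):
            raise ValueError(f"unknown refinement mode {self.mode!r}")

    def active(self, k: int) -> bool:
        if self.mode == "off":
            return False
        if self.mode == "on":
            return True
        return k <= self.k_max


def _strip_all_gap_columns(rows: list[str]) -> list[str]:
    keep = [
        j
        for j in range(len(rows[0]))
        if any(r[j] not in GAP_CHARS for r in rows)
    ]
    return ["".join(r[j] for j in keep) for r in rows]


def refine(
    aln: Alignment,
    matrix: SubstitutionMatrix,
    model: GapModel,
    cfg: RefineConfig | None = None,
    accepted_scores: list | None = None,
) -> Alignment:
    """Iteratively refine an alignment; the returned alignment never scores
    below the input.  ``model`` is used as configured (pre-scaled).

    When ``accepted_scores`` is a list, the score after every accepted
    proposal is appended (a strictly increasing sequence).
    """
    cfg = cfg or RefineConfig()
    if not cfg.active(aln.k):
        return aln
    rng = np.random.default_rng(cfg.seed)
    current = aln
    current_score = model_score(aln, matrix, model)
    for _ in range(cfg.iterations):
        gap_cols = [
            j
            for j in range(current.width)
            if any(r[j] in GAP_CHARS for r in current.rows)
        ]
        if not gap_cols:
            break
        col = int(rng.choice(np.array(gap_cols)))
        in_gap = [i for i in range(current.k) if current.rows[i][col] in GAP_CHARS]
        no_gap = [i for i in range(current.k) if i not in in_gap]
        # the chosen column has >= 1 gap and >= 1 residue, so neither side
        # can be empty
        rows_a = _strip_all_gap_columns([current.rows[i] for i in in_gap])
        rows_b = _strip_all_gap_columns([current.rows[i] for i in no_gap])
        pa = profile_from_rows(rows_a, in_gap)
        pb = profile_from_rows(rows_b, no_gap)
        res = align_profiles(pa, pb, matrix, model)
        if res.score > current_score:
            merged = res.profile
            order = np.argsort(merged.member_ids)
            rows = merged.realize_rows()
            current = Alignment(
                [current.ids[merged.member_ids[i]] for i in order],
                [rows[i] for i in order],
                [current.descriptions[merged.member_ids[i]] for i in order],
            )
            current_score = res.score
            if accepted_scores is not None:
                accepted_scores.append(current_score)
    return current
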