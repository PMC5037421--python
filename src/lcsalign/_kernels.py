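"""Numba kernels for the profile-profile dynamic programming."""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30

# state codes; also the traceback pointer vocabulary
_M, _IX, _IY = 0, 1, 2


@njit(cache=False)
def affine_profile_dp(
    match: np.ndarray,  # (n1, n2) column-vs-column match scores
    resx: np.ndarray,  # residues per X column
    resy: np.ndarray,  # residues per Y column
    k1: float,
    k2: float,
    go: float,
    ge: float,
    to: float,
    te: float,
):
    """Three-state affine DP over profile columns, maximizing the summed
    cross-pair score.  Gap columns inserted at the first/last row or column
    of the DP are priced as terminal (to/te), others as internal (go/ge);
    direct transitions between the two insertion states are permitted (the
    double-gap-column check).  Ties prefer MATCH, then GAP_IN_Y, then
    GAP_IN_X.  Returns (score, ops) with ops[i] in {0: MATCH, 1: GAP_IN_X
    consuming a Y column, 2: GAP_IN_Y consuming an X column}.
    """
    n1 = match.shape[0]
    n2 = match.shape[1]
    M = np.full((n1 + 1, n2 + 1), NEG)
    IX = np.full((n1 + 1, n2 + 1), NEG)
    IY = np.full((n1 + 1, n2 + 1), NEG)
    pM = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    pIX = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    pIY = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    M[0, 0] = 0.0
    # first row: leading gap columns in X (terminal, i == 0)
    for j in range(1, n2 + 1):
        w = k1 * resy[j - 1]
        open_v = M[0, j - 1] + w * to
        ext_v = IX[0, j - 1] + w * te
        if open_v >= ext_v:
            IX[0, j] = open_v
            pIX[0, j] = _M
        else:
            IX[0, j] = ext_v
            pIX[0, j] = _IX
    # first column: leading gap columns in Y (terminal, j == 0)
    for i in range(1, n1 + 1):
        w = k2 * resx[i - 1]
        open_v = M[i - 1, 0] + w * to
        ext_v = IY[i - 1, 0] + w * te
        if open_v >= ext_v:
            IY[i, 0] = open_v
            pIY[i, 0] = _M
        else:
            IY[i, 0] = ext_v
            pIY[i, 0] = _IY
    for i in range(1, n1 + 1):
        x_term = i == n1  # i == 0 handled above
        for j in range(1, n2 + 1):
            # MATCH: tie preference M > IY > IX
            best = M[i - 1, j - 1]
            src = _M
            if IY[i - 1, j - 1] > best:
                best = IY[i - 1, j - 1]
                src = _IY
            if IX[i - 1, j - 1] > best:
                best = IX[i - 1, j - 1]
                src = _IX
            M[i, j] = best + match[i - 1, j - 1]
            pM[i, j] = src
            # GAP_IN_X consuming Y column j-1
            w = k1 * resy[j - 1]
            og = to if x_term else go
            eg = te if x_term else ge
            open_src = _M
            open_base = M[i, j - 1]
            if IY[i, j - 1] > open_base:
                open_base = IY[i, j - 1]
                open_src = _IY
            open_v = open_base + w * og
            ext_v = IX[i, j - 1] + w * eg
            if open_v >= ext_v:
                IX[i, j] = open_v
                pIX[i, j] = open_src
            else:
                IX[i, j] = ext_v
                pIX[i, j] = _IX
            # GAP_IN_Y consuming X column i-1
            y_term = j == n2
            w2 = k2 * resx[i - 1]
            og2 = to if y_term else go
            eg2 = te if y_term else ge
            open_src2 = _M
            open_base2 = M[i - 1, j]
            if IX[i - 1, j] > open_base2:
                open_base2 = IX[i - 1, j]
                open_src2 = _IX
            open_v2 = open_base2 + w2 * og2
            ext_v2 = IY[i - 1, j] + w2 * eg2
            if open_v2 >= ext_v2:
                IY[i, j] = open_v2
                pIY[i, j] = open_src2
            else:
                IY[i, j] = ext_v2
                pIY[i, j] = _IY
    # final state: prefer M, then IY, then IX
    state = _M
    score = M[n1, n2]
    if IY[n1, n2] > score:
        score = IY[n1, n2]
        state = _IY
    if IX[n1, n2] > score:
        score = IX[n1, n2]
        state = _IX
    # traceback
    ops = np.empty(n1 + n2, dtype=np.int8)
    pos = n1 + n2
    i, j = n1, n2
    while i > 0 or j > 0:
        pos -= 1
        if state == _M:
            ops[pos] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == _IX:
            ops[pos] = 1
            state = pIX[i, j]
            j -= 1
        else:
            ops[pos] = 2
            state = pIY[i, j]
            i -= 1
    return score, ops[pos:]


@njit(cache=False)
def lcs_dp_matrix(a: np.ndarray, b: np.ndarray) -> int:
    n = a.shape[0]
    m = b.shape[0]
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    for i in range(n):
        ai = a[i]
        for j in range(m):
            if ai == b[j]:
                cur[j + 1] = prev[j] + 1
            else:
                pj = prev[j + 1]
                cj = cur[j]
                cur[j + 1] = pj if pj >= cj else cj
        prev, cur = cur, prev
    return prev[m]
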