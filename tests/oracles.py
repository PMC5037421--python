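"""Independent reference implementations used only as test oracles.

Everything here is deliberately naive and kept separate from the package:
brute-force LCS, textbook Gotoh with terminal gap penalties, single- and
average-linkage agglomeration by repeated matrix scans, gap-run
classification by string scanning, and exhaustive enumeration of monotone
column matchings.
"""

from __future__ import annotations

import itertools

import numpy as np

NEG = -1.0e30


def lcs_exhaustive(a: str, b: str) -> int:
    """LCS by enumerating all subsequences of the shorter string."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for r in range(len(short), 0, -1):
        for comb in itertools.combinations(short, r):
            sub = "".join(comb)
            it = iter(long_)
            if all(ch in it for ch in sub):
                return r
    return best


def gotoh_terminal(a, b, score_fn, go, ge, to, te) -> float:
    """Affine alignment score, terminal runs priced To/Te, maximization."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    IX = np.full((n + 1, m + 1), NEG)
    IY = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        IX[0, j] = (M[0, j - 1] + to) if j == 1 else (IX[0, j - 1] + te)
    for i in range(1, n + 1):
        IY[i, 0] = (M[i - 1, 0] + to) if i == 1 else (IY[i - 1, 0] + te)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], IX[i - 1, j - 1], IY[i - 1, j - 1]) + score_fn(
                a[i - 1], b[j - 1]
            )
            og, eg = (to, te) if i == n else (go, ge)
            IX[i, j] = max(M[i, j - 1] + og, IY[i, j - 1] + og, IX[i, j - 1] + eg)
            og, eg = (to, te) if j == m else (go, ge)
            IY[i, j] = max(M[i - 1, j] + og, IX[i - 1, j] + og, IY[i - 1, j] + eg)
    return float(max(M[n, m], IX[n, m], IY[n, m]))


def linkage_heights(d: np.ndarray, method: str) -> list[float]:
    """Merge heights of single/average linkage by naive agglomeration."""
    k = len(d)
    clusters: list[list[int]] = [[i] for i in range(k)]
    heights = []
    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                vals = [d[x, y] for x in clusters[ai] for y in clusters[bi]]
                h = min(vals) if method == "single" else float(np.mean(vals))
                if best is None or h < best[0]:
                    best = (h, ai, bi)
        h, ai, bi = best
        heights.append(h)
        clusters[ai] = clusters[ai] + clusters[bi]
        del clusters[bi]
    return heights


def classify_gaps(row: str) -> list[str]:
    """Per-column label of a realized row: residue letter or one of
    To/Te/Go/Ge by run position (first gap of a maximal run is an open,
    terminal when the run touches either row end)."""
    out = []
    n = len(row)
    i = 0
    while i < n:
        if row[i] not in "-.":
            out.append(row[i])
            i += 1
            continue
        j = i
        while j < n and row[j] in "-.":
            j += 1
        terminal = i == 0 or j == n
        out.append("To" if terminal else "Go")
        out.extend(["Te" if terminal else "Ge"] * (j - i - 1))
        i = j
    return out


def pairwise_row_score(ra: str, rb: str, score_fn, pen: dict) -> float:
    """Score of two realized rows under the typed gap model."""
    ta, tb = classify_gaps(ra), classify_gaps(rb)
    total = 0.0
    for x, y in zip(ta, tb):
        xg, yg = x in pen, y in pen
        if xg and yg:
            continue
        if xg:
            total += pen[x]
        elif yg:
            total += pen[y]
        else:
            total += score_fn(x, y)
    return total


def alignment_score(rows: list[str], score_fn, pen: dict) -> float:
    total = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            total += pairwise_row_score(rows[i], rows[j], score_fn, pen)
    return total


def enumerate_matchings(n1: int, n2: int):
    """All monotone column matchings without double-gap columns, as op
    strings over M (match), X (gap in X), Y (gap in Y)."""

    def rec(i, j, prev):
        if i == n1 and j == n2:
            yield ""
            return
        if i < n1 and j < n2:
            for rest in rec(i + 1, j + 1, "M"):
                yield "M" + rest
        if j < n2 and prev != "Y":
            for rest in rec(i, j + 1, "X"):
                yield "X" + rest
        if i < n1 and prev != "X":
            for rest in rec(i + 1, j, "Y"):
                yield "Y" + rest

    yield from rec(0, 0, "")


def apply_matching(rows_x: list[str], rows_y: list[str], ops: str) -> list[str]:
    """Realize a merged alignment from per-profile rows and an op string."""
    out_x = ["" for _ in rows_x]
    out_y = ["" for _ in rows_y]
    xi = yi = 0
    for op in ops:
        if op == "M":
            for r, row in enumerate(rows_x):
                out_x[r] += row[xi]
            for r, row in enumerate(rows_y):
                out_y[r] += row[yi]
            xi += 1
            yi += 1
        elif op == "X":
            for r in range(len(rows_x)):
                out_x[r] += "-"
            for r, row in enumerate(rows_y):
                out_y[r] += row[yi]
            yi += 1
        else:
            for r, row in enumerate(rows_x):
                out_x[r] += row[xi]
            for r in range(len(rows_y)):
                out_y[r] += "-"
            xi += 1
    return out_x + out_y
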