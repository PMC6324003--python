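"""Affine-gap pairwise alignment kernel (Gotoh) with a deterministic traceback.

The dynamic program keeps the usual three states per cell:

* ``M`` — last column is a match/mismatch (consumes one residue of each),
* ``X`` — last column is a gap in the *target* (consumes a query residue),
* ``Y`` — last column is a gap in the *query* (consumes a target residue).

A gap of length L costs ``gap_open + L * gap_extend`` (both are <= 0 under the
score convention).  In ``semiglobal`` mode leading and trailing gap runs are
free in either sequence (overlap alignment); in ``global`` mode they are
penalised as usual.

The traceback is fully deterministic: among equal-scoring predecessors it
prefers a match/mismatch step over either gap step, and a gap in the query
over a gap in the target; in semiglobal mode the end cell is selected by a
fixed scan (full corner first, then longer alignments first).

The matrix fill is numba-jitted; the traceback is plain Python (O(n+m)).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30
_EPS = 1.0e-6

# state codes used during traceback
_M, _Y, _X = 0, 1, 2


@njit(cache=True)
def _fill(q, t, q_amb, match, mismatch, gap_open, gap_extend, semiglobal):
    n = q.shape[0]
    m = t.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if semiglobal else gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if semiglobal else gap_open + j * gap_extend
    for i in range(1, n + 1):
        qi = q[i - 1]
        ambi = q_amb[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == t[j - 1] and not ambi) else mismatch
            prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
            M[i, j] = prev + s

            a = M[i - 1, j] + gap_open + gap_extend
            b = X[i - 1, j] + gap_extend
            c = Y[i - 1, j] + gap_open + gap_extend
            best = a
            if b > best:
                best = b
            if c > best:
                best = c
            X[i, j] = best

            a = M[i, j - 1] + gap_open + gap_extend
            b = Y[i, j - 1] + gap_extend
            c = X[i, j - 1] + gap_open + gap_extend
            best = a
            if b > best:
                best = b
            if c > best:
                best = c
            Y[i, j] = best
    return M, X, Y


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _EPS


def _select_end(M, X, Y, n, m, semiglobal):
    """End cell + state for the traceback.

    Global mode always ends at (n, m).  Semiglobal mode scans the corner,
    then the last column bottom-up, then the last row right-to-left, taking
    the first strictly-better score; at equal score within a cell the state
    preference is M > Y > X.
    """
    if semiglobal:
        cells = [(n, m)]
        cells += [(i, m) for i in range(n - 1, -1, -1)]
        cells += [(n, j) for j in range(m - 1, -1, -1)]
    else:
        cells = [(n, m)]
    best_score = NEG_INF
    best = (n, m, _M)
    for i, j in cells:
        for state, mat in ((_M, M), (_Y, Y), (_X, X)):
            v = mat[i, j]
            if v > best_score + _EPS:
                best_score = v
                best = (i, j, state)
    return best_score, best


def align_core(q_codes, t_codes, q_amb, match, mismatch, gap_open, gap_extend, semiglobal):
    """Run the DP and return ``(score, pairs)``.

    ``pairs`` is the list of 1-based ``(query_pos, target_pos)`` aligned
    columns (matches and mismatches), strictly increasing in both coordinates.
    """
    M, X, Y = _fill(
        q_codes, t_codes, q_amb,
        float(match), float(mismatch), float(gap_open), float(gap_extend),
        semiglobal,
    )
    n, m = q_codes.shape[0], t_codes.shape[0]
    score, (i, j, state) = _select_end(M, X, Y, n, m, semiglobal)

    go, ge = gap_open, gap_extend
    pairs: list[tuple[int, int]] = []
    while True:
        if i == 0 and j == 0:
            break
        if semiglobal and (i == 0 or j == 0):
            break  # free leading gap run
        if state == _M:
            s = match if (q_codes[i - 1] == t_codes[j - 1] and not q_amb[i - 1]) else mismatch
            pairs.append((i, j))
            want = M[i, j] - s
            if _close(M[i - 1, j - 1], want):
                state = _M
            elif _close(Y[i - 1, j - 1], want):
                state = _Y
            else:
                state = _X
            i -= 1
            j -= 1
        elif state == _X:  # gap in target, consumed q[i]
            v = X[i, j]
            if _close(M[i - 1, j] + go + ge, v):
                state = _M
            elif _close(Y[i - 1, j] + go + ge, v):
                state = _Y
            else:
                state = _X
            i -= 1
        else:  # _Y: gap in query, consumed t[j]
            v = Y[i, j]
            if _close(M[i, j - 1] + go + ge, v):
                state = _M
            elif _close(Y[i, j - 1] + ge, v):
                state = _Y
            else:
                state = _X
            j -= 1
    pairs.reverse()
    return float(score), pairs
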