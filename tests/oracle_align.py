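"""Independent alignment oracles used by the tests.

``brute_force_score`` enumerates every monotone alignment path (diagonal /
query-gap / target-gap moves) without memoisation and scores each with the
affine-gap model, so it shares no code path with the production dynamic
program.  Feasible for sequences up to ~8 residues.

``biopython_aligner`` configures Bio.Align.PairwiseAligner to the package's
scoring scheme as a second, library-grade cross-check at realistic lengths.
"""

from __future__ import annotations

from Bio import Align


def _score_path(path: str, q: str, t: str, params, semiglobal: bool) -> float:
    # leading/trailing maximal uniform gap runs are free in semiglobal mode
    lead = 0
    if semiglobal and path and path[0] in "UL":
        while lead < len(path) and path[lead] == path[0]:
            lead += 1
    trail = 0
    if semiglobal and path and path[-1] in "UL":
        while trail < len(path) - lead and path[len(path) - 1 - trail] == path[-1]:
            trail += 1
    score = 0.0
    i = j = 0
    prev_gap = None
    for idx, mv in enumerate(path):
        scored = lead <= idx < len(path) - trail
        if mv == "D":
            if scored:
                score += params.match_score if q[i] == t[j] else params.mismatch_score
            i += 1
            j += 1
            prev_gap = None
        else:
            if scored:
                score += params.gap_extend
                if prev_gap != mv or idx == lead:
                    score += params.gap_open
            prev_gap = mv
            if mv == "U":
                i += 1
            else:
                j += 1
    return score


def brute_force_score(q: str, t: str, params) -> float:
    """Optimal alignment score by exhaustive path enumeration."""
    semiglobal = params.mode == "semiglobal"
    n, m = len(q), len(t)
    best = [-1.0e30]

    def rec(path: str, i: int, j: int) -> None:
        if i == n and j == m:
            s = _score_path(path, q, t, params, semiglobal)
            if s > best[0]:
                best[0] = s
            return
        if i < n and j < m:
            rec(path + "D", i + 1, j + 1)
        if i < n:
            rec(path + "U", i + 1, j)
        if j < m:
            rec(path + "L", i, j + 1)

    rec("", 0, 0)
    return best[0]


def biopython_aligner(params) -> Align.PairwiseAligner:
    """PairwiseAligner configured to the package's scoring scheme."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = params.match_score
    a.mismatch_score = params.mismatch_score
    a.open_gap_score = params.gap_open + params.gap_extend
    a.extend_gap_score = params.gap_extend
    if params.mode == "semiglobal":
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    return a


def biopython_identity_overlap(query: str, target: str, params) -> tuple[float, int]:
    """(identity, aligned column count) of one optimal Biopython alignment.

    Identity is identical aligned columns over aligned columns, matching the
    package's definition.
    """
    aln = biopython_aligner(params).align(query, target)[0]
    n_cols = 0
    n_ident = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for k in range(qe - qs):
            n_cols += 1
            n_ident += query[qs + k] == target[ts + k]
    return (n_ident / n_cols if n_cols else 0.0), n_cols
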