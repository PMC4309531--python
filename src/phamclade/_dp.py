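"""Gotoh-style affine-gap dynamic programming on a precomputed cell-score matrix.

One kernel serves every alignment flavour in the package: residue-vs-residue
(pairwise homology), profile-vs-sequence (remote-homolog search) and
profile-vs-profile (progressive MSA merges).  The caller supplies the
(n, m) matrix of per-cell match scores; the kernel only knows about gaps and
which sequence ends are free.

State encoding: 0 = M (match), 1 = E (vertical run, gap in the column
sequence), 2 = F (horizontal run, gap in the row sequence), 3 = origin.
Tie-breaks are deterministic: diagonal over vertical over horizontal, and the
full-corner end cell over earlier free-overhang ends.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18

M_STATE, E_STATE, F_STATE, START = 0, 1, 2, 3


@njit(cache=True)
def _fill(S, gap_open, gap_extend, free_rows, free_cols):
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    PM = np.full((n + 1, m + 1), START, dtype=np.int8)
    PE = np.full((n + 1, m + 1), START, dtype=np.int8)
    PF = np.full((n + 1, m + 1), START, dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        E[i, 0] = 0.0 if free_rows else gap_open + (i - 1) * gap_extend
        PE[i, 0] = START if i == 1 else E_STATE
    for j in range(1, m + 1):
        F[0, j] = 0.0 if free_cols else gap_open + (j - 1) * gap_extend
        PF[0, j] = START if j == 1 else F_STATE
    both_free = free_rows and free_cols
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match: predecessor is any state at (i-1, j-1); with both ends
            # free the alignment may also open here, the skipped prefixes of
            # both sequences being free overhangs
            best = M[i - 1, j - 1]
            ptr = M_STATE
            if E[i - 1, j - 1] > best:
                best = E[i - 1, j - 1]
                ptr = E_STATE
            if F[i - 1, j - 1] > best:
                best = F[i - 1, j - 1]
                ptr = F_STATE
            if both_free and 0.0 > best:
                best = 0.0
                ptr = START
            M[i, j] = best + S[i - 1, j - 1]
            PM[i, j] = ptr
            # vertical run (consumes row residue i, gap in column sequence)
            best = M[i - 1, j] + gap_open
            ptr = M_STATE
            if E[i - 1, j] + gap_extend > best:
                best = E[i - 1, j] + gap_extend
                ptr = E_STATE
            if F[i - 1, j] + gap_open > best:
                best = F[i - 1, j] + gap_open
                ptr = F_STATE
            E[i, j] = best
            PE[i, j] = ptr
            # horizontal run (consumes column residue j, gap in row sequence)
            best = M[i, j - 1] + gap_open
            ptr = M_STATE
            if E[i, j - 1] + gap_open > best:
                best = E[i, j - 1] + gap_open
                ptr = E_STATE
            if F[i, j - 1] + gap_extend > best:
                best = F[i, j - 1] + gap_extend
                ptr = F_STATE
            F[i, j] = best
            PF[i, j] = ptr
    return M, E, F, PM, PE, PF


@njit(cache=True)
def _pick_end(M, E, F, free_rows, free_cols):
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    # full corner, any state
    best = M[n, m]
    ei, ej, estate = n, m, M_STATE
    if E[n, m] > best:
        best, estate = E[n, m], E_STATE
    if F[n, m] > best:
        best, estate = F[n, m], F_STATE
    if free_rows:
        # end anywhere in the last column; the remaining rows are a free
        # terminal vertical run
        for i in range(n - 1, -1, -1):
            if M[i, m] > best:
                best, ei, ej, estate = M[i, m], i, m, M_STATE
            if F[i, m] > best:
                best, ei, ej, estate = F[i, m], i, m, F_STATE
    if free_cols:
        for j in range(m - 1, -1, -1):
            if M[n, j] > best:
                best, ei, ej, estate = M[n, j], n, j, M_STATE
            if E[n, j] > best:
                best, ei, ej, estate = E[n, j], n, j, E_STATE
    if free_rows and free_cols:
        # alignment may also end anywhere, the remaining suffixes of both
        # sequences being free trailing overhangs
        for i in range(n - 1, -1, -1):
            for j in range(m - 1, -1, -1):
                if M[i, j] > best:
                    best, ei, ej, estate = M[i, j], i, j, M_STATE
        if 0.0 > best:
            # empty alignment: both sequences are pure terminal overhang
            best, ei, ej, estate = 0.0, 0, 0, M_STATE
    return best, ei, ej, estate


DIAG, VERT, HORIZ = 0, 1, 2


def semiglobal_align(S, gap_open, gap_extend, free_rows=True, free_cols=True):
    """Optimal affine-gap alignment over cell-score matrix ``S``.

    Returns ``(score, moves, core_start, core_end)`` where ``moves`` is the
    full move sequence (0 diagonal, 1 vertical, 2 horizontal) covering both
    sequences end to end, and ``moves[core_start:core_end]`` excludes the
    terminal free-overhang runs.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    n, m = S.shape
    M, E, F, PM, PE, PF = _fill(S, float(gap_open), float(gap_extend), free_rows, free_cols)
    score, ei, ej, estate = _pick_end(M, E, F, free_rows, free_cols)

    moves = []
    # trailing overhang (free or simply beyond the chosen end cell)
    moves.extend([HORIZ] * (m - ej))
    moves.extend([VERT] * (n - ei))
    i, j, state = ei, ej, estate
    while not (i == 0 and j == 0):
        if state == START:
            # leading boundary run straight back to the origin
            moves.extend([VERT] * i)
            moves.extend([HORIZ] * j)
            i = j = 0
        elif state == M_STATE:
            moves.append(DIAG)
            state = PM[i, j]
            i, j = i - 1, j - 1
        elif state == E_STATE:
            moves.append(VERT)
            state = PE[i, j]
            i -= 1
        else:
            moves.append(HORIZ)
            state = PF[i, j]
            j -= 1
    moves.reverse()
    # terminal gap runs (the end-gap overhangs) are excluded from the core span
    lead = 0
    while lead < len(moves) and moves[lead] != DIAG:
        lead += 1
    tail = len(moves)
    while tail > lead and moves[tail - 1] != DIAG:
        tail -= 1
    return float(score), moves, lead, tail


def semiglobal_score(S, gap_open, gap_extend, free_rows=True, free_cols=True):
    """Score-only variant (no traceback)."""
    S = np.ascontiguousarray(S, dtype=np.float64)
    M, E, F, _, _, _ = _fill(S, float(gap_open), float(gap_extend), free_rows, free_cols)
    score, _, _, _ = _pick_end(M, E, F, free_rows, free_cols)
    return float(score)
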