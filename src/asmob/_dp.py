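"""Numba dynamic-programming kernels for pairwise and profile alignment.

Both kernels use the BLAST gap convention: a gap of length g costs
open + g*extend.  Traceback tie-break order is diagonal > up > left,
and gap runs are closed as early as possible; this makes every alignment
deterministic for a given input.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=False)
def sw_align(q, s, sub, gap_open, gap_extend):
    """Smith-Waterman local alignment with affine gaps.

    Returns (score, ops, n_ops, qend, send) where ops (reversed order)
    holds 1 = aligned pair, 2 = gap in subject (consumes query),
    3 = gap in query (consumes subject); qend/send are 1-based inclusive
    end coordinates of the optimal local alignment (0 if score is 0).
    """
    m = q.shape[0]
    n = s.shape[0]
    go = gap_open + gap_extend
    ge = gap_extend
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    ptr = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - go
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            f = H[i - 1, j] - go
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            d = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            h = d
            p = 1
            if f > h:
                h = f
                p = 2
            if e > h:
                h = e
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    ops = np.zeros(m + n, np.uint8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = F (up), 2 = E (left)
    while i > 0 or j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                ops[k] = 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 2
            k += 1
            if F[i, j] == H[i - 1, j] - go:
                state = 0
            i -= 1
        else:
            ops[k] = 3
            k += 1
            if E[i, j] == H[i, j - 1] - go:
                state = 0
            j -= 1
    return best, ops, k, bi, bj


@njit(cache=False)
def nw_profile(cell, gap_open, gap_extend):
    """Global Needleman-Wunsch with affine gaps on precomputed cell scores.

    ``cell[i, j]`` is the score of aligning row-profile column i against
    column j.  Returns (score, ops, n_ops) with ops encoded as in
    :func:`sw_align` (reversed order).
    """
    m = cell.shape[0]
    n = cell.shape[1]
    go = gap_open + gap_extend
    ge = gap_extend
    neg = -1e30
    H = np.full((m + 1, n + 1), neg)
    E = np.full((m + 1, n + 1), neg)
    F = np.full((m + 1, n + 1), neg)
    ptr = np.zeros((m + 1, n + 1), np.uint8)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -go - (j - 1) * ge
        H[0, j] = E[0, j]
        ptr[0, j] = 3
    for i in range(1, m + 1):
        F[i, 0] = -go - (i - 1) * ge
        H[i, 0] = F[i, 0]
        ptr[i, 0] = 2
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - go
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            f = H[i - 1, j] - go
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            d = H[i - 1, j - 1] + cell[i - 1, j - 1]
            h = d
            p = 1
            if f > h:
                h = f
                p = 2
            if e > h:
                h = e
                p = 3
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            ptr[i, j] = p
    ops = np.zeros(m + n, np.uint8)
    k = 0
    i = m
    j = n
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if i == 0:
                ops[k] = 3
                k += 1
                j -= 1
                continue
            if j == 0:
                ops[k] = 2
                k += 1
                i -= 1
                continue
            p = ptr[i, j]
            if p == 1:
                ops[k] = 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 2
            k += 1
            if i == 1 or F[i, j] == H[i - 1, j] - go:
                state = 0
            i -= 1
        else:
            ops[k] = 3
            k += 1
            if j == 1 or E[i, j] == H[i, j - 1] - go:
                state = 0
            j -= 1
    return H[m, n], ops, k
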