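"""Numba kernels for affine-gap dynamic programming.

All kernels work on integer-encoded sequences (A=0, C=1, G=2, T=3, N=4).
A gap of length L costs ``gap_open + L * gap_extend``.  N scores as a
mismatch against everything, including another N.

Traceback pointers are bit-packed into one uint8 per cell:

* bits 0-1: H source — 0 stop, 1 diagonal, 2 up (from F), 3 left (from E)
* bit 2: E extended (gap in a continues)
* bit 3: F extended (gap in b continues)

Tie-breaking is fixed: diagonal beats up beats left beats stop, so
alignments are bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(2**30))


@njit(cache=True)
def sw_fill(a, b, match, mismatch, gap_open, gap_extend, forbidden):
    """Fill Smith-Waterman matrices; return (best, bi, bj, ptr).

    ``forbidden`` is a uint8 (len(a), len(b)) matrix; a 1 bars the diagonal
    transition through that residue pair (Waterman-Eggert declumping).
    """
    n, m = len(a), len(b)
    go = gap_open + gap_extend
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    h_prev = np.zeros(m + 1, dtype=np.int32)
    h_cur = np.zeros(m + 1, dtype=np.int32)
    f_row = np.full(m + 1, NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        e = NEG
        h_cur[0] = 0
        ai = a[i - 1]
        prow = ptr[i]
        for j in range(1, m + 1):
            p = np.uint8(0)
            # E: gap in a (left move)
            e_open = h_cur[j - 1] - go
            e_ext = e - gap_extend
            if e_open >= e_ext:
                e = e_open
            else:
                e = e_ext
                p |= 4
            # F: gap in b (up move)
            f_open = h_prev[j] - go
            f_ext = f_row[j] - gap_extend
            if f_open >= f_ext:
                f_row[j] = f_open
            else:
                f_row[j] = f_ext
                p |= 8
            # H: diagonal / up / left / zero, fixed priority
            bj_ = b[j - 1]
            if forbidden[i - 1, j - 1]:
                diag = NEG
            else:
                s = match if (ai == bj_ and ai < 4) else mismatch
                diag = h_prev[j - 1] + s
            h = np.int32(0)
            src = np.uint8(0)
            if diag >= h:
                h = diag
                src = 1
            if f_row[j] > h:
                h = f_row[j]
                src = 2
            if e > h:
                h = e
                src = 3
            if h == 0:
                src = 0
            h_cur[j] = h
            prow[j] = p | src
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best, bi, bj, ptr


@njit(cache=True)
def sw_score_only(a, b, match, mismatch, gap_open, gap_extend):
    """Best local alignment score only (no traceback storage)."""
    n, m = len(a), len(b)
    go = gap_open + gap_extend
    h_prev = np.zeros(m + 1, dtype=np.int32)
    h_cur = np.zeros(m + 1, dtype=np.int32)
    f_row = np.full(m + 1, NEG, dtype=np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        e = NEG
        h_cur[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_open = h_cur[j - 1] - go
            e_ext = e - gap_extend
            e = e_open if e_open >= e_ext else e_ext
            f_open = h_prev[j] - go
            f_ext = f_row[j] - gap_extend
            f_row[j] = f_open if f_open >= f_ext else f_ext
            bj_ = b[j - 1]
            s = match if (ai == bj_ and ai < 4) else mismatch
            diag = h_prev[j - 1] + s
            h = np.int32(0)
            if diag > h:
                h = diag
            if f_row[j] > h:
                h = f_row[j]
            if e > h:
                h = e
            h_cur[j] = h
            if h > best:
                best = h
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best


@njit(cache=True)
def nw_fill(a, b, match, mismatch, gap_open, gap_extend):
    """Fill global (Needleman-Wunsch) matrices with penalized end gaps.

    Returns (score, ptr); traceback starts at (n, m) and stops at (0, 0).
    """
    n, m = len(a), len(b)
    go = gap_open + gap_extend
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    h_prev = np.zeros(m + 1, dtype=np.int32)
    h_cur = np.zeros(m + 1, dtype=np.int32)
    f_row = np.full(m + 1, NEG, dtype=np.int32)
    for j in range(1, m + 1):
        h_prev[j] = -(go + (j - 1) * gap_extend)
        ptr[0, j] = 3 | (0 if j == 1 else 4)
    for i in range(1, n + 1):
        e = NEG
        h_cur[0] = -(go + (i - 1) * gap_extend)
        ptr[i, 0] = 2 | (0 if i == 1 else 8)
        ai = a[i - 1]
        prow = ptr[i]
        for j in range(1, m + 1):
            p = np.uint8(0)
            e_open = h_cur[j - 1] - go
            e_ext = e - gap_extend
            if e_open >= e_ext:
                e = e_open
            else:
                e = e_ext
                p |= 4
            f_open = h_prev[j] - go
            f_ext = f_row[j] - gap_extend
            if f_open >= f_ext:
                f_row[j] = f_open
            else:
                f_row[j] = f_ext
                p |= 8
            bj_ = b[j - 1]
            s = match if (ai == bj_ and ai < 4) else mismatch
            diag = h_prev[j - 1] + s
            h = diag
            src = np.uint8(1)
            if f_row[j] > h:
                h = f_row[j]
                src = 2
            if e > h:
                h = e
                src = 3
            h_cur[j] = h
            prow[j] = p | src
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return h_prev[m], ptr
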