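"""Numba dynamic-programming kernels for pairwise and profile alignment.

Two kernels live here:

``nw_affine``
    Needleman-Wunsch global alignment with affine gaps (Gotoh three-state
    recursion). Terminal gaps are penalized. Traceback ties are broken
    deterministically: diagonal (match) is preferred over up (gap in the
    second sequence) over left (gap in the first sequence).

``sw_pssm``
    Smith-Waterman local alignment of a position-specific score matrix
    against a residue index sequence, affine gaps, scores in whatever unit
    the PSSM is expressed in (bits throughout this package).
"""
from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18
_EPS = 1e-9


@njit(cache=True)
def nw_affine(a, b, sub, gap_open, gap_ext):  # pragma: no cover - numba
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b: consume a ("up")
    Y = np.full((n + 1, m + 1), NEG)  # gap in a: consume b ("left")
    M[0, 0] = 0.0
    oe = gap_open + gap_ext
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + gap_ext * i)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + gap_ext * j)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[ai, b[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - oe, X[i - 1, j] - gap_ext, Y[i - 1, j] - oe)
            Y[i, j] = max(M[i, j - 1] - oe, X[i, j - 1] - oe, Y[i, j - 1] - gap_ext)

    best = max(M[n, m], X[n, m], Y[n, m])
    if M[n, m] >= best - _EPS:
        state = 0
    elif X[n, m] >= best - _EPS:
        state = 1
    else:
        state = 2

    cap = n + m
    ra = np.empty(cap, np.int64)
    rb = np.empty(cap, np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ra[k] = i - 1
            rb[k] = j - 1
            k += 1
            v = M[i, j] - sub[a[i - 1], b[j - 1]]
            if M[i - 1, j - 1] >= v - _EPS:
                state = 0
            elif X[i - 1, j - 1] >= v - _EPS:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            ra[k] = i - 1
            rb[k] = -1
            k += 1
            v = X[i, j]
            if M[i - 1, j] - oe >= v - _EPS:
                state = 0
            elif X[i - 1, j] - gap_ext >= v - _EPS:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            ra[k] = -1
            rb[k] = j - 1
            k += 1
            v = Y[i, j]
            if M[i, j - 1] - oe >= v - _EPS:
                state = 0
            elif X[i, j - 1] - oe >= v - _EPS:
                state = 1
            else:
                state = 2
            j -= 1

    out_a = ra[:k][::-1].copy()
    out_b = rb[:k][::-1].copy()
    return best, out_a, out_b


@njit(cache=True)
def sw_pssm(pssm, seq, gap_open, gap_ext):  # pragma: no cover - numba
    """Best local alignment of ``pssm`` (L x 21) against ``seq``.

    Returns (score, prof_start, prof_end, seq_start, seq_end), 1-based
    inclusive coordinates. A non-positive best score yields the degenerate
    region (1, 1, 1, 1).
    """
    L = pssm.shape[0]
    m = seq.shape[0]
    H = np.zeros((L + 1, m + 1))
    E = np.full((L + 1, m + 1), NEG)
    F = np.full((L + 1, m + 1), NEG)
    oe = gap_open + gap_ext
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] - oe, E[i - 1, j] - gap_ext)
            F[i, j] = max(H[i, j - 1] - oe, F[i, j - 1] - gap_ext)
            v = H[i - 1, j - 1] + pssm[i - 1, seq[j - 1]]
            if E[i, j] > v:
                v = E[i, j]
            if F[i, j] > v:
                v = F[i, j]
            if v < 0.0:
                v = 0.0
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j

    if best <= 0.0:
        return 0.0, 1, 1, 1, 1

    i, j = bi, bj
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            v = H[i, j]
            if v <= _EPS:
                break
            s = pssm[i - 1, seq[j - 1]]
            if abs(H[i - 1, j - 1] + s - v) <= _EPS:
                i -= 1
                j -= 1
            elif abs(E[i, j] - v) <= _EPS:
                state = 1
            elif abs(F[i, j] - v) <= _EPS:
                state = 2
            else:
                break
        elif state == 1:
            v = E[i, j]
            if abs(H[i - 1, j] - oe - v) <= _EPS:
                state = 0
            i -= 1
        else:
            v = F[i, j]
            if abs(H[i, j - 1] - oe - v) <= _EPS:
                state = 0
            j -= 1
    return best, i + 1, bi, j + 1, bj
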