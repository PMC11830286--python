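"""Numba dynamic-programming kernels.

Three-layer (match / vertical-gap / horizontal-gap) affine-gap recurrences in
the Gotoh formulation, plus the profile-HMM forward recursion in odds-ratio
space with running rescaling.  Tie-breaks are fixed everywhere (predecessor
preference M > X > Y, i.e. diagonal > up > left) so tracebacks are
byte-reproducible.

Gap cost convention: a gap of length L costs ``gap_open + L * gap_extend``
(the opening residue is charged both terms).

Pointer codes: 0 = came from M, 1 = from X (up), 2 = from Y (left),
3 = alignment start / boundary.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def fill_global(S, gap_open, gap_extend, free_ends):
    """Affine-gap global DP over score matrix S (m x n).

    Returns the three score layers and their pointer layers, each (m+1, n+1).
    """
    m, n = S.shape
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in b: consume a[i-1], move up
    Y = np.full((m + 1, n + 1), NEG)  # gap in a: consume b[j-1], move left
    pM = np.full((m + 1, n + 1), 3, dtype=np.int8)
    pX = np.full((m + 1, n + 1), 3, dtype=np.int8)
    pY = np.full((m + 1, n + 1), 3, dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = 0.0 if free_ends else -(gap_open + i * gap_extend)
        pX[i, 0] = 3 if i == 1 else 1
    for j in range(1, n + 1):
        Y[0, j] = 0.0 if free_ends else -(gap_open + j * gap_extend)
        pY[0, j] = 3 if j == 1 else 2
    oe = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # M: diagonal; predecessor preference M > X > Y
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = ptr
            # X: gap in b (up)
            best = M[i - 1, j] - oe
            ptr = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                ptr = 1
            if Y[i - 1, j] - oe > best:
                best = Y[i - 1, j] - oe
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr
            # Y: gap in a (left)
            best = M[i, j - 1] - oe
            ptr = 0
            if X[i, j - 1] - oe > best:
                best = X[i, j - 1] - oe
                ptr = 1
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr
    return M, X, Y, pM, pX, pY


@njit(cache=True)
def fill_local(S, gap_open, gap_extend):
    """Smith–Waterman affine-gap DP.  Returns layers, pointers and best cell."""
    m, n = S.shape
    M = np.zeros((m + 1, n + 1))
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    pM = np.full((m + 1, n + 1), 3, dtype=np.int8)
    pX = np.full((m + 1, n + 1), 3, dtype=np.int8)
    pY = np.full((m + 1, n + 1), 3, dtype=np.int8)
    M[0, :] = NEG
    M[:, 0] = NEG
    M[0, 0] = NEG
    oe = gap_open + gap_extend
    best_score = 0.0
    best_i = 0
    best_j = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # prefer extension (M > X > Y) over a fresh start
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            if best < 0.0:
                best = 0.0
                ptr = 3
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = ptr

            best = M[i - 1, j] - oe
            ptr = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                ptr = 1
            if Y[i - 1, j] - oe > best:
                best = Y[i - 1, j] - oe
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr

            best = M[i, j - 1] - oe
            ptr = 0
            if X[i, j - 1] - oe > best:
                best = X[i, j - 1] - oe
                ptr = 1
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr

            if M[i, j] > best_score:  # strict: earliest best cell in scan order
                best_score = M[i, j]
                best_i = i
                best_j = j
    return M, X, Y, pM, pX, pY, best_score, best_i, best_j


@njit(cache=True)
def local_score(S, gap_open, gap_extend):
    """Smith–Waterman best score only (no pointers; used for bulk search)."""
    m, n = S.shape
    prevM = np.full(n + 1, NEG)
    prevX = np.full(n + 1, NEG)
    prevY = np.full(n + 1, NEG)
    curM = np.full(n + 1, NEG)
    curX = np.full(n + 1, NEG)
    curY = np.full(n + 1, NEG)
    oe = gap_open + gap_extend
    best_score = 0.0
    for i in range(1, m + 1):
        curM[0] = NEG
        curX[0] = NEG
        curY[0] = NEG
        for j in range(1, n + 1):
            b = prevM[j - 1]
            if prevX[j - 1] > b:
                b = prevX[j - 1]
            if prevY[j - 1] > b:
                b = prevY[j - 1]
            if b < 0.0:
                b = 0.0
            curM[j] = b + S[i - 1, j - 1]

            b = prevM[j] - oe
            if prevX[j] - gap_extend > b:
                b = prevX[j] - gap_extend
            if prevY[j] - oe > b:
                b = prevY[j] - oe
            curX[j] = b

            b = curM[j - 1] - oe
            if curX[j - 1] - oe > b:
                b = curX[j - 1] - oe
            if curY[j - 1] - gap_extend > b:
                b = curY[j - 1] - gap_extend
            curY[j] = b

            if curM[j] > best_score:
                best_score = curM[j]
        prevM, curM = curM, prevM
        prevX, curX = curX, prevX
        prevY, curY = curY, prevY
    return best_score


@njit(cache=True)
def forward_odds(odds, entry, exitp, tM, tI, tD, seq):
    """Profile-HMM forward in odds-ratio space.

    odds  : (L, 21) emission odds (match emission / background; X column = 1)
    entry : (L,)   B -> M_j probabilities
    exitp : (L,)   M_j -> E probabilities (exitp[L-1] == 1)
    tM    : (L, 3) core M_j -> {M_{j+1}, I_j, D_{j+1}} (normalised; scaled by 1-exitp)
    tI    : (L, 2) I_j -> {M_{j+1}, I_j}
    tD    : (L, 2) D_j -> {M_{j+1}, D_{j+1}}
    seq   : int8 residue indices

    Returns log2 of the summed path odds (flanking residues score odds 1),
    or -inf when no path has positive probability.
    """
    L = odds.shape[0]
    N = seq.shape[0]
    fM = np.zeros(L)
    fI = np.zeros(L)
    fD = np.zeros(L)
    nM = np.zeros(L)
    nI = np.zeros(L)
    nD = np.zeros(L)
    base = 1.0
    endacc = 0.0
    logscale = 0.0
    for i in range(N):
        x = seq[i]
        for j in range(L):
            v = entry[j] * base
            if j > 0:
                v += fM[j - 1] * (1.0 - exitp[j - 1]) * tM[j - 1, 0]
                v += fI[j - 1] * tI[j - 1, 0]
                v += fD[j - 1] * tD[j - 1, 0]
            nM[j] = v * odds[j, x]
            nI[j] = fM[j] * (1.0 - exitp[j]) * tM[j, 1] + fI[j] * tI[j, 1]
        # delete chain (consumes nothing): computed left-to-right at position i
        nD[0] = 0.0
        for j in range(1, L):
            nD[j] = nM[j - 1] * (1.0 - exitp[j - 1]) * tM[j - 1, 2] + nD[j - 1] * tD[j - 1, 1]
        for j in range(L):
            fM[j] = nM[j]
            fI[j] = nI[j]
            fD[j] = nD[j]
        e = fD[L - 1]
        for j in range(L):
            e += fM[j] * exitp[j]
        endacc += e
        # rescale to keep everything in float64 range
        s = endacc
        if base > s:
            s = base
        for j in range(L):
            if fM[j] > s:
                s = fM[j]
            if fI[j] > s:
                s = fI[j]
            if fD[j] > s:
                s = fD[j]
        if s > 1.0e100 or (0.0 < s < 1.0e-100):
            for j in range(L):
                fM[j] /= s
                fI[j] /= s
                fD[j] /= s
            endacc /= s
            base /= s
            logscale += math.log(s)
    if endacc <= 0.0:
        return -np.inf
    return (math.log(endacc) + logscale) / math.log(2.0)
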