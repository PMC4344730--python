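"""Affine-gap dynamic-programming kernels (numba-compiled).

Two kernels are provided: a global profile-profile aligner used for pairwise
and progressive multiple alignment, and a Smith-Waterman local aligner with
position masking used for homology scanning with suboptimal-hit extraction.

Conventions shared by both kernels:

* gap cost: opening a gap costs ``gap_open + gap_extend`` for its first
  column and ``gap_extend`` for each further column (end gaps in the global
  aligner are charged the same way);
* tie-breaking is deterministic: diagonal > up (gap in the second profile /
  subject) > left, evaluated with strict improvement so the first-listed
  move wins ties.

Alignments are returned as op-code paths: 0 = diagonal (consume both),
1 = up (consume first sequence only), 2 = left (consume second only).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8; every non-ACGT code maps to 4 (N-like)."""
    return np.array([_ENCODE.get(c, 4) for c in seq], dtype=np.int8)


def substitution_matrix(match: float, mismatch: float, n_score: float | None = None) -> np.ndarray:
    """5x5 scoring matrix over {A,C,G,T,N}; N scores ``n_score`` vs anything
    (default: the mismatch score)."""
    if n_score is None:
        n_score = mismatch
    m = np.full((5, 5), mismatch, dtype=np.float64)
    np.fill_diagonal(m, match)
    m[4, :] = n_score
    m[:, 4] = n_score
    m[4, 4] = n_score
    return m


@njit(cache=True)
def global_dp(S, gap_open, gap_extend):  # pragma: no cover - exercised via wrappers
    """Global affine alignment over a precomputed column-score matrix.

    S has shape (la, lb): S[i, j] is the score of aligning column i of the
    first profile with column j of the second.  Returns (score, ops) where
    ops is the op-code path from start to end.
    """
    la, lb = S.shape
    go = gap_open + gap_extend
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in second profile (up)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in first profile (left)
    # pointers: predecessor state 0/1/2; -1 marks origin
    pM = np.full((la + 1, lb + 1), -1, dtype=np.int8)
    pX = np.full((la + 1, lb + 1), -1, dtype=np.int8)
    pY = np.full((la + 1, lb + 1), -1, dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, lb + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # M: diagonal move; prefer M > X > Y predecessors
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
            # X: up move (consume first profile)
            best = M[i - 1, j] - go
            ptr = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                ptr = 1
            if Y[i - 1, j] - go > best:
                best = Y[i - 1, j] - go
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr
            # Y: left move (consume second profile)
            best = M[i, j - 1] - go
            ptr = 0
            if X[i, j - 1] - go > best:
                best = X[i, j - 1] - go
                ptr = 1
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr
    # final state: prefer M > X > Y
    score = M[la, lb]
    state = 0
    if X[la, lb] > score:
        score = X[la, lb]
        state = 1
    if Y[la, lb] > score:
        score = Y[la, lb]
        state = 2
    # traceback
    ops = np.empty(la + lb, dtype=np.int8)
    k = 0
    i, j = la, lb
    while i > 0 or j > 0:
        ops[k] = state
        if state == 0:
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
        k += 1
    return score, ops[:k][::-1].copy()


@njit(cache=True)
def local_dp(a, b, submat, gap_open, gap_extend, mask):  # pragma: no cover
    """Smith-Waterman local alignment of encoded sequences a vs b.

    ``mask`` is a boolean array over b; masked subject positions cannot be
    aligned (used for greedy suboptimal-hit extraction).  Returns
    (score, a_start, a_end, b_start, b_end, ops) with 0-based half-open
    coordinates; score 0 means no positive-scoring alignment exists.
    """
    la = a.shape[0]
    lb = b.shape[0]
    go = gap_open + gap_extend
    M = np.zeros((la + 1, lb + 1))
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    pM = np.full((la + 1, lb + 1), -1, dtype=np.int8)
    pX = np.full((la + 1, lb + 1), -1, dtype=np.int8)
    pY = np.full((la + 1, lb + 1), -1, dtype=np.int8)
    best_score = 0.0
    bi = 0
    bj = 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            if mask[j - 1]:
                M[i, j] = 0.0
                X[i, j] = NEG
                Y[i, j] = NEG
                continue
            s = submat[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            if best <= 0.0:
                best = 0.0
                ptr = -1  # local start
            M[i, j] = best + s
            pM[i, j] = ptr
            best = M[i - 1, j] - go
            ptr = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                ptr = 1
            if Y[i - 1, j] - go > best:
                best = Y[i - 1, j] - go
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr
            best = M[i, j - 1] - go
            ptr = 0
            if X[i, j - 1] - go > best:
                best = X[i, j - 1] - go
                ptr = 1
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr
            if M[i, j] > best_score:
                best_score = M[i, j]
                bi = i
                bj = j
    ops = np.empty(la + lb, dtype=np.int8)
    if best_score <= 0.0:
        return 0.0, 0, 0, 0, 0, ops[:0]
    k = 0
    i, j = bi, bj
    state = 0
    while True:
        ops[k] = state
        k += 1
        if state == 0:
            nxt = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            nxt = pX[i, j]
            i -= 1
        else:
            nxt = pY[i, j]
            j -= 1
        if nxt == -1:
            break
        state = nxt
    return best_score, i, bi, j, bj, ops[:k][::-1].copy()
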