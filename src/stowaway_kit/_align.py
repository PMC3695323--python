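"""Low-level dynamic-programming kernels (numba-compiled).

Three kernels live here: affine-gap Needleman-Wunsch (global, end gaps
penalized), affine-gap Smith-Waterman (local), and the Nussinov
maximum-base-pairing recursion used for the hairpin score.  A gap of length
k costs ``gap_open + (k-1) * gap_extend``.

Sequences are encoded as uint8: A=0, C=1, G=2, T=3, N=4.  N never matches
anything (scored as a mismatch, never paired).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i

NEG = -1.0e18


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _nw_fill(a, b, match, mismatch, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        pX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        pY[0, j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != 4) else mismatch
            # M: diagonal
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            pM[i, j] = ptr
            # X: vertical (gap in b)
            best = M[i - 1, j] + gap_open
            ptr = 0
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                ptr = 1
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr
            # Y: horizontal (gap in a)
            best = M[i, j - 1] + gap_open
            ptr = 0
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                ptr = 1
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr
    # traceback from the best terminal state
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    ai_idx = np.empty(n + m, dtype=np.int64)
    bi_idx = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            nxt = pM[i, j]
            i -= 1
            j -= 1
            ai_idx[k] = i
            bi_idx[k] = j
        elif state == 1:
            nxt = pX[i, j]
            i -= 1
            ai_idx[k] = i
            bi_idx[k] = -1
        else:
            nxt = pY[i, j]
            j -= 1
            ai_idx[k] = -1
            bi_idx[k] = j
        state = nxt
        k += 1
    return score, ai_idx[:k][::-1].copy(), bi_idx[:k][::-1].copy()


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag-from-M, 1 from-X, 2 from-Y, 3 start
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    best_score = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != 4) else mismatch
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            v = best + s
            if v < 0.0:
                v = 0.0
                ptr = 3
            M[i, j] = v
            pM[i, j] = ptr
            best = M[i - 1, j] + gap_open
            ptr = 0
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                ptr = 1
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr
            best = M[i, j - 1] + gap_open
            ptr = 0
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                ptr = 1
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr
            if M[i, j] > best_score:
                best_score = M[i, j]
                bi = i
                bj = j
    # traceback (local alignments start and end in M)
    ai_idx = np.empty(n + m, dtype=np.int64)
    bi_idx = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = bi, bj
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            nxt = pM[i, j]
            if nxt == 3 and M[i, j] == 0.0:
                break
            i -= 1
            j -= 1
            ai_idx[k] = i
            bi_idx[k] = j
            k += 1
            if nxt == 3:
                break
        elif state == 1:
            nxt = pX[i, j]
            i -= 1
            ai_idx[k] = i
            bi_idx[k] = -1
            k += 1
        else:
            nxt = pY[i, j]
            j -= 1
            ai_idx[k] = -1
            bi_idx[k] = j
            k += 1
        state = nxt
    return best_score, ai_idx[:k][::-1].copy(), bi_idx[:k][::-1].copy()


@njit(cache=True)
def _nussinov(code, min_loop, allow_gu):
    n = code.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i, j - 1]
            for k in range(i, j - min_loop):
                x, y = code[k], code[j]
                ok = (x == 0 and y == 3) or (x == 3 and y == 0) or \
                     (x == 1 and y == 2) or (x == 2 and y == 1)
                if allow_gu and ((x == 2 and y == 3) or (x == 3 and y == 2)):
                    ok = True
                if ok:
                    left = dp[i, k - 1] if k > i else 0
                    v = left + 1 + dp[k + 1, j - 1]
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp[0, n - 1]


def nw_align(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
             gap_open: float = -4.0, gap_extend: float = -1.0):
    """Global affine alignment; returns (score, a_idx, b_idx).

    ``a_idx``/``b_idx`` are parallel arrays over alignment columns holding
    the residue index consumed in each row, or -1 for a gap.
    """
    return _nw_fill(encode(a), encode(b), match, mismatch, gap_open, gap_extend)


def sw_align(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
             gap_open: float = -4.0, gap_extend: float = -1.0):
    """Best local affine alignment; returns (score, a_idx, b_idx)."""
    return _sw_fill(encode(a), encode(b), match, mismatch, gap_open, gap_extend)


def max_base_pairs(seq: str, min_loop: int = 3, allow_gu: bool = False) -> int:
    """Maximum number of nested base pairs (Nussinov DP)."""
    if len(seq) < 2:
        return 0
    return int(_nussinov(encode(seq), min_loop, allow_gu))
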