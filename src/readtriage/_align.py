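"""Numerical alignment kernels (numba-jitted Smith–Waterman and helpers).

Scoring is the package-wide local-alignment scheme: match +1, mismatch -2,
linear gap -3. The DP reports, for the best-scoring local alignment, the
query/target spans, the number of aligned columns and of identical columns.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -2
GAP = -3


@njit(cache=True)
def _sw_kernel(a, b, match, mismatch, gap):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    # traceback: 0 stop, 1 diag, 2 up (gap in b), 3 left (gap in a)
    T = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            h = diag
            t = 1
            if up > h:
                h = up
                t = 2
            if left > h:
                h = left
                t = 3
            if h <= 0:
                h = 0
                t = 0
            H[i, j] = h
            T[i, j] = t
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i, j = bi, bj
    cols = 0
    ident = 0
    while i > 0 and j > 0 and T[i, j] != 0:
        t = T[i, j]
        cols += 1
        if t == 1:
            if a[i - 1] == b[j - 1]:
                ident += 1
            i -= 1
            j -= 1
        elif t == 2:
            i -= 1
        else:
            j -= 1
    return best, i, bi, j, bj, cols, ident


def smith_waterman(
    a: np.ndarray,
    b: np.ndarray,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap: int = GAP,
):
    """Full Smith–Waterman on 2-bit code arrays.

    Returns ``(score, (a_start, a_end), (b_start, b_end), columns, identical)``
    with half-open spans; a zero score yields empty spans.
    """
    score, ai, aj, bi, bj, cols, ident = _sw_kernel(
        np.ascontiguousarray(a, dtype=np.int64),
        np.ascontiguousarray(b, dtype=np.int64),
        match,
        mismatch,
        gap,
    )
    if score <= 0:
        return 0, (0, 0), (0, 0), 0, 0
    return int(score), (int(ai), int(aj)), (int(bi), int(bj)), int(cols), int(ident)


@njit(cache=True)
def count_mismatches(read, ref, ref_start, limit):
    """Mismatches of ``read`` against ``ref[ref_start:...]``, early-exit past limit."""
    n = len(read)
    if ref_start < 0 or ref_start + n > len(ref):
        return limit + 1
    mm = 0
    for i in range(n):
        if read[i] != ref[ref_start + i]:
            mm += 1
            if mm > limit:
                return mm
    return mm


def scan_placements(query: np.ndarray, window: np.ndarray, max_mismatch: int) -> list[int]:
    """All start offsets where ``query`` fits in ``window`` with ≤ max_mismatch.

    Vectorised sliding comparison; suitable for the breakpoint-rescue windows.
    """
    n, m = len(window), len(query)
    if m == 0 or m > n:
        return []
    sw = np.lib.stride_tricks.sliding_window_view(window, m)
    mism = (sw != query).sum(axis=1)
    return np.nonzero(mism <= max_mismatch)[0].tolist()
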