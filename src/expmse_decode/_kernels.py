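"""Numba kernels for template match counting.

Brute-force Chebyshev template matching is quadratic in the index size;
the kernels below narrow each query to the templates whose first past
coordinate is within tolerance (via binary search on a sorted copy) and
scan only that band.  Results are exact — identical to an exhaustive
double loop — and deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def count_matches(
    t_first: np.ndarray,   # (K,) first past coordinate, ascending
    t_past: np.ndarray,    # (K, m) full past vectors, same order
    t_cur: np.ndarray,     # (K,) current values, same order
    t_pos: np.ndarray,     # (K,) global positions, same order
    q_past: np.ndarray,    # (Q, m)
    q_cur: np.ndarray,     # (Q,)
    q_pos: np.ndarray,     # (Q,) global position of each query, -1 = none
    r: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Count A (past matches) and B (past+current matches) per query.

    A template at sorted row ``i`` matches a query when every past
    coordinate differs by at most ``r`` (Chebyshev); it contributes to B
    when additionally the current values differ by at most ``r``.  A
    template whose global position equals the query's is skipped
    (no self-match).
    """
    Q = q_past.shape[0]
    m = q_past.shape[1]
    A = np.zeros(Q, dtype=np.int64)
    B = np.zeros(Q, dtype=np.int64)
    for q in range(Q):
        q0 = q_past[q, 0]
        lo = np.searchsorted(t_first, q0 - r, side="left")
        hi = np.searchsorted(t_first, q0 + r, side="right")
        a = 0
        b = 0
        qp = q_pos[q]
        for i in range(lo, hi):
            if t_pos[i] == qp:
                continue
            ok = True
            for d in range(1, m):
                if abs(t_past[i, d] - q_past[q, d]) > r:
                    ok = False
                    break
            if ok:
                a += 1
                if abs(t_cur[i] - q_cur[q]) <= r:
                    b += 1
        A[q] = a
        B[q] = b
    return A, B
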