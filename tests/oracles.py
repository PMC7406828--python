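"""Independent brute-force oracles for the entropy statistics.

Deliberately naive: explicit double loops over template positions with
no sorting, capping or vectorization, so they share nothing with the
implementation they check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_match_counts(values, boundaries, m, r, query_past, query_current,
                       self_position=None):
    """Exhaustive (A, B) over all admissible template positions."""
    A = B = 0
    for b in range(len(boundaries) - 1):
        start, end = boundaries[b], boundaries[b + 1]
        for j in range(start + m, end):
            if self_position is not None and j == self_position:
                continue
            if max(abs(values[j - m + k] - query_past[k])
                   for k in range(m)) <= r:
                A += 1
                if abs(values[j] - query_current) <= r:
                    B += 1
    return A, B


def brute_exp_sampen(values, boundaries, m, r):
    """Per-point -log(B/A) with self-exclusion; NaN where undefined."""
    out = np.full(len(values), np.nan)
    for b in range(len(boundaries) - 1):
        start, end = boundaries[b], boundaries[b + 1]
        for n in range(start + m, end):
            A, B = brute_match_counts(values, boundaries, m, r,
                                      values[n - m: n], values[n],
                                      self_position=n)
            if A > 0 and B > 0:
                out[n] = -math.log(B / A)
    return out


def _series_counts(x, m, r):
    n = len(x)
    bounds = [0, n]
    rows = []
    for q in range(m, n):
        rows.append(brute_match_counts(x, bounds, m, r, x[q - m: q], x[q],
                                       self_position=q))
    return np.array(rows)


def brute_apen(x, m, r):
    ab = _series_counts(x, m, r)
    vals = [-math.log(B / A) for A, B in ab if A > 0 and B > 0]
    return float(np.mean(vals))


def brute_sampen(x, m, r):
    ab = _series_counts(x, m, r)
    return float(-math.log(ab[:, 1].sum() / ab[:, 0].sum()))


def brute_lsampen(x, m, r):
    ab = _series_counts(x, m, r)
    ratios = [B / A for A, B in ab if A > 0]
    return float(-math.log(np.mean(ratios)))
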