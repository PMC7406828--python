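"""Empirical mode decomposition with ensemble averaging (EEMD).

Classic sifting: cubic-spline upper/lower envelopes through local
extrema, mirrored boundary extension, and a fixed number of sifting
iterations per intrinsic mode function (IMF).  EEMD perturbs the input
with white noise and averages the IMFs over an ensemble of runs, which
suppresses mode mixing at the cost of a small residual noise floor
(~ ``noise_sd_ratio / sqrt(n_ensembles)`` relative RMS).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DecompositionError

#: Fixed number of sifting iterations per IMF.
N_SIFT = 10
#: Maximum number of IMFs extracted.
MAX_IMF = 10


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (flat runs use their midpoint)."""
    d = np.diff(x)
    s = np.sign(d)
    # carry the previous non-zero slope through flat segments
    nz = s != 0
    if not nz.any():
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    idx = np.where(nz, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.clip(idx, 0, None)], 0)
    turn = np.diff(filled)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _envelope(pos: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through (pos, vals), mirrored at both ends."""
    pos = pos.astype(np.float64)
    k = min(2, pos.size - 1)
    # mirror up to two interior extrema across each end
    left_pos = (2.0 * pos[0] - pos[1:k + 1])[::-1]
    left_val = vals[1:k + 1][::-1]
    right_pos = (2.0 * pos[-1] - pos[-(k + 1):-1])[::-1]
    right_val = vals[-(k + 1):-1][::-1]
    xs = np.concatenate((left_pos, pos, right_pos))
    ys = np.concatenate((left_val, vals, right_val))
    # guarantee the spline domain covers [0, n-1]
    if xs[0] > 0:
        xs = np.concatenate(([-1.0], xs))
        ys = np.concatenate(([vals[0]], ys))
    if xs[-1] < n - 1:
        xs = np.concatenate((xs, [float(n)]))
        ys = np.concatenate((ys, [vals[-1]]))
    keep = np.concatenate(([True], np.diff(xs) > 0))
    spline = CubicSpline(xs[keep], ys[keep])
    return spline(np.arange(n))


def emd(x: np.ndarray, max_imf: int = MAX_IMF,
        n_sift: int = N_SIFT) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose ``x`` into IMFs plus a residual trend.

    Extraction stops when the residual has fewer than four extrema or
    ``max_imf`` IMFs have been extracted.  Raises
    :class:`DecompositionError` on constant input (nothing to sift).
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise DecompositionError("signal contains non-finite values")
    if np.ptp(x) == 0:
        raise DecompositionError("constant signal has no extrema to sift")
    residual = x.copy()
    n = x.size
    imfs: list[np.ndarray] = []
    for _ in range(max_imf):
        maxima, minima = local_extrema(residual)
        if maxima.size + minima.size < 4:
            break
        h = residual.copy()
        for _ in range(n_sift):
            maxima, minima = local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            upper = _envelope(maxima, h[maxima], n)
            lower = _envelope(minima, h[minima], n)
            h = h - 0.5 * (upper + lower)
        imfs.append(h)
        residual = residual - h
    return imfs, residual


def eemd(
    x: np.ndarray,
    noise_sd_ratio: float = 0.2,
    n_ensembles: int = 200,
    seed: int = 0,
    max_imf: int = MAX_IMF,
    n_sift: int = N_SIFT,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-averaged EMD.

    Returns ``(imfs, residual)`` where ``imfs`` has shape
    ``(n_imfs, len(x))``.  With ``n_ensembles == 1`` and
    ``noise_sd_ratio == 0`` this reduces to plain EMD.  Identical seeds
    produce identical output.
    """
    x = np.asarray(x, dtype=np.float64)
    if noise_sd_ratio < 0:
        raise DecompositionError("noise_sd_ratio must be >= 0")
    if n_ensembles < 1:
        raise DecompositionError("n_ensembles must be >= 1")
    sd = noise_sd_ratio * x.std()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEEED]))
    sum_imfs = np.zeros((max_imf, x.size))
    sum_res = np.zeros(x.size)
    n_slots = 0
    for _ in range(n_ensembles):
        noisy = x + sd * rng.normal(size=x.size) if sd > 0 else x
        imfs, res = emd(noisy, max_imf=max_imf, n_sift=n_sift)
        for i, imf in enumerate(imfs):
            sum_imfs[i] += imf
        n_slots = max(n_slots, len(imfs))
        sum_res += res
    if n_slots == 0:
        raise DecompositionError("no IMFs could be extracted")
    imfs = sum_imfs[:n_slots] / n_ensembles
    residual = sum_res / n_ensembles
    return imfs, residual
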