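"""Time-resolved sample entropy (expSampEn) and classic relatives.

All four statistics share one probability-estimation machinery.  For a
standardized series with embedding dimension ``m`` and tolerance ``r``,
a *template* at position ``j`` is the ``m+1``-vector
``(x[j-m], ..., x[j])``.  For a query point ``n`` with past vector
``x_n^- = (x[n-m], ..., x[n-1])`` and current value ``x[n]``:

* ``A_n`` — number of templates whose past vector matches ``x_n^-``
  within Chebyshev distance ``r``;
* ``B_n`` — the subset of those that also match ``x[n]`` within ``r``.

The conditional continuation probability is ``p(x_n | x_n^-) = B_n/A_n``
and the four measures differ only in where the time average sits:

* ``expSampEn(n) = -log(B_n/A_n)`` — kept as a time series (no
  averaging): the per-time-point complexity that feeds the decoder;
* ``ApEn = mean_n[-log(B_n/A_n)]`` — entropy per point, then averaged;
* ``SampEn = -log(sum_n B_n / sum_n A_n)`` — probabilities averaged
  before the log;
* ``LSampEn = -log(mean_n[B_n/A_n])`` — conditional probability
  averaged before the log.

Self-matches are excluded in all four measures so that the exact
identity ``mean(defined expSampEn) == ApEn`` holds by construction.
Natural logarithms (nats) throughout.

For the multiscale map the template pool is built from the whole
recording: each region's series is coarse-grained at the time scale
factor (TSF) ``tau``, the per-region coarse series are concatenated
(templates never span a region boundary), and the concatenated index is
standardized to mean 0 / SD 1, so ``r = 0.2`` means 0.2 SD of the
index.  Query points that yield ``A_n = 0`` or ``B_n = 0`` are undefined
and later filled by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import count_matches
from .decompose import BANDS, COMPONENTS, BandComponents
from .errors import ConfigError, UndefinedEntropyError

#: Per-band coarse-graining time scale factors, labelled A-E.
DEFAULT_TSF_TABLE: dict[str, tuple[int, ...]] = {
    "gamma": (2, 4, 8, 16, 32),
    "beta": (4, 8, 16, 32, 64),
    "alpha": (8, 16, 32, 64, 128),
}
TSF_LETTERS = "ABCDE"

#: Default cap on the number of template positions in one index.
DEFAULT_INDEX_CAP = 500_000


@dataclass(frozen=True)
class EntropyParams:
    """Embedding dimension, tolerance and time scale factor."""

    m: int = 2
    r: float = 0.2
    tsf: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.r <= 0:
            raise ConfigError("r must be positive")
        if self.tsf < 1:
            raise ConfigError("tsf must be >= 1")


def coarse_grain(series: np.ndarray, tsf: int) -> np.ndarray:
    """Non-overlapping means of ``tsf`` consecutive samples."""
    series = np.asarray(series, dtype=np.float64)
    if tsf < 1:
        raise ConfigError("tsf must be >= 1")
    if tsf > series.size:
        raise ConfigError(f"tsf={tsf} exceeds series length {series.size}")
    if tsf == 1:
        return series.copy()
    n = series.size // tsf
    return series[: n * tsf].reshape(n, tsf).mean(axis=1)


@dataclass
class TemplateIndex:
    """Standardized concatenated coarse series with region boundaries.

    ``values`` is the full concatenated series (queries are drawn from
    it and are never subsampled); ``boundaries`` holds the start offset
    of each region block plus the total length.  Template *positions*
    (not values) are uniformly stride-subsampled to at most ``cap``.
    """

    values: np.ndarray
    boundaries: np.ndarray  # (n_blocks + 1,)
    tsf: int = 1
    cap: int = DEFAULT_INDEX_CAP
    mean_: float = 0.0
    std_: float = 1.0
    source: dict = field(default_factory=dict)
    _templates: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n_blocks(self) -> int:
        return self.boundaries.size - 1

    def block(self, i: int) -> np.ndarray:
        return self.values[self.boundaries[i]: self.boundaries[i + 1]]

    def admissible_positions(self, m: int) -> np.ndarray:
        """Template positions with a full m+1 window inside one block,
        stride-subsampled to at most ``cap``."""
        pos_list = []
        for i in range(self.n_blocks):
            s, e = int(self.boundaries[i]), int(self.boundaries[i + 1])
            if e - s > m:
                pos_list.append(np.arange(s + m, e, dtype=np.int64))
        if not pos_list:
            return np.empty(0, dtype=np.int64)
        pos = np.concatenate(pos_list)
        if pos.size > self.cap:
            stride = int(np.ceil(pos.size / self.cap))
            pos = pos[::stride]
        return pos

    def _sorted_templates(self, m: int):
        """(t_first, t_past, t_cur, t_pos) sorted by first past coord."""
        key = int(m)
        if key not in self._templates:
            pos = self.admissible_positions(m)
            win = np.lib.stride_tricks.sliding_window_view(self.values, m)
            t_past = np.ascontiguousarray(win[pos - m])
            t_cur = self.values[pos]
            order = np.argsort(t_past[:, 0], kind="stable")
            self._templates[key] = (
                np.ascontiguousarray(t_past[order, 0]),
                np.ascontiguousarray(t_past[order]),
                np.ascontiguousarray(t_cur[order]),
                np.ascontiguousarray(pos[order]),
            )
        return self._templates[key]


def build_template_index(
    per_region_series: list[np.ndarray] | np.ndarray,
    tsf: int = 1,
    cap: int = DEFAULT_INDEX_CAP,
    source: dict | None = None,
) -> TemplateIndex:
    """Coarse-grain each region at ``tsf``, concatenate and standardize.

    Raises :class:`UndefinedEntropyError` when the concatenated series
    has zero variance (no tolerance scale exists).
    """
    if len({np.asarray(s).size for s in per_region_series}) != 1:
        raise ConfigError("all regions must have the same length")
    blocks = [coarse_grain(np.asarray(s, dtype=np.float64), tsf)
              for s in per_region_series]
    concat = np.concatenate(blocks)
    std = concat.std()
    if std == 0:
        raise UndefinedEntropyError(
            "zero-variance concatenated series: no scale for tolerance r"
        )
    mean = concat.mean()
    values = (concat - mean) / std
    boundaries = np.zeros(len(blocks) + 1, dtype=np.int64)
    boundaries[1:] = np.cumsum([b.size for b in blocks])
    return TemplateIndex(values=values, boundaries=boundaries, tsf=tsf,
                         cap=cap, mean_=float(mean), std_=float(std),
                         source=dict(source or {}))


def match_counts(
    index: TemplateIndex,
    query_past: np.ndarray,
    query_current: float,
    params: EntropyParams,
    self_position: int | None = None,
) -> tuple[int, int]:
    """(A, B) template match counts for one standardized query."""
    query_past = np.asarray(query_past, dtype=np.float64)
    if query_past.size != params.m:
        raise ConfigError("query_past must have length m")
    t_first, t_past, t_cur, t_pos = index._sorted_templates(params.m)
    q_pos = np.array(
        [-1 if self_position is None else int(self_position)],
        dtype=np.int64,
    )
    A, B = count_matches(
        t_first, t_past, t_cur, t_pos,
        query_past[None, :], np.array([float(query_current)]),
        q_pos, float(params.r),
    )
    return int(A[0]), int(B[0])


@dataclass
class ExpSampEnSeries:
    """Per-time-point entropy with an undefined-point mask.

    ``values[n]`` is ``-log(B_n/A_n)`` where defined; the mask is True
    at the first ``m`` points of the block (no full past) and wherever
    ``A_n`` or ``B_n`` is zero.
    """

    values: np.ndarray
    undefined_mask: np.ndarray
    A: np.ndarray
    B: np.ndarray
    source: dict = field(default_factory=dict)


def exp_sampen(
    queries: np.ndarray,
    index: TemplateIndex,
    params: EntropyParams,
    index_offset: int | None = None,
) -> ExpSampEnSeries:
    """expSampEn of every point of a query series against an index.

    ``queries`` must already be on the index's standardized scale.  When
    the query series is a block of the index itself, ``index_offset`` is
    the global position of ``queries[0]``; it enables self-match
    exclusion.  Undefined points (no full past, or no matches) are
    flagged, not interpolated — see :func:`interpolate_undefined`.
    """
    q = np.asarray(queries, dtype=np.float64)
    m = params.m
    n = q.size
    values = np.zeros(n)
    mask = np.ones(n, dtype=bool)
    A_out = np.zeros(n, dtype=np.int64)
    B_out = np.zeros(n, dtype=np.int64)
    if n > m:
        t_first, t_past, t_cur, t_pos = index._sorted_templates(m)
        win = np.lib.stride_tricks.sliding_window_view(q, m)
        q_past = np.ascontiguousarray(win[:-1])  # past of points m..n-1
        q_cur = q[m:]
        if index_offset is None:
            q_pos = np.full(n - m, -1, dtype=np.int64)
        else:
            q_pos = np.arange(index_offset + m, index_offset + n,
                              dtype=np.int64)
        A, B = count_matches(t_first, t_past, t_cur, t_pos,
                             q_past, q_cur, q_pos, float(params.r))
        defined = (A > 0) & (B > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = -np.log(B / A)
        values[m:][defined] = v[defined]
        mask[m:] = ~defined
        A_out[m:] = A
        B_out[m:] = B
    return ExpSampEnSeries(values=values, undefined_mask=mask,
                           A=A_out, B=B_out)


def _self_counts(series: np.ndarray,
                 params: EntropyParams) -> tuple[np.ndarray, np.ndarray]:
    """(A, B) for every point of a single raw series against itself.

    No rescaling is applied: ``r`` is in the units of the series as
    given (callers standardize when they want r in SD units).
    Self-matches are excluded.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.size <= params.m + 1:
        raise ConfigError("series too short: need length > m + 1")
    index = TemplateIndex(
        values=series.copy(),
        boundaries=np.array([0, series.size], dtype=np.int64),
        tsf=1, cap=DEFAULT_INDEX_CAP,
    )
    res = exp_sampen(series, index, params, index_offset=0)
    return res.A[params.m:], res.B[params.m:]


def apen(series: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """Approximate entropy: per-point entropy averaged over time.

    Averages ``-log(B_n/A_n)`` over the points where it is defined;
    identical by construction to the mean of the defined expSampEn
    values of the same series.
    """
    A, B = _self_counts(series, params)
    defined = (A > 0) & (B > 0)
    if not defined.any():
        raise UndefinedEntropyError("ApEn: no defined points")
    return float(np.mean(-np.log(B[defined] / A[defined])))


def sampen(series: np.ndarray,
           params: EntropyParams = EntropyParams()) -> float:
    """Sample entropy: probabilities averaged over time before the log."""
    A, B = _self_counts(series, params)
    sa, sb = int(A.sum()), int(B.sum())
    if sa == 0 or sb == 0:
        raise UndefinedEntropyError("SampEn: no template matches")
    return float(-np.log(sb / sa))


def lsampen(series: np.ndarray,
            params: EntropyParams = EntropyParams()) -> float:
    """Local sample entropy: conditional probability averaged, then log."""
    A, B = _self_counts(series, params)
    defined = A > 0
    if not defined.any():
        raise UndefinedEntropyError("LSampEn: no defined points")
    ratio = np.mean(B[defined] / A[defined])
    if ratio == 0:
        raise UndefinedEntropyError("LSampEn: all continuations unmatched")
    return float(-np.log(ratio))


def interpolate_undefined(series: ExpSampEnSeries) -> np.ndarray:
    """Fill undefined points: linear interior, nearest-value edges.

    Raises :class:`UndefinedEntropyError` when nothing is defined.
    """
    values, mask = series.values, series.undefined_mask
    if not (~mask).any():
        src = series.source
        raise UndefinedEntropyError(
            f"fully undefined block {src or ''}: nothing to interpolate"
        )
    if not mask.any():
        return values.copy()
    idx = np.arange(values.size)
    defined = ~mask
    return np.interp(idx, idx[defined], values[defined])


def align_to_ml_rate(
    series: np.ndarray,
    tsf: int,
    fs: float,
    bin_s: float = 0.64,
) -> np.ndarray:
    """Average a coarse series (rate fs/tsf) into the 0.64 s ML grid.

    ML bin ``k`` covers raw samples ``[k*B, (k+1)*B)`` with
    ``B = round(bin_s*fs)``; a coarse sample is assigned to the bin
    containing its first raw sample.  The trailing partial bin is
    dropped.
    """
    series = np.asarray(series, dtype=np.float64)
    bin_raw = int(round(bin_s * fs))
    if tsf > bin_raw:
        raise ConfigError(
            f"ML bin ({bin_raw} samples) shorter than one coarse sample "
            f"(tsf={tsf})"
        )
    n_raw = series.size * tsf
    n_bins = n_raw // bin_raw
    if n_bins == 0:
        raise ConfigError("series shorter than one ML bin")
    bins = (np.arange(series.size) * tsf) // bin_raw
    keep = bins < n_bins
    sums = np.bincount(bins[keep], weights=series[keep], minlength=n_bins)
    counts = np.bincount(bins[keep], minlength=n_bins)
    return sums / counts


@dataclass
class ComplexityTensor:
    """region x feature-column x ML-time expMSE values (gap-free).

    Columns are ordered band (gamma, beta, alpha) x component
    (Amp, Phase) x TSF (A..E); 30 columns in the default configuration.
    """

    values: np.ndarray  # (n_regions, n_columns, n_ml)
    columns: tuple[str, ...]
    region_labels: tuple[str, ...]
    bin_s: float = 0.64

    def column_index(self, name: str) -> int:
        return self.columns.index(name)


def feature_columns(
    tsf_table: dict[str, tuple[int, ...]] = DEFAULT_TSF_TABLE,
) -> tuple[str, ...]:
    """Stable, documented feature-column order of the complexity map."""
    cols = []
    for band in BANDS:
        for comp in COMPONENTS:
            for letter, _ in zip(TSF_LETTERS, tsf_table[band]):
                cols.append(f"{band}-{comp}-{letter}")
    return tuple(cols)


def expmse_map(
    components: BandComponents,
    tsf_table: dict[str, tuple[int, ...]] = DEFAULT_TSF_TABLE,
    params: EntropyParams = EntropyParams(),
    cap: int = DEFAULT_INDEX_CAP,
    bin_s: float = 0.64,
) -> ComplexityTensor:
    """The full multiscale complexity map of a recording.

    For each (band, component, TSF) the template index is built from
    the *whole* recording (all tasks and rest periods of all regions),
    expSampEn is computed at every query point, edge-flagged and
    undefined points are interpolated, and the gap-free coarse series is
    averaged onto the common 0.64 s ML grid.
    """
    fs = components.fs
    n_raw = components.n_samples
    edge = int(np.floor(n_raw * components.edge_fraction))
    col_names = feature_columns(tsf_table)
    col_arrays: list[np.ndarray] = []
    for band in BANDS:
        taus = tsf_table[band]
        for comp in COMPONENTS:
            series = components.component(band, comp)
            for letter, tau in zip(TSF_LETTERS, taus):
                try:
                    col = _expmse_column(series, tau, params, cap, fs,
                                         bin_s, edge, band, comp, letter)
                except UndefinedEntropyError as err:
                    raise UndefinedEntropyError(
                        f"({band}, {comp}, tsf {tau}): {err}"
                    ) from err
                col_arrays.append(col)
    n_ml = min(c.shape[1] for c in col_arrays)
    values = np.stack([c[:, :n_ml] for c in col_arrays], axis=1)
    return ComplexityTensor(values=values, columns=col_names,
                            region_labels=components.region_labels,
                            bin_s=bin_s)


def _expmse_column(
    series: np.ndarray,
    tau: int,
    params: EntropyParams,
    cap: int,
    fs: float,
    bin_s: float,
    edge: int,
    band: str,
    comp: str,
    letter: str,
) -> np.ndarray:
    """One (band, component, TSF) column: (n_regions, n_ml)."""
    n_regions, n_raw = series.shape
    index = build_template_index(
        [series[g] for g in range(n_regions)], tsf=tau, cap=cap,
        source={"band": band, "component": comp, "tsf": tau},
    )
    out_rows = []
    for g in range(n_regions):
        s = int(index.boundaries[g])
        q = index.block(g)
        res = exp_sampen(q, index, params, index_offset=s)
        if edge > 0:
            starts = np.arange(q.size) * tau
            flagged = (starts < edge) | (starts + tau > n_raw - edge)
            res.undefined_mask |= flagged
        res.source = {"region": g, "band": band,
                      "component": comp, "tsf": tau}
        filled = interpolate_undefined(res)
        out_rows.append(align_to_ml_rate(filled, tau, fs, bin_s))
    return np.vstack(out_rows)


__all__ = [
    "EntropyParams", "TemplateIndex", "ExpSampEnSeries", "ComplexityTensor",
    "DEFAULT_TSF_TABLE", "DEFAULT_INDEX_CAP", "TSF_LETTERS",
    "coarse_grain", "build_template_index", "match_counts", "exp_sampen",
    "apen", "sampen", "lsampen", "interpolate_undefined",
    "align_to_ml_rate", "feature_columns", "expmse_map",
]
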