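"""Imputation methods: moving-mean interpolation and iterative gappy SVD.

Moving mean is a univariate statistical method: each missing day in a gap of
length L is filled with the mean of the observed values in a symmetric
window of 2L+1 days centred on it (the window covers twice the gap length
around the gap).

Gappy SVD (GSVD) is a multivariate, data-driven method: yearly and replicate
series are stacked as columns of a day-by-series matrix, missing entries are
given an initial guess, and the matrix is repeatedly decomposed
(X = U S V^T), truncated to its first N modes (X* = U* S* V*^T) and the
missing entries replaced by the low-rank reconstruction, until the mean
squared change of the imputed entries between iterations drops below a
tolerance.  The leading modes carry the dominant seasonal structure; the
discarded tail carries noise and the arbitrariness of the initial guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import PollenSeries

__all__ = [
    "GappyMatrix",
    "GsvdConfig",
    "ImputationResult",
    "moving_mean_fill",
    "impute_moving_mean",
    "assemble_matrix",
    "initial_fill",
    "gsvd_impute",
]


# ---------------------------------------------------------------------------
# moving mean


def _missing_runs(isnan: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    runs = []
    n = len(isnan)
    i = 0
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def moving_mean_fill(values: np.ndarray, window_factor: float = 1.0) -> np.ndarray:
    """Fill NaN runs with symmetric-window means of observed neighbours.

    For a missing run of length L, each missing day ``i`` receives the mean
    of the *observed* values at days ``[i - h, i + h]`` with half-width
    ``h = ceil(window_factor * L)`` (window truncated at the series edges).
    If that window contains no observed value the half-width is doubled
    until it does.  Observed values are never altered and never replaced by
    previously imputed ones.
    """
    v = np.asarray(values, dtype=float)
    isnan = np.isnan(v)
    if isnan.all():
        raise ValueError("cannot impute a fully missing series")
    if not isnan.any():
        return v.copy()
    out = v.copy()
    n = len(v)
    for start, stop in _missing_runs(isnan):
        L = stop - start
        h0 = max(1, int(np.ceil(window_factor * L)))
        for i in range(start, stop):
            h = h0
            while True:
                lo, hi = max(0, i - h), min(n, i + h + 1)
                window = v[lo:hi]
                present = window[~np.isnan(window)]
                if len(present):
                    out[i] = present.mean()
                    break
                h *= 2
    return out


def impute_moving_mean(
    series: PollenSeries, window_factor: float = 1.0
) -> PollenSeries:
    """Moving-mean imputation of a :class:`PollenSeries` (see
    :func:`moving_mean_fill`)."""
    filled = moving_mean_fill(series.values, window_factor=window_factor)
    return PollenSeries(series.station_id, series.taxon, series.dates, filled)


# ---------------------------------------------------------------------------
# gappy SVD


@dataclass
class GappyMatrix:
    """Day-by-series matrix with a boolean mask of entries to impute.

    Rows are the days of the common window; columns are labelled series
    (historical years, then gappy replicates).  ``mask`` is True where the
    entry is missing/removed; the value there may be NaN.  Observed entries
    must be finite and nonnegative.
    """

    values: np.ndarray
    mask: np.ndarray
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have identical shape")
        if not self.columns:
            self.columns = [f"c{j}" for j in range(self.values.shape[1])]
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("one column label per column required")
        observed = self.values[~self.mask]
        if np.any(~np.isfinite(observed)) or np.any(observed < 0):
            raise ValueError("observed entries must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class GsvdConfig:
    """Settings of the iterative SVD imputation.

    ``n_modes`` is the number of retained modes N; ``init`` the initial gap
    fill (``"mean"``: column mean of observed values; ``"linear"``: linear
    interpolation along the day axis with flat edge extension); ``tol`` the
    convergence tolerance on the mean squared inter-iteration change of the
    imputed entries (relative to the mean square of the previous iterate if
    ``relative`` is set); nonnegative clipping reflects that concentrations
    cannot be negative.
    """

    n_modes: int
    init: str = "mean"
    tol: float = 1e-6
    max_iter: int = 1000
    relative: bool = False
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.init not in ("mean", "linear"):
            raise ValueError("init must be 'mean' or 'linear'")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class ImputationResult:
    """Completed matrix plus convergence diagnostics."""

    completed: np.ndarray
    iterations: int
    final_delta: float
    converged: bool
    columns: list[str] = field(default_factory=list)


def assemble_matrix(
    historical: Mapping[str, np.ndarray],
    replicates: Mapping[str, np.ndarray] | Sequence[np.ndarray] = (),
    include_reference_year: bool = True,
    reference_label: str | None = None,
) -> GappyMatrix:
    """Stack aligned yearly columns and gappy replicate columns.

    ``historical`` maps year labels to aligned value vectors (the complete
    target year among them, named by ``reference_label``); ``replicates``
    holds the gappy copies of the target year.  The mask marks every NaN:
    the simulated gaps and any historically missing day.

    .. warning::
       ``include_reference_year=True`` keeps the complete target-year column
       in the matrix next to its gappy replicates, so the truth of the
       removed entries is visible to the reconstruction.  Pass ``False`` for
       a leakage-free evaluation.
    """
    cols: list[str] = []
    vecs: list[np.ndarray] = []
    for label, vec in historical.items():
        if label == reference_label and not include_reference_year:
            continue
        cols.append(str(label))
        vecs.append(np.asarray(vec, dtype=float))
    if isinstance(replicates, Mapping):
        rep_items = list(replicates.items())
    else:
        rep_items = [(f"rep{i}", v) for i, v in enumerate(replicates)]
    for label, vec in rep_items:
        cols.append(str(label))
        vecs.append(np.asarray(vec, dtype=float))
    if not vecs:
        raise ValueError("no columns to assemble")
    lengths = {len(v) for v in vecs}
    if len(lengths) != 1:
        raise ValueError(f"columns have mismatched lengths: {sorted(lengths)}")
    values = np.column_stack(vecs)
    return GappyMatrix(values=values, mask=np.isnan(values), columns=cols)


def initial_fill(
    column: np.ndarray, mask: np.ndarray | None = None, method: str = "mean"
) -> np.ndarray:
    """Initial guess for one column's masked entries.

    ``mean``: masked entries take the mean of the column's observed values.
    ``linear``: linear interpolation between the nearest observed neighbours
    along the index axis, extended flat beyond the first/last observation.
    """
    v = np.asarray(column, dtype=float)
    m = np.isnan(v) if mask is None else np.asarray(mask, dtype=bool)
    if m.all():
        raise ValueError("cannot initialise a fully masked column")
    out = v.copy()
    obs_idx = np.flatnonzero(~m)
    if method == "mean":
        out[m] = v[obs_idx].mean()
    elif method == "linear":
        out[m] = np.interp(np.flatnonzero(m), obs_idx, v[obs_idx])
    else:
        raise ValueError("method must be 'mean' or 'linear'")
    return out


def gsvd_impute(matrix: GappyMatrix, config: GsvdConfig) -> ImputationResult:
    """Iterative truncated-SVD completion of a gappy matrix.

    Each iteration decomposes the current filled matrix, reconstructs it
    from the first ``n_modes`` modes and overwrites the masked entries with
    the reconstruction; observed entries are untouched throughout.  Stops
    when the mean squared change of the imputed entries falls below ``tol``
    or at ``max_iter`` (then flagged not converged).  Imputed concentrations
    are clipped at zero on output.
    """
    n_rows, n_cols = matrix.shape
    if config.n_modes > min(n_rows, n_cols):
        raise ValueError(
            f"n_modes={config.n_modes} exceeds matrix rank bound "
            f"{min(n_rows, n_cols)}"
        )
    mask = matrix.mask
    if mask.all(axis=0).any():
        raise ValueError("matrix has a fully masked column")

    X = matrix.values.copy()
    for j in range(n_cols):
        if mask[:, j].any():
            X[:, j] = initial_fill(X[:, j], mask[:, j], method=config.init)

    n_gap = int(mask.sum())
    N = config.n_modes
    prev = X[mask].copy()
    delta = 0.0
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        Xstar = (U[:, :N] * s[:N]) @ Vt[:N]
        if n_gap == 0:
            converged = True
            break
        new = Xstar[mask]
        delta = float(np.mean((new - prev) ** 2))
        if config.relative:
            denom = float(np.mean(prev**2))
            delta = delta / denom if denom > 0 else delta
        X[mask] = new
        prev = new
        if delta < config.tol:
            converged = True
            break
    if n_gap and config.clip_negative:
        X[mask] = np.maximum(X[mask], 0.0)
    return ImputationResult(
        completed=X,
        iterations=it,
        final_delta=delta,
        converged=converged,
        columns=list(matrix.columns),
    )
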