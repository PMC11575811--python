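"""Imputation-accuracy evaluation: RMSE, per-scenario medians, and the
log-RMSE regression with heteroskedasticity-robust standard errors.

One evaluation record is a single (pollen, station, method, %NA, gap length,
replicate) -> RMSE row.  Per stratum (pollen x station), the error model
regresses log(RMSE) on indicator-coded method, missing proportion and gap
length; exponentiated coefficients Exp(beta) are ratios of geometric-mean
RMSE versus the reference levels (moving mean, 5% NA, 3-day gaps).
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["rmse", "summarize_rmse", "fit_error_model", "RECORD_COLUMNS"]

RECORD_COLUMNS = [
    "pollen",
    "station",
    "method",
    "na_prop",
    "gap_len",
    "replicate",
    "rmse",
]

_CELL_KEYS = ["pollen", "station", "method", "na_prop", "gap_len"]


def rmse(
    predicted: np.ndarray,
    observed: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Root mean squared difference between two equal-length vectors.

    By default the mean runs over all N days of the evaluation window, so
    days that were never removed contribute zero error.  Passing a boolean
    ``mask`` restricts the average to the masked (gap) days only.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    diff = p - o
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != p.shape:
            raise ValueError("mask shape mismatch")
        d2 = diff[m] ** 2
        if d2.size == 0:
            raise ValueError("empty mask: no days to evaluate")
        return float(np.sqrt(d2.mean()))
    if np.isnan(diff).any():
        raise ValueError("missing entries in predicted/observed")
    return float(np.sqrt(np.mean(diff**2)))


def summarize_rmse(records: pd.DataFrame) -> pd.DataFrame:
    """Median RMSE over replicates per (pollen, station, method, %NA, gap).

    Returns one row per scenario cell with columns ``median_rmse`` and
    ``n_replicates``; the 12 values per (pollen, station, method) are the
    per-method distributions behind the study's boxplot summaries.
    """
    required = set(_CELL_KEYS + ["rmse"])
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    out = (
        records.groupby(_CELL_KEYS, sort=True, observed=True)["rmse"]
        .agg(median_rmse="median", n_replicates="size")
        .reset_index()
    )
    return out


def _term_level(name: str) -> tuple[str, str] | None:
    """Map a patsy design-column name to (covariate, level)."""
    m = re.match(r"C\((\w+).*\)\[T\.(.+)\]$", name)
    if not m:
        return None
    return m.group(1), m.group(2)


def fit_error_model(
    records: pd.DataFrame,
    cov_type: str = "HC1",
    references: tuple[str, object, object] = ("movingmean", 5, 3),
) -> pd.DataFrame:
    """OLS of log(RMSE) on method, %NA and gap length for one stratum.

    All three covariates enter as unordered categories with the given
    reference levels; standard errors are heteroskedasticity-consistent
    (HC1 by default, HC3 available).  The returned tidy table has one row
    per level including the references, with ``exp_beta`` and its 95% CI
    (references carry exp_beta 1 and the ``reference`` flag).
    """
    df = records.copy()
    if (df["rmse"] <= 0).any():
        raise ValueError("all RMSE values must be positive for the log transform")
    ref_method, ref_prop, ref_gap = references
    for col, ref in (("method", ref_method), ("na_prop", ref_prop), ("gap_len", ref_gap)):
        if ref not in set(df[col]):
            raise ValueError(f"reference level {ref!r} absent from column {col!r}")
    df["log_rmse"] = np.log(df["rmse"].astype(float))
    terms = []
    for col, ref in (("method", ref_method), ("na_prop", ref_prop), ("gap_len", ref_gap)):
        if df[col].nunique() > 1:
            terms.append(f"C({col}, Treatment(reference={ref!r}))")
    if not terms:
        raise ValueError("no varying covariate to model")
    model = smf.ols("log_rmse ~ " + " + ".join(terms), data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = model.fit(cov_type=cov_type)
    ci = res.conf_int(alpha=0.05)

    level_order = {
        "method": list(pd.unique(df["method"])),
        "na_prop": sorted(pd.unique(df["na_prop"])),
        "gap_len": sorted(pd.unique(df["gap_len"])),
    }
    estimates: dict[tuple[str, str], tuple[float, float, float]] = {}
    for name in res.params.index:
        tl = _term_level(name)
        if tl is None:
            continue
        estimates[tl] = (
            float(np.exp(res.params[name])),
            float(np.exp(ci.loc[name, 0])),
            float(np.exp(ci.loc[name, 1])),
        )
    rows = []
    for col, ref in (("method", ref_method), ("na_prop", ref_prop), ("gap_len", ref_gap)):
        for level in level_order[col]:
            is_ref = str(level) == str(ref)
            if is_ref:
                eb = lo = hi = 1.0
            else:
                key = (col, str(level))
                if key not in estimates:
                    continue
                eb, lo, hi = estimates[key]
            rows.append(
                {
                    "term": col,
                    "level": str(level),
                    "exp_beta": eb,
                    "ci_low": lo,
                    "ci_high": hi,
                    "reference": is_ref,
                }
            )
    return pd.DataFrame(rows)
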