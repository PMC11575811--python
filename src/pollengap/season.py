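"""Pollen-season definition and variability statistics.

The season of a calendar year is defined by the cumulative-percentage
("95-percentage") rule: it starts on the first day on which the cumulative
annual pollen sum reaches 2.5% of the annual total and ends on the first day
on which it reaches 97.5%.  The Variation Index (VIn) quantifies day-to-day
variability as the mean two-day moving coefficient of variation over a
window, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import PollenSeries, SeasonWindow

__all__ = [
    "SummaryStats",
    "season_bounds",
    "extended_window",
    "descriptive_stats",
    "variation_index",
]


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive statistics of daily concentrations over a window.

    ``sd`` is the sample (n-1) standard deviation; ``cv`` = sd/mean in
    percent; quartiles use linear interpolation between order statistics.
    """

    mean: float
    sd: float
    cv: float
    q1: float
    median: float
    q3: float
    max: float
    duration: int


def season_bounds(
    series: PollenSeries, year: int, coverage: float = 95.0
) -> SeasonWindow:
    """Season window of ``year`` by the cumulative-percentage method.

    ``coverage`` percent of the annual pollen sum falls inside the window:
    the start is the earliest day whose inclusive cumulative sum reaches
    ``(100 - coverage)/2`` percent of the annual total, the end the earliest
    day reaching ``100 - (100 - coverage)/2`` percent.  With ``coverage=95``
    this is the classical 2.5%/97.5% rule.
    """
    if not 0 < coverage <= 100:
        raise ValueError("coverage must be in (0, 100]")
    y0 = pd.Timestamp(year=year, month=1, day=1)
    y1 = pd.Timestamp(year=year, month=12, day=31)
    if series.start > y0 or series.end < y1:
        raise ValueError(f"series does not cover calendar year {year}")
    vals = series.slice(SeasonWindow(y0, y1))
    vals = np.where(np.isnan(vals), 0.0, vals)
    csum = np.cumsum(vals)
    total = float(csum[-1])  # cumulative total, so thresholds are reachable
    if total <= 0:
        raise ValueError(f"annual pollen total is zero in {year}: no season definable")
    tail = (100.0 - coverage) / 2.0 / 100.0
    lo, hi = tail * total, (1.0 - tail) * total
    if lo > 0:
        i_start = int(np.argmax(csum >= lo))
    else:  # full coverage: first day carrying any pollen
        i_start = int(np.argmax(vals > 0))
    i_end = int(np.argmax(csum >= hi))
    dates = pd.date_range(y0, y1, freq="D")
    return SeasonWindow(dates[i_start], dates[i_end])


def extended_window(windows: Iterable[SeasonWindow]) -> SeasonWindow:
    """Common imputation period spanning several observed seasons.

    The earliest start is extended back to the first day of its month and the
    latest end forward to the last day of its month, giving a fixed
    month-aligned window shared by all stations of a taxon.
    """
    wins = list(windows)
    if not wins:
        raise ValueError("no windows given")
    start = min(w.start for w in wins)
    end = max(w.end for w in wins)
    start = start.replace(day=1)
    end = end + pd.offsets.MonthEnd(0)
    return SeasonWindow(start, end)


def descriptive_stats(series: PollenSeries, window: SeasonWindow) -> SummaryStats:
    """Mean, SD, CV, quartiles, maximum and duration over ``window``."""
    vals = series.slice(window)
    present = vals[~np.isnan(vals)]
    if len(present) < 2:
        raise ValueError("need at least 2 present values for descriptive statistics")
    mean = float(present.mean())
    sd = float(present.std(ddof=1))
    cv = sd / mean * 100.0 if mean > 0 else float("nan")
    q1, median, q3 = (float(q) for q in np.quantile(present, [0.25, 0.5, 0.75]))
    return SummaryStats(
        mean=mean,
        sd=sd,
        cv=cv,
        q1=q1,
        median=median,
        q3=q3,
        max=float(present.max()),
        duration=window.duration,
    )


def variation_index(series: PollenSeries, window: SeasonWindow) -> float:
    """Variation Index (VIn) over ``window``, in percent.

    For every pair of consecutive days with both values present, the two-day
    moving CV is the sample SD of the pair (|a - b| / sqrt(2)) divided by the
    pair mean; VIn is the average of these CVs x 100.  Pairs with a missing
    member or zero mean are excluded (the CV is undefined at mean zero).
    """
    vals = series.slice(window)
    a, b = vals[:-1], vals[1:]
    valid = ~np.isnan(a) & ~np.isnan(b)
    means = (a + b) / 2.0
    valid &= means > 0
    if not valid.any():
        raise ValueError("no valid consecutive-day pair in window")
    cvs = (np.abs(a - b) / np.sqrt(2.0))[valid] / means[valid]
    return float(cvs.mean() * 100.0)
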