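"""Core containers for daily pollen-concentration series and tabular I/O.

A :class:`PollenSeries` holds the daily concentration record of one taxon at
one monitoring station on a gap-free, strictly consecutive calendar-day axis;
days without a measurement are NaN.  A :class:`SeasonWindow` is an inclusive
calendar interval (a pollen season, or the fixed period used for imputation).

The on-disk format is delimited text with columns
``date,station,taxon,concentration`` (ISO-8601 dates; missing values written
as empty fields).
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PollenSeries",
    "SeasonWindow",
    "read_daily_concentrations",
    "write_daily_concentrations",
    "align_to_window",
]

COLUMNS = ("date", "station", "taxon", "concentration")

PathLike = Union[str, Path, IO[str]]


@dataclass(frozen=True)
class SeasonWindow:
    """Inclusive calendar-day interval (season bounds or imputation period)."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start).normalize())
        object.__setattr__(self, "end", pd.Timestamp(self.end).normalize())
        if self.start > self.end:
            raise ValueError(f"window start {self.start.date()} after end {self.end.date()}")

    @property
    def duration(self) -> int:
        """Number of calendar days in the window, both endpoints included."""
        return int((self.end - self.start).days) + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    def shift_to_year(self, year: int) -> "SeasonWindow":
        """Same month/day bounds transplanted into another calendar year.

        A day-of-month that does not exist in the target year's month (e.g. a
        month-end) is clamped to that month's last day.
        """

        def _move(ts: pd.Timestamp) -> pd.Timestamp:
            day = min(ts.day, calendar.monthrange(year, ts.month)[1])
            return pd.Timestamp(year=year, month=ts.month, day=day)

        return SeasonWindow(_move(self.start), _move(self.end))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SeasonWindow({self.start.date()} .. {self.end.date()}, "
            f"{self.duration} days)"
        )


@dataclass
class PollenSeries:
    """Daily concentrations (pollen grains / m^3) for one station and taxon.

    Invariants enforced at construction: dates are strictly consecutive
    calendar days, every present value is nonnegative and finite, and the
    value vector matches the date axis in length.
    """

    station_id: str
    taxon: str
    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates).normalize()
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError(
                f"{len(self.dates)} dates but {len(self.values)} values"
            )
        if len(self.dates) == 0:
            raise ValueError("empty series")
        steps = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if len(steps) and not np.all(steps == 1):
            raise ValueError("dates must be strictly consecutive calendar days")
        present = self.values[~np.isnan(self.values)]
        if np.any(present < 0) or np.any(~np.isfinite(present)):
            raise ValueError("present concentrations must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    def copy(self) -> "PollenSeries":
        return PollenSeries(
            self.station_id, self.taxon, self.dates.copy(), self.values.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "station": self.station_id,
                "taxon": self.taxon,
                "concentration": self.values,
            }
        )

    def slice(self, window: SeasonWindow) -> np.ndarray:
        """Values inside ``window`` (no leap-day handling); view-free copy."""
        if window.start < self.start or window.end > self.end:
            raise ValueError(
                f"window {window} outside series range "
                f"{self.start.date()}..{self.end.date()}"
            )
        i0 = int((window.start - self.start).days)
        return self.values[i0 : i0 + window.duration].copy()


def read_daily_concentrations(source: PathLike, sep: str = ",") -> list[PollenSeries]:
    """Read delimited text into one gap-free :class:`PollenSeries` per unit.

    Expected columns: ``date,station,taxon,concentration``.  Dates absent
    from the file are materialized as NaN so each series covers a consecutive
    day axis from its first to last recorded date.  Rows with negative
    concentrations are rejected with a warning (the day becomes missing);
    duplicate ``(date, station, taxon)`` rows raise ``ValueError``.
    """
    df = pd.read_csv(source, sep=sep)
    missing_cols = set(COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing required columns: {sorted(missing_cols)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.normalize()
    df["concentration"] = pd.to_numeric(df["concentration"])

    dup = df.duplicated(subset=["date", "station", "taxon"], keep=False)
    if dup.any():
        bad = df.loc[dup, ["date", "station", "taxon"]].iloc[0]
        raise ValueError(
            f"duplicate entry for {bad['station']}/{bad['taxon']} on "
            f"{bad['date'].date()}"
        )
    neg = df["concentration"] < 0
    if neg.any():
        for _, row in df[neg].iterrows():
            warnings.warn(
                f"negative concentration {row['concentration']} for "
                f"{row['station']}/{row['taxon']} on {row['date'].date()}: "
                "row rejected",
                stacklevel=2,
            )
        df = df[~neg]

    out: list[PollenSeries] = []
    for (station, taxon), grp in df.groupby(["station", "taxon"], sort=True):
        grp = grp.sort_values("date")
        axis = pd.date_range(grp["date"].iloc[0], grp["date"].iloc[-1], freq="D")
        values = grp.set_index("date")["concentration"].reindex(axis).to_numpy()
        out.append(PollenSeries(str(station), str(taxon), axis, values))
    return out


def write_daily_concentrations(
    series: Iterable[PollenSeries], target: PathLike, sep: str = ","
) -> None:
    """Write series to delimited text (missing values as empty fields)."""
    frames = [s.to_frame() for s in series]
    df = pd.concat(frames, ignore_index=True)
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(target, sep=sep, index=False, na_rep="")


def align_to_window(
    series: PollenSeries, window: SeasonWindow, drop_leap_day: bool = False
) -> np.ndarray:
    """Extract the value vector of ``series`` over ``window``.

    With ``drop_leap_day``, Feb 29 (if inside the window) is removed so that
    the same month/day window has identical length in leap and common years —
    a requirement for stacking yearly columns into one rectangular matrix.
    """
    vals = series.slice(window)
    if drop_leap_day:
        dates = window.dates()
        leap = (dates.month == 2) & (dates.day == 29)
        if leap.any():
            vals = vals[~leap]
    return vals
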