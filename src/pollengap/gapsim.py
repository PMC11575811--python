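"""Missing-data scenario arithmetic and random gap placement.

A scenario is defined by a season (window) length, a target proportion of
missing days, and a fixed gap length (run of consecutive missing days).
:func:`plan_gaps` converts the target proportion into an integer number of
non-overlapping runs; :func:`place_gaps` draws a concrete missingness mask
uniformly at random over all valid placements; :func:`build_scenarios`
expands the full factorial study grid with per-replicate seeds.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["GapPlan", "plan_gaps", "place_gaps", "build_scenarios", "derive_seed"]

#: study defaults: missing proportions and gap lengths of the simulation grid
DEFAULT_PROPORTIONS = (0.05, 0.10, 0.25)
DEFAULT_GAP_LENGTHS = (3, 5, 7, 10)


@dataclass(frozen=True)
class GapPlan:
    """Resolved scenario: how many runs of which length in a given window."""

    na_prop: float
    gap_len: int
    season_len: int
    target_days: float
    n_gaps: int
    total_na_days: int
    resulting_pct: float

    def __post_init__(self) -> None:
        if self.total_na_days != self.n_gaps * self.gap_len:
            raise ValueError("total_na_days must equal n_gaps * gap_len")
        if self.total_na_days > self.season_len:
            raise ValueError(
                f"{self.n_gaps} gaps of {self.gap_len} days do not fit in "
                f"{self.season_len} days"
            )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def plan_gaps(
    season_len: int,
    na_prop: float,
    gap_len: int,
    rounding: str = "half-away",
) -> GapPlan:
    """Number of gap runs approximating ``na_prop`` missingness.

    ``target_days = na_prop * season_len`` is divided by the gap length and
    rounded (half away from zero by default, ``rounding='half-even'`` for
    banker's rounding), with a floor of one run.  The realized missing
    percentage therefore deviates from the nominal one by up to about half a
    gap length.
    """
    if not 0 < na_prop < 1:
        raise ValueError("na_prop must be a fraction in (0, 1)")
    if gap_len < 1:
        raise ValueError("gap_len must be >= 1")
    if season_len < gap_len:
        raise ValueError("season shorter than one gap")
    target = na_prop * season_len
    if rounding == "half-away":
        n_gaps = _round_half_away(target / gap_len)
    elif rounding == "half-even":
        n_gaps = round(target / gap_len)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    n_gaps = max(1, n_gaps)
    total = n_gaps * gap_len
    if total > season_len:
        raise ValueError(
            f"infeasible scenario: {n_gaps} gaps x {gap_len} days > "
            f"{season_len}-day season"
        )
    return GapPlan(
        na_prop=na_prop,
        gap_len=gap_len,
        season_len=season_len,
        target_days=target,
        n_gaps=n_gaps,
        total_na_days=total,
        resulting_pct=total / season_len * 100.0,
    )


def place_gaps(
    season_len: int,
    plan: GapPlan,
    seed: int,
    forbid_adjacent: bool = True,
) -> np.ndarray:
    """Draw a boolean mask with the plan's runs placed uniformly at random.

    True marks a day to remove.  Runs never overlap; by default they may not
    touch either (at least one observed day separates consecutive runs), so
    every realized missing run has length exactly ``plan.gap_len``.  The draw
    is uniform over all valid configurations via the stars-and-bars bijection,
    so it needs no rejection loop and reaches every feasible mask.
    """
    k, L = plan.n_gaps, plan.gap_len
    sep = 1 if forbid_adjacent else 0
    slack = season_len - k * L - (k - 1) * sep
    if slack < 0:
        raise ValueError(
            f"cannot place {k} runs of {L} days in {season_len} days"
            + (" without adjacency" if sep else "")
        )
    rng = np.random.default_rng(seed)
    # sorted k-subset of {0..slack+k-1} maps to a nondecreasing k-tuple in
    # {0..slack}; offsets then spread the runs with the mandatory separation
    draw = np.sort(rng.choice(slack + k, size=k, replace=False))
    frees = draw - np.arange(k)
    starts = frees + np.arange(k) * (L + sep)
    mask = np.zeros(season_len, dtype=bool)
    for s in starts:
        mask[s : s + L] = True
    return mask


def derive_seed(master_seed: int, *keys: object) -> int:
    """Deterministic child seed (< 2^31) from a master seed and any keys."""
    entropy = [int(master_seed) & 0xFFFFFFFF]
    for key in keys:
        if isinstance(key, (int, np.integer)):
            entropy.append(int(key) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(key).encode()))
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_scenarios(
    units: Sequence[tuple[str, str, int]],
    proportions: Iterable[float] = DEFAULT_PROPORTIONS,
    gap_lengths: Iterable[int] = DEFAULT_GAP_LENGTHS,
    replicates: int = 100,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Expand the factorial scenario grid into one row per replicate.

    ``units`` are ``(pollen, station, season_len)`` triples.  Every unit gets
    one :class:`GapPlan` per (proportion, gap length) cell and ``replicates``
    independent placement seeds per plan, derived deterministically from the
    master seed.
    """
    rows = []
    for pollen, station, season_len in units:
        for prop in proportions:
            for gap_len in gap_lengths:
                plan = plan_gaps(season_len, prop, gap_len)
                for rep in range(replicates):
                    rows.append(
                        {
                            "pollen": pollen,
                            "station": station,
                            "season_len": season_len,
                            "na_prop": prop,
                            "gap_len": gap_len,
                            "n_gaps": plan.n_gaps,
                            "total_na_days": plan.total_na_days,
                            "resulting_pct": plan.resulting_pct,
                            "replicate": rep,
                            "seed": derive_seed(
                                master_seed, pollen, station, prop, gap_len, rep
                            ),
                        }
                    )
    return pd.DataFrame(rows)
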