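"""End-to-end simulation study orchestration.

For every (taxon, station) unit with a complete target year, the study:

1. defines the taxon's 95% pollen season in the target year at each station
   and extends the earliest start / latest end to month boundaries, giving
   one fixed imputation window per taxon;
2. builds the factorial scenario grid (missing proportions x gap lengths),
   resolves each cell into a number of non-overlapping gap runs and draws
   the replicate missingness masks;
3. imputes every gappy replicate with each configured method — moving mean
   column by column, gappy SVD on the day-by-series matrix that stacks the
   historical yearly columns with all replicate columns of the cell;
4. scores each replicate by RMSE against the true target-year values over
   the full imputation window and summarises: per-cell medians, the
   Variation Index of each unit, and per-stratum log-RMSE regressions with
   robust standard errors.

Everything downstream of the master seed is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import PollenSeries, SeasonWindow, align_to_window
from .evaluate import RECORD_COLUMNS, fit_error_model, rmse, summarize_rmse
from .gapsim import (
    DEFAULT_GAP_LENGTHS,
    DEFAULT_PROPORTIONS,
    derive_seed,
    place_gaps,
    plan_gaps,
)
from .imputers import GsvdConfig, assemble_matrix, gsvd_impute, moving_mean_fill
from .season import extended_window, season_bounds, variation_index
from .synthdata import make_study_fixture

__all__ = ["MethodSpec", "StudyConfig", "StudyResult", "run_study"]


@dataclass(frozen=True)
class MethodSpec:
    """One imputation method configuration.

    ``name`` is ``"movingmean"`` or ``"gsvd"``; for gappy SVD, ``modes`` and
    ``init`` select the truncation order and the initial gap fill.
    """

    name: str
    modes: int | None = None
    init: str | None = None

    def __post_init__(self) -> None:
        if self.name not in ("movingmean", "gsvd"):
            raise ValueError(f"unknown method {self.name!r}")
        if self.name == "gsvd" and (self.modes is None or self.init is None):
            raise ValueError("gsvd method needs modes and init")

    @property
    def label(self) -> str:
        if self.name == "movingmean":
            return "movingmean"
        init_tag = {"mean": "mean", "linear": "interp"}[self.init]
        return f"gsvd-{init_tag}-{self.modes}m"


DEFAULT_METHODS: tuple[MethodSpec, ...] = (
    MethodSpec("movingmean"),
    MethodSpec("gsvd", modes=5, init="mean"),
    MethodSpec("gsvd", modes=10, init="linear"),
)


@dataclass
class StudyConfig:
    """Full study configuration.

    Provide either ``dataset`` (complete multi-year series) or
    ``synth_seed`` to generate the built-in synthetic fixture.  The target
    year must be complete for every unit over its imputation window.
    """

    dataset: list[PollenSeries] | None = None
    synth_seed: int | None = None
    target_year: int = 2022
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    gap_lengths: tuple[int, ...] = DEFAULT_GAP_LENGTHS
    replicates: int = 100
    methods: tuple[MethodSpec, ...] = DEFAULT_METHODS
    include_reference_year: bool = True
    coverage: float = 95.0
    tol: float = 1e-6
    max_iter: int = 1000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not all(0 < p < 1 for p in self.proportions):
            raise ValueError("proportions must be fractions in (0, 1)")
        if self.dataset is None and self.synth_seed is None:
            raise ValueError("provide a dataset or a synth_seed")


@dataclass
class StudyResult:
    """All study outputs as tidy tables plus the run log."""

    windows: dict[str, SeasonWindow]
    vin: pd.DataFrame
    scenarios: pd.DataFrame
    records: pd.DataFrame
    medians: pd.DataFrame
    effects: pd.DataFrame
    log: dict

    def write(self, out_dir: str | Path) -> None:
        """Write scenarios/records/medians/effects CSVs and the run log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scenarios.to_csv(out / "scenarios.csv", index=False)
        self.records.to_csv(out / "records.csv", index=False)
        self.medians.to_csv(out / "medians.csv", index=False)
        self.effects.to_csv(out / "effects.csv", index=False)
        self.vin.to_csv(out / "vin.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2, sort_keys=True)


def _units(dataset: Sequence[PollenSeries]) -> dict[tuple[str, str], PollenSeries]:
    units = {}
    for s in dataset:
        key = (s.taxon, s.station_id)
        if key in units:
            raise ValueError(f"duplicate unit {key}")
        units[key] = s
    return units


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the complete simulation study (see module docstring)."""
    dataset = (
        config.dataset
        if config.dataset is not None
        else make_study_fixture(config.synth_seed)
    )
    units = _units(dataset)
    taxa = sorted({t for t, _ in units})
    year = config.target_year

    # one month-extended imputation window per taxon, spanning all stations
    windows: dict[str, SeasonWindow] = {}
    for taxon in taxa:
        seasons = [
            season_bounds(series, year, config.coverage)
            for (t, _), series in sorted(units.items())
            if t == taxon
        ]
        windows[taxon] = extended_window(seasons)

    # candidate yearly columns (the target year's complete column included)
    years = list(
        range(
            min(s.start.year for s in units.values()),
            max(s.end.year for s in units.values()) + 1,
        )
    )

    scenario_rows = []
    record_rows = []
    vin_rows = []
    cell_log: list[dict] = []

    for (taxon, station), series in sorted(units.items()):
        window = windows[taxon]
        target = align_to_window(series, window, drop_leap_day=True)
        if np.isnan(target).any():
            raise ValueError(
                f"target year {year} incomplete for {taxon}/{station}: "
                "cannot run the simulation"
            )
        n_days = len(target)
        historical = {}
        for y in years:
            win_y = window.shift_to_year(y)
            if win_y.start < series.start or win_y.end > series.end:
                continue
            historical[str(y)] = align_to_window(series, win_y, drop_leap_day=True)
        season = season_bounds(series, year, config.coverage)
        vin_rows.append(
            {
                "pollen": taxon,
                "station": station,
                "vin": variation_index(series, season),
                "season_start": str(season.start.date()),
                "season_end": str(season.end.date()),
                "season_duration": season.duration,
                "window_start": str(window.start.date()),
                "window_end": str(window.end.date()),
                "window_days": n_days,
            }
        )

        for prop in config.proportions:
            for gap_len in config.gap_lengths:
                plan = plan_gaps(n_days, prop, gap_len)
                masks = []
                for rep in range(config.replicates):
                    seed = derive_seed(
                        config.master_seed, taxon, station, prop, gap_len, rep
                    )
                    masks.append(place_gaps(n_days, plan, seed))
                    scenario_rows.append(
                        {
                            "pollen": taxon,
                            "station": station,
                            "na_prop": prop,
                            "gap_len": gap_len,
                            "n_gaps": plan.n_gaps,
                            "total_na_days": plan.total_na_days,
                            "resulting_pct": plan.resulting_pct,
                            "replicate": rep,
                            "seed": seed,
                        }
                    )
                gappy = []
                for mask in masks:
                    g = target.copy()
                    g[mask] = np.nan
                    gappy.append(g)

                for method in config.methods:
                    if method.name == "movingmean":
                        preds = [moving_mean_fill(g) for g in gappy]
                        diag = None
                    else:
                        matrix = assemble_matrix(
                            historical,
                            {f"rep{i}": g for i, g in enumerate(gappy)},
                            include_reference_year=config.include_reference_year,
                            reference_label=str(year),
                        )
                        result = gsvd_impute(
                            matrix,
                            GsvdConfig(
                                n_modes=method.modes,
                                init=method.init,
                                tol=config.tol,
                                max_iter=config.max_iter,
                            ),
                        )
                        n_hist = matrix.shape[1] - len(gappy)
                        preds = [
                            result.completed[:, n_hist + i]
                            for i in range(len(gappy))
                        ]
                        diag = {
                            "iterations": result.iterations,
                            "final_delta": result.final_delta,
                            "converged": bool(result.converged),
                        }
                    cell_log.append(
                        {
                            "pollen": taxon,
                            "station": station,
                            "na_prop": prop,
                            "gap_len": gap_len,
                            "method": method.label,
                            **(diag or {}),
                        }
                    )
                    for rep, pred in enumerate(preds):
                        record_rows.append(
                            {
                                "pollen": taxon,
                                "station": station,
                                "method": method.label,
                                "na_prop": int(round(prop * 100)),
                                "gap_len": gap_len,
                                "replicate": rep,
                                "rmse": rmse(pred, target),
                            }
                        )

    records = pd.DataFrame(record_rows, columns=RECORD_COLUMNS)
    if records.duplicated(subset=RECORD_COLUMNS[:-1]).any():
        raise RuntimeError("duplicate evaluation records produced")
    vin = pd.DataFrame(vin_rows)
    medians = summarize_rmse(records).merge(
        vin[["pollen", "station", "vin"]], on=["pollen", "station"], how="left"
    )

    effect_frames = []
    ref_prop = int(round(min(config.proportions) * 100))
    ref_gap = min(config.gap_lengths)
    for (taxon, station), grp in records.groupby(["pollen", "station"]):
        eff = fit_error_model(
            grp, references=(config.methods[0].label, ref_prop, ref_gap)
        )
        eff.insert(0, "station", station)
        eff.insert(0, "pollen", taxon)
        effect_frames.append(eff)
    effects = pd.concat(effect_frames, ignore_index=True)

    log = {
        "master_seed": config.master_seed,
        "target_year": year,
        "replicates": config.replicates,
        "include_reference_year": config.include_reference_year,
        "methods": [m.label for m in config.methods],
        "windows": {
            t: [str(w.start.date()), str(w.end.date()), w.duration]
            for t, w in windows.items()
        },
        "cells": cell_log,
    }
    return StudyResult(
        windows=windows,
        vin=vin,
        scenarios=pd.DataFrame(scenario_rows),
        records=records,
        medians=medians,
        effects=effects,
        log=log,
    )
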