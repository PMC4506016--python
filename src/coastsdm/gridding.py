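"""From raw sightings and effort to the modelling frame.

The modelling frame (*cell-season-year table*) has one row per surveyed
cell-season-year stratum carrying the three ecological measurements —
presence/absence, number of sightings, summed group size — the survey effort
offset, and the environmental predictor values for that stratum.
"""

from __future__ import annotations

import logging
from datetime import date as _date

import numpy as np
import pandas as pd

from .grid import Grid
from .synthetic import PREDICTORS, EnvLayerStack, SurveyDataset

logger = logging.getLogger(__name__)

RESPONSES = ("presence", "n_sightings", "group_size_sum")

_MONTH_SEASON = {
    1: "summer", 2: "summer", 3: "summer",
    4: "autumn", 5: "autumn", 6: "autumn",
    7: "winter", 8: "winter", 9: "winter",
    10: "spring", 11: "spring", 12: "spring",
}


def assign_season(date) -> str:
    """Season label from a calendar date.

    Seasons follow the local sea-weather convention: summer Jan-Mar,
    autumn Apr-Jun, winter Jul-Sep, spring Oct-Dec.
    """
    if isinstance(date, str):
        ts = pd.to_datetime(date, format="ISO8601")
    elif isinstance(date, (pd.Timestamp, _date)):
        ts = pd.Timestamp(date)
    else:
        raise TypeError(f"cannot interpret {date!r} as a date")
    return _MONTH_SEASON[ts.month]


def rasterize_observations(records: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """Bin sighting records to (cell, season, year) strata.

    Returns the records with ``cell_id``, ``season`` and ``year`` columns
    attached; out-of-bounds records are dropped (their count is logged and
    available via the ``attrs['n_out_of_bounds']`` of the result).
    """
    out = records.copy()
    dates = pd.to_datetime(out["date"], format="ISO8601")
    out["season"] = dates.dt.month.map(_MONTH_SEASON)
    out["year"] = dates.dt.year
    out["cell_id"] = grid.cell_index_of(
        out["x_km"].to_numpy(), out["y_km"].to_numpy()
    )
    oob = int((out["cell_id"] < 0).sum())
    if oob:
        logger.warning("%d sighting records fall outside the grid", oob)
    out = out[out["cell_id"] >= 0].reset_index(drop=True)
    out.attrs["n_out_of_bounds"] = oob
    return out


def compute_ecological_measurements(
    rasterized: pd.DataFrame, effort: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate records into the three per-stratum ecological measurements.

    Every stratum with recorded effort appears in the output; strata with no
    sightings get (presence 0, n_sightings 0, group_size_sum 0).  Sightings
    falling in strata without recorded effort trigger a consistency warning
    and are kept with effort NaN.
    """
    key = ["cell_id", "season", "year"]
    agg = (
        rasterized.groupby(key)
        .agg(n_sightings=("group_size", "size"), group_size_sum=("group_size", "sum"))
        .reset_index()
    )
    table = effort.merge(agg, on=key, how="outer")
    no_effort = table["effort_km"].isna() & (table["n_sightings"].fillna(0) > 0)
    if no_effort.any():
        logger.warning(
            "%d strata contain sightings but no recorded effort", int(no_effort.sum())
        )
    table[["n_sightings", "group_size_sum"]] = (
        table[["n_sightings", "group_size_sum"]].fillna(0).astype(int)
    )
    table["presence"] = (table["n_sightings"] >= 1).astype(int)
    return table.sort_values(key).reset_index(drop=True)


def filter_min_effort(table: pd.DataFrame, min_km: float = 1.0) -> pd.DataFrame:
    """Drop strata with less than ``min_km`` of survey effort (inclusive keep).

    The 1 km default guards against small-sample bias from barely surveyed
    cells.  The number of removed rows is logged.
    """
    keep = table["effort_km"] >= min_km
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("effort filter removed %d strata below %g km", n_removed, min_km)
    out = table[keep].reset_index(drop=True)
    out.attrs["n_removed_by_effort_filter"] = n_removed
    return out


def join_environment(table: pd.DataFrame, env: EnvLayerStack) -> pd.DataFrame:
    """Attach the ten predictor columns to each stratum row."""
    return table.merge(env.long_frame(), on=["cell_id", "season", "year"], how="left")


def build_cell_season_table(
    dataset: SurveyDataset,
    env: EnvLayerStack | None = None,
    min_effort_km: float = 1.0,
) -> pd.DataFrame:
    """Full gridding chain: rasterize, aggregate, effort-filter, join predictors."""
    env = env or dataset.env
    rast = rasterize_observations(dataset.sightings, dataset.grid)
    table = compute_ecological_measurements(rast, dataset.effort)
    table = table[table["effort_km"].notna()]
    table = filter_min_effort(table, min_effort_km)
    if env is not None:
        table = join_environment(table, env)
        missing = table[PREDICTORS].isna().any(axis=1)
        if missing.any():
            logger.warning("%d strata lack predictor values", int(missing.sum()))
    return table


def yearly_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Survey-summary table: one row per year plus a ``Total`` row.

    Columns: number of distinct seasons surveyed, total searching effort (km),
    number of cell-season strata with presence, total sightings, total summed
    group size.
    """
    per_year = (
        table.groupby("year")
        .agg(
            seasons=("season", "nunique"),
            effort_km=("effort_km", "sum"),
            cells_present=("presence", "sum"),
            sightings=("n_sightings", "sum"),
            group_size=("group_size_sum", "sum"),
        )
        .reset_index()
    )
    total = pd.DataFrame([{
        "year": "Total",
        "seasons": per_year["seasons"].sum(),
        "effort_km": per_year["effort_km"].sum(),
        "cells_present": per_year["cells_present"].sum(),
        "sightings": per_year["sightings"].sum(),
        "group_size": per_year["group_size"].sum(),
    }])
    return pd.concat([per_year, total], ignore_index=True)
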