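"""Shared fixtures: a simulated default survey and a printed-summary fixture."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coastsdm.gridding import build_cell_season_table
from coastsdm.screening import PredictorStandardizer
from coastsdm.synthetic import PREDICTORS, StudyScenario, simulate_survey


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated survey under the default study emulation."""
    return simulate_survey(StudyScenario(), seed=7)


@pytest.fixture(scope="session")
def default_table(default_dataset):
    return build_cell_season_table(default_dataset)


@pytest.fixture(scope="session")
def default_ztable(default_table):
    std = PredictorStandardizer(columns=PREDICTORS).fit(default_table)
    return std.transform(default_table)


# printed yearly survey summary: (year, seasons, effort km, cells with
# presence, sightings, summed group size)
PRINTED_YEARLY_ROWS = [
    (2006, 4, 3887, 73, 131, 981),
    (2007, 4, 3757, 89, 137, 1184),
    (2008, 2, 1849, 42, 70, 747),
    (2009, 4, 4009, 94, 152, 1601),
]
PRINTED_TOTALS = {
    "seasons": 14, "effort_km": 13502, "cells_present": 298,
    "sightings": 490, "group_size": 4513,
}

_SEASON_OF = {1: "summer", 2: "autumn", 3: "winter", 4: "spring"}
_SEASON_MONTH = {"summer": 2, "autumn": 5, "winter": 8, "spring": 11}


def make_printed_survey() -> pd.DataFrame:
    """A minimal cell-season-year table whose yearly summary equals the
    printed survey-summary rows exactly.

    Construction: each year uses its printed number of seasons; presence
    strata are spread over distinct (cell, season) combinations; one stratum
    absorbs the surplus sightings and group size so that the totals match.
    """
    rows = []
    for (year, n_seasons, effort, n_present, n_sight, n_ind) in PRINTED_YEARLY_ROWS:
        seasons = [_SEASON_OF[i + 1] for i in range(n_seasons)]
        extra_sightings = n_sight - n_present
        extra_individuals = n_ind - n_sight
        for j in range(n_present):
            season = seasons[j % n_seasons]
            cell = j // n_seasons
            sightings = 1 + (extra_sightings if j == 0 else 0)
            group_sum = sightings + (extra_individuals if j == 0 else 0)
            rows.append({
                "cell_id": cell, "season": season, "year": year,
                "effort_km": 0.0, "presence": 1,
                "n_sightings": sightings, "group_size_sum": group_sum,
            })
        # spread the printed effort evenly over the year's strata, adding
        # one absence stratum per season so every season is represented
        for k, season in enumerate(seasons):
            rows.append({
                "cell_id": 10_000 + k, "season": season, "year": year,
                "effort_km": 0.0, "presence": 0,
                "n_sightings": 0, "group_size_sum": 0,
            })
    table = pd.DataFrame(rows)
    for (year, _, effort, *_rest) in PRINTED_YEARLY_ROWS:
        sel = table["year"] == year
        table.loc[sel, "effort_km"] = effort / sel.sum()
    return table


@pytest.fixture(scope="session")
def printed_survey_table():
    return make_printed_survey()
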