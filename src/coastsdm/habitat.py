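"""Habitat classification, abundance surfaces and protected-area assessment.

Seasonal prediction surfaces are summarized into per-cell mean and SD maps.
Cells are then classified relative to the grid-wide averages of those maps:

* recurrent    — high mean (above the global mean) and low SD;
* occasional   — high SD (above the global SD), whatever the mean;
* unfavourable — low mean and low SD;
* uncategorized — cells missing any seasonal prediction.

Recurrent plus occasional cells constitute the key areas.  Comparisons with
respect to a protected-area mask report the share of each category inside
and outside, Welch two-sample t tests on the per-cell mean predictions, and
the fraction of key habitat the protected area captures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

from .grid import Grid

CATEGORIES = ("recurrent", "occasional", "unfavourable", "uncategorized")


def prediction_summary(stack) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean and sample SD over a list of seasonal surfaces.

    Cells with a missing (NaN) value in any layer are marked NaN in both
    outputs: classification treats them as unsampled.
    """
    layers = [np.asarray(s, dtype=float) for s in stack]
    if len(layers) == 0:
        raise ValueError("empty prediction stack")
    if len(layers) < 2:
        raise ValueError("need at least two layers to compute an SD map")
    arr = np.stack(layers)
    complete = ~np.isnan(arr).any(axis=0)
    mean = np.where(complete, arr.mean(axis=0), np.nan)
    sd = np.where(complete, arr.std(axis=0, ddof=1), np.nan)
    return mean, sd


def classify_habitat(mean_map: np.ndarray, sd_map: np.ndarray) -> pd.DataFrame:
    """Classify each cell from its prediction mean and SD.

    Global thresholds are the averages of the mean map and the SD map over
    categorizable (non-NaN) cells.  The SD rule takes precedence: a cell
    with both high mean and high SD is occasional.  Threshold ties fall to
    the low side (strict inequalities).
    """
    mean_map = np.asarray(mean_map, dtype=float)
    sd_map = np.asarray(sd_map, dtype=float)
    if mean_map.shape != sd_map.shape:
        raise ValueError("mean and SD maps are not aligned")
    ok = ~(np.isnan(mean_map) | np.isnan(sd_map))
    if not ok.any():
        raise ValueError("no categorizable cells")
    mean_thr = float(mean_map[ok].mean())
    sd_thr = float(sd_map[ok].mean())

    cat = np.full(mean_map.shape, "uncategorized", dtype=object)
    high_sd = ok & (sd_map > sd_thr)
    high_mean = ok & (mean_map > mean_thr)
    cat[ok] = "unfavourable"
    cat[high_mean & ~high_sd] = "recurrent"
    cat[high_sd] = "occasional"

    out = pd.DataFrame({
        "cell_id": np.arange(mean_map.size),
        "mean": mean_map,
        "sd": sd_map,
        "category": cat,
    })
    out.attrs["mean_threshold"] = mean_thr
    out.attrs["sd_threshold"] = sd_thr
    return out


def abundance_surface(
    sightings_surface: np.ndarray, group_size_surface: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-cell abundance as sightings x group size, and its total.

    The two ensemble surfaces must be aligned and refer to the same
    reference effort; the total sums the categorizable (non-NaN) cells.
    """
    s = np.asarray(sightings_surface, dtype=float)
    g = np.asarray(group_size_surface, dtype=float)
    if s.shape != g.shape:
        raise ValueError("surfaces are not aligned")
    ab = s * g
    total = float(np.nansum(ab))
    return ab, total


def build_mask(polygon, grid: Grid) -> np.ndarray:
    """Per-cell boolean protected-area mask: cell center inside the polygon."""
    if not isinstance(polygon, Polygon):
        ring = list(polygon)
        if len(ring) < 4 or tuple(ring[0]) != tuple(ring[-1]):
            raise ValueError("polygon ring must be closed (first == last vertex)")
        polygon = Polygon(ring)
    if not polygon.is_valid:
        raise ValueError("polygon is invalid (self-intersecting?)")
    centers = grid.cell_centers()
    return np.array([
        polygon.covers(Point(x, y)) for x, y in centers
    ], dtype=bool)


def mpa_comparison(
    habitat: pd.DataFrame,
    mask: np.ndarray,
    surfaces: dict[str, np.ndarray] | None = None,
) -> dict:
    """Assess how a protected area captures the classified habitat.

    Returns, per category, the percentage of that category's cells falling
    inside vs outside the mask; per supplied summary surface, a Welch
    two-sided t test comparing per-cell values inside vs outside (statistic
    signed as outside minus inside); and the percentage of key
    (recurrent + occasional) cells captured by the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != len(habitat):
        raise ValueError("mask is not defined for every grid cell")
    if mask.all() or (~mask).all():
        if (~mask).all():
            raise ValueError("mask selects no cells: comparison undefined")

    report: dict = {"categories": {}, "t_tests": {}}
    for cat in CATEGORIES:
        in_cat = habitat["category"].to_numpy() == cat
        n = int(in_cat.sum())
        if n == 0:
            report["categories"][cat] = {"n": 0, "pct_inside": np.nan,
                                         "pct_outside": np.nan}
            continue
        inside = int((in_cat & mask).sum())
        report["categories"][cat] = {
            "n": n,
            "pct_inside": 100.0 * inside / n,
            "pct_outside": 100.0 * (n - inside) / n,
        }

    key = habitat["category"].isin(["recurrent", "occasional"]).to_numpy()
    n_key = int(key.sum())
    report["pct_key_area_inside"] = (
        100.0 * int((key & mask).sum()) / n_key if n_key else np.nan
    )

    if surfaces:
        if (~mask).sum() == 0:
            raise ValueError("no outside cells: t test undefined")
        for name, surf in surfaces.items():
            v = np.asarray(surf, dtype=float)
            inside_v = v[mask & ~np.isnan(v)]
            outside_v = v[~mask & ~np.isnan(v)]
            if inside_v.size < 2 or outside_v.size < 2:
                raise ValueError(f"too few cells for a t test on {name!r}")
            t, p = stats.ttest_ind(outside_v, inside_v, equal_var=False)
            report["t_tests"][name] = {
                "t": float(t), "p_value": float(p),
                "mean_inside": float(inside_v.mean()),
                "mean_outside": float(outside_v.mean()),
            }
    return report
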