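"""Plain-text I/O: ESRI ASCII grids, survey CSV schemas, GeoJSON masks, YAML.

Rasters are exchanged as ESRI ASCII grids (``.asc``) so that every artefact
of the pipeline is human-readable text.  Surfaces are stored internally as
1-D vectors ordered by ``cell_id`` (row-major from the grid origin, i.e. the
southernmost row first); the ``.asc`` dialect stores the northernmost row
first, so writers and readers flip row order accordingly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape as shapely_shape

from .grid import Grid

NODATA = -9999.0

SIGHTINGS_COLUMNS = ["date", "x_km", "y_km", "group_size"]
EFFORT_COLUMNS = ["cell_id", "season", "year", "effort_km"]


def write_ascii_grid(path: str | Path, values, grid: Grid, nodata: float = NODATA) -> None:
    """Write a per-cell vector (ordered by cell_id, NaN = no data) as .asc."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_cells,):
        raise ValueError(
            f"expected {grid.n_cells} values for the grid, got shape {values.shape}"
        )
    arr = values.reshape(grid.n_y, grid.n_x)
    arr = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {grid.n_x}\n"
        f"nrows {grid.n_y}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {nodata:g}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in arr[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, Grid]:
    """Read an ESRI ASCII grid; returns (values ordered by cell_id, Grid)."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    grid = Grid(
        n_x=int(header["ncols"]),
        n_y=int(header["nrows"]),
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    nodata = header.get("nodata_value", NODATA)
    arr = np.loadtxt(lines[i:], dtype=float).reshape(grid.n_y, grid.n_x)
    arr = arr[::-1]  # file stores north row first; cell_id order starts south
    values = arr.ravel()
    values = np.where(values == nodata, np.nan, values)
    return values, grid


def write_sightings_csv(path: str | Path, sightings: pd.DataFrame) -> None:
    sightings = sightings[SIGHTINGS_COLUMNS].copy()
    sightings["date"] = pd.to_datetime(sightings["date"]).dt.strftime("%Y-%m-%d")
    sightings.to_csv(path, index=False)


def read_sightings_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SIGHTINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sightings file missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    return df[SIGHTINGS_COLUMNS]


def write_effort_csv(path: str | Path, effort: pd.DataFrame) -> None:
    effort[EFFORT_COLUMNS].to_csv(path, index=False)


def read_effort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EFFORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"effort file missing columns: {sorted(missing)}")
    return df[EFFORT_COLUMNS]


def read_mask_geojson(path: str | Path):
    """Read a planar polygon (or multipolygon) from a GeoJSON file."""
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in obj["features"]]
        from shapely.ops import unary_union

        return unary_union(geoms)
    if obj.get("type") == "Feature":
        return shapely_shape(obj["geometry"])
    return shapely_shape(obj)


def read_cell_mask_csv(path: str | Path, grid: Grid) -> np.ndarray:
    """Read an explicit inside-cell list (single ``cell_id`` column) as a mask."""
    ids = pd.read_csv(path)["cell_id"].to_numpy(dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= grid.n_cells):
        raise ValueError("cell_id outside grid range in mask file")
    mask = np.zeros(grid.n_cells, dtype=bool)
    mask[ids] = True
    return mask


def write_yaml(path: str | Path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
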