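"""Regular planar analysis grid.

All spatial work in the package happens on a regular square grid in planar
(projected) kilometre coordinates.  Survey observations are binned to cells,
environmental layers are stored per cell, and prediction surfaces are vectors
indexed by ``cell_id``.

Cells are half-open boxes ``[x, x + cell_size) x [y, y + cell_size)``: a point
lying exactly on an interior edge belongs to the cell with the higher index.
Cell ids run row-major from the grid origin: ``cell_id = iy * n_x + ix``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid:
    """A regular square grid in planar km coordinates.

    Parameters
    ----------
    n_x, n_y : int
        Number of columns / rows; must be >= 1.
    cell_size : float
        Edge length of one cell in km; must be > 0.
    origin : tuple of float
        (x, y) of the lower-left corner of cell (0, 0), in km.
    """

    n_x: int
    n_y: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates, ordered by cell_id."""
        ix = np.arange(self.n_x)
        iy = np.arange(self.n_y)
        gx, gy = np.meshgrid(ix, iy)  # shape (n_y, n_x), row-major like cell_id
        cx = self.origin[0] + (gx.ravel() + 0.5) * self.cell_size
        cy = self.origin[1] + (gy.ravel() + 0.5) * self.cell_size
        return np.column_stack([cx, cy])

    def cell_index_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Map point coordinates to cell ids; -1 for out-of-bounds points.

        Containment uses half-open cells, so a point on a shared edge maps to
        the higher-index cell, and a point on the outer max edge is out of
        bounds.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        iy = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        inside = (ix >= 0) & (ix < self.n_x) & (iy >= 0) & (iy < self.n_y)
        out = np.where(inside, iy * self.n_x + ix, -1)
        return out

    def to_meta(self) -> dict:
        return {
            "n_x": self.n_x,
            "n_y": self.n_y,
            "cell_size": self.cell_size,
            "origin": list(self.origin),
        }

    @classmethod
    def from_meta(cls, meta: dict) -> "Grid":
        return cls(
            n_x=int(meta["n_x"]),
            n_y=int(meta["n_y"]),
            cell_size=float(meta["cell_size"]),
            origin=tuple(float(v) for v in meta["origin"]),
        )


def generate_grid(
    n_x: int,
    n_y: int,
    cell_size: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Grid:
    """Build a regular planar grid (deterministic; no randomness involved)."""
    return Grid(n_x=n_x, n_y=n_y, cell_size=cell_size, origin=origin)
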