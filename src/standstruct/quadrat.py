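"""Quadrat-level aggregation: biotic summaries, structure means with an
inner buffer, transformed aspect (TRASP), and terrain metrics from a
corner-elevation raster.

The plot is tiled by square quadrats (default 20 m) indexed (row, col)
from the south-west corner.  Stems are assigned by half-open intervals,
so a stem exactly on an internal boundary belongs to the cell that
starts there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import StructureTable


class GridConfigError(ValueError):
    """Plot dimensions are not divisible by the quadrat size."""


@dataclass
class QuadratGrid:
    """Regular quadrat tiling of the plot."""

    cell: float
    nrows: int
    ncols: int

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cell_of(self, x, y):
        """(row, col) of each point; half-open interval rule."""
        col = np.floor(np.asarray(x, float) / self.cell).astype(int)
        row = np.floor(np.asarray(y, float) / self.cell).astype(int)
        # points exactly on the far plot edge belong to the last cell
        col = np.clip(col, 0, self.ncols - 1)
        row = np.clip(row, 0, self.nrows - 1)
        return row, col

    def centroids(self) -> pd.DataFrame:
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "cx": (cols.ravel() + 0.5) * self.cell,
                "cy": (rows.ravel() + 0.5) * self.cell,
            }
        )


def make_grid(geometry, cell: float = 20.0) -> QuadratGrid:
    nc, nr = geometry.width / cell, geometry.height / cell
    if abs(nc - round(nc)) > 1e-9 or abs(nr - round(nr)) > 1e-9:
        raise GridConfigError(
            f"plot {geometry.width}x{geometry.height} m is not divisible by {cell} m cells"
        )
    return QuadratGrid(cell=cell, nrows=int(round(nr)), ncols=int(round(nc)))


def grid_and_biotics(census, cell: float = 20.0):
    """Quadrat grid plus per-quadrat biotic summaries of the alive stems.

    Summaries per cell: stem count (Ind), mean and maximum DBH (cm), and
    basal area (m², sum of pi*(dbh/2)^2 over stems).  Every cell of the
    grid is present; empty cells carry Ind = 0 and NaN diameters.
    """
    grid = make_grid(census.geometry, cell)
    alive = census.alive()
    row, col = grid.cell_of(alive["x"].to_numpy(), alive["y"].to_numpy())
    df = pd.DataFrame(
        {
            "row": row,
            "col": col,
            "dbh": alive["dbh"].to_numpy(float),
        }
    )
    # basal area: dbh is in cm, area in m^2
    df["ba"] = np.pi * (df["dbh"] / 200.0) ** 2
    agg = df.groupby(["row", "col"]).agg(
        Ind=("dbh", "size"),
        meandbh=("dbh", "mean"),
        maxdbh=("dbh", "max"),
        basal_area=("ba", "sum"),
    )
    full = pd.MultiIndex.from_product(
        [range(grid.nrows), range(grid.ncols)], names=["row", "col"]
    )
    agg = agg.reindex(full)
    agg["Ind"] = agg["Ind"].fillna(0).astype(int)
    agg["basal_area"] = agg["basal_area"].fillna(0.0)
    return grid, agg.reset_index()


def quadrat_structure_means(
    table: StructureTable, grid: QuadratGrid, inner_buffer: float = 2.0
) -> pd.DataFrame:
    """Per-quadrat means of W, U, M over reference trees at least
    ``inner_buffer`` metres inside the quadrat boundary.

    Neighbour relations are plot-wide (the structure table is computed on
    the full census first); the inner buffer only decides which reference
    trees a quadrat averages over.  Quadrats with no eligible tree carry
    NaN and are excluded from downstream models.
    """
    t = table.table
    row, col = grid.cell_of(t["x"].to_numpy(), t["y"].to_numpy())
    # offsets within the quadrat
    ox = t["x"].to_numpy() - col * grid.cell
    oy = t["y"].to_numpy() - row * grid.cell
    inside = (
        (ox >= inner_buffer)
        & (ox <= grid.cell - inner_buffer)
        & (oy >= inner_buffer)
        & (oy <= grid.cell - inner_buffer)
    )
    sub = pd.DataFrame(
        {
            "row": row[inside],
            "col": col[inside],
            "W": t["W"].to_numpy()[inside],
            "U": t["U"].to_numpy()[inside],
            "M": t["M"].to_numpy()[inside],
        }
    )
    means = sub.groupby(["row", "col"])[["W", "U", "M"]].mean()
    full = pd.MultiIndex.from_product(
        [range(grid.nrows), range(grid.ncols)], names=["row", "col"]
    )
    return means.reindex(full).reset_index()


def trasp(aspect) -> np.ndarray | float:
    """Transformed aspect index in [0, 1].

    ``TRASP = (1 - cos((pi/180) * (aspect - 30))) / 2``: 0 at 30°
    (north-northeast, coolest) and 1 at 210° (south-southwest, hottest).
    Inputs are wrapped modulo 360.
    """
    a = np.asarray(aspect, dtype=float) % 360.0
    out = (1.0 - np.cos(np.radians(a - 30.0))) / 2.0
    return float(out) if out.ndim == 0 else out


def terrain_metrics(corner_z: np.ndarray, cell: float = 20.0) -> pd.DataFrame:
    """Per-quadrat elevation, slope, aspect, TRASP and convexity from a
    corner-elevation raster.

    ``corner_z`` has shape (nrows+1, ncols+1), row 0 at the south edge.
    Elevation is the mean of the four corners.  Slope is the mean angular
    slope of the four planes through three of the four corners (the
    standard large-plot convention).  Aspect is the downslope azimuth of
    the least-squares plane (degrees clockwise from north; NaN on flat
    cells).  Convexity is the quadrat elevation minus the mean elevation
    of its up-to-8 neighbouring quadrats.
    """
    z = np.asarray(corner_z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("corner grid must be (nrows+1) x (ncols+1)")
    if not np.all(np.isfinite(z)):
        bad = np.argwhere(~np.isfinite(z))[0]
        raise ValueError(f"missing corner elevation at (row={bad[0]}, col={bad[1]})")
    nrows, ncols = z.shape[0] - 1, z.shape[1] - 1
    z00 = z[:-1, :-1]  # SW
    z01 = z[:-1, 1:]   # SE
    z10 = z[1:, :-1]   # NW
    z11 = z[1:, 1:]    # NE
    elev = (z00 + z01 + z10 + z11) / 4.0

    # slope of the plane through 3 corners, for each corner left out.
    # gradient components are rises over one cell width.
    def tri_slope(gx, gy):
        return np.degrees(np.arctan(np.hypot(gx, gy) / cell))

    s1 = tri_slope(z01 - z00, z10 - z00)  # omit NE
    s2 = tri_slope(z11 - z10, z10 - z00)  # omit SE
    s3 = tri_slope(z01 - z00, z11 - z01)  # omit NW
    s4 = tri_slope(z11 - z10, z11 - z01)  # omit SW
    slope = (s1 + s2 + s3 + s4) / 4.0

    # least-squares plane z = a*x + b*y + c over the 4 corners:
    # a = mean east-west rise / cell, b = mean north-south rise / cell
    a = ((z01 - z00) + (z11 - z10)) / (2.0 * cell)
    b = ((z10 - z00) + (z11 - z01)) / (2.0 * cell)
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-a, -b)) % 360.0
    aspect[np.hypot(a, b) == 0] = np.nan

    # convexity vs the mean of available 8-neighbour elevations
    kernel_sum = np.zeros_like(elev)
    kernel_n = np.zeros_like(elev)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            src = elev[
                max(0, -dr) : nrows - max(0, dr), max(0, -dc) : ncols - max(0, dc)
            ]
            kernel_sum[
                max(0, dr) : nrows - max(0, -dr), max(0, dc) : ncols - max(0, -dc)
            ] += src
            kernel_n[
                max(0, dr) : nrows - max(0, -dr), max(0, dc) : ncols - max(0, -dc)
            ] += 1
    convexity = elev - kernel_sum / kernel_n

    rows, cols = np.mgrid[0:nrows, 0:ncols]
    return pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "elevation": elev.ravel(),
            "slope": slope.ravel(),
            "aspect": aspect.ravel(),
            "TRASP": trasp(np.nan_to_num(aspect.ravel(), nan=30.0)),
            "convexity": convexity.ravel(),
        }
    )


def quadrat_table(
    census,
    structure_table: StructureTable,
    corner_z: np.ndarray | None = None,
    rbr: pd.DataFrame | None = None,
    cell: float = 20.0,
    inner_buffer: float = 2.0,
) -> pd.DataFrame:
    """Assemble the full per-quadrat covariate table.

    Joins biotic summaries, structure means, terrain metrics (if a corner
    raster is given) and any extra per-quadrat columns such as RBR
    (expected columns ``row, col, ...``).
    """
    grid, biotics = grid_and_biotics(census, cell)
    sm = quadrat_structure_means(structure_table, grid, inner_buffer)
    out = biotics.merge(sm, on=["row", "col"], how="left")
    if corner_z is not None:
        out = out.merge(terrain_metrics(corner_z, cell), on=["row", "col"], how="left")
    if rbr is not None:
        out = out.merge(rbr, on=["row", "col"], how="left")
    return out
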