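"""Nearest-neighbour structural units and the three classical stand
spatial-structure indices.

Each alive tree far enough from the plot edge is a *reference tree*; with
its four nearest alive neighbours it forms a *structural unit* on which
three indices are computed, each taking one of the five levels
0, 0.25, 0.5, 0.75, 1:

* uniform angle index W — fraction of the four circular gaps between the
  sorted neighbour azimuths that fall below the standard angle of 72°
  (0 = very uniform spacing, 1 = very irregular);
* dominance U — fraction of neighbours with DBH strictly greater than
  the reference tree's (0 = predominant, 1 = absolutely disadvantaged);
* mingling M — fraction of heterospecific neighbours (0 = no mingling,
  1 = complete mingling).

Stand-level values are arithmetic means over reference trees.  The edge
buffer (default 5 m) removes trees whose neighbour set would be censored
by the plot boundary; buffer trees still serve as neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

LEVELS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
STANDARD_ANGLE = 72.0
N_NEIGHBORS = 4

PARAM_NAMES = ("W", "U", "M")


class EmptyResultError(ValueError):
    """An operation produced no eligible trees/cells."""


@dataclass
class StructureTable:
    """Per-reference-tree index table plus stand-level means.

    ``table`` has one row per reference tree with columns
    ``tree_id, x, y, species, dbh, W, U, M``.
    """

    table: pd.DataFrame
    buffer: float

    @property
    def n(self) -> int:
        return len(self.table)

    def stand_means(self) -> dict:
        return {p: float(self.table[p].mean()) for p in PARAM_NAMES}

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class LevelDistribution:
    """Relative-frequency distribution over level combinations.

    ``params`` is the ordered subset of (W, U, M); ``freq`` is an array of
    shape (5,)*arity whose cells sum to one; ``n`` the reference-tree count.
    """

    params: tuple
    freq: np.ndarray
    n: int

    @property
    def arity(self) -> int:
        return len(self.params)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per level combination plus frequency."""
        grids = np.meshgrid(*[LEVELS] * self.arity, indexing="ij")
        data = {f"level_{p}": g.ravel() for p, g in zip(self.params, grids)}
        data["freq"] = self.freq.ravel()
        return pd.DataFrame(data)


def _azimuth(dx, dy):
    """Azimuth in degrees, clockwise from north (+y), in [0, 360)."""
    return np.degrees(np.arctan2(dx, dy)) % 360.0


def neighbor_table(census, k: int = N_NEIGHBORS):
    """k nearest alive neighbours of every alive tree.

    Distance ties are broken by ascending ``tree_id``.  Returns
    ``(alive, neighbor_index)`` where ``alive`` is the alive-tree frame
    (positionally indexed) and ``neighbor_index`` is an (n, k) array of
    positions into it, ordered by increasing distance.
    """
    alive = census.alive().reset_index(drop=True)
    n = len(alive)
    if n < k + 1:
        raise EmptyResultError(f"need at least {k + 1} alive trees, have {n}")
    xy = alive[["x", "y"]].to_numpy(float)
    ids = alive["tree_id"].to_numpy(str)
    tree = cKDTree(xy)
    # query extra candidates so distance ties can be reordered by id
    kq = min(n, k + 4)
    dist, idx = tree.query(xy, k=kq)
    out = np.empty((n, k), dtype=np.intp)
    for i in range(n):
        d, j = dist[i], idx[i]
        keep = j != i
        d, j = d[keep], j[keep]
        # ties that straddle the query cutoff: fall back to a full scan
        if len(d) > k and d[k - 1] == d[-1]:
            dd = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
            dd[i] = np.inf
            order = np.lexsort((ids, dd))
            out[i] = order[:k]
            continue
        order = np.lexsort((ids[j], d))
        out[i] = j[order[:k]]
    return alive, out


def neighbor_set(census, reference_id, k: int = N_NEIGHBORS) -> dict:
    """Structural unit (neighbours only; indices unset) for one reference tree.

    Returns a dict with ``reference_id``, ``neighbor_ids`` (ordered by
    increasing distance, ties by ascending id), ``distances`` and
    ``azimuths`` (degrees clockwise from north).
    """
    alive, nbr = neighbor_table(census, k=k)
    pos = np.flatnonzero(alive["tree_id"].to_numpy(str) == str(reference_id))
    if len(pos) == 0:
        raise KeyError(f"tree {reference_id!r} is not an alive tree of this census")
    i = int(pos[0])
    js = nbr[i]
    xy = alive[["x", "y"]].to_numpy(float)
    dx = xy[js, 0] - xy[i, 0]
    dy = xy[js, 1] - xy[i, 1]
    return {
        "reference_id": str(reference_id),
        "neighbor_ids": list(alive["tree_id"].iloc[js]),
        "distances": np.hypot(dx, dy),
        "azimuths": _azimuth(dx, dy),
    }


def uniform_angle(azimuths, alpha0: float = STANDARD_ANGLE, convention: str = "gap") -> float:
    """Uniform angle index of one structural unit from neighbour azimuths.

    The four azimuths are sorted and the four circular gaps (summing to
    360°) formed; W is the fraction of gaps strictly below ``alpha0``.
    With ``convention="minor_arc"`` each gap is first replaced by
    min(gap, 360 − gap), the convention under which four tightly
    clustered neighbours score W = 1.
    """
    az = np.sort(np.asarray(azimuths, dtype=float) % 360.0)
    if az.shape[-1] != N_NEIGHBORS:
        raise ValueError(f"expected {N_NEIGHBORS} azimuths")
    gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
    if convention == "minor_arc":
        gaps = np.minimum(gaps, 360.0 - gaps)
    elif convention != "gap":
        raise ValueError("convention must be 'gap' or 'minor_arc'")
    return float(np.sum(gaps < alpha0) / N_NEIGHBORS)


def dominance(ref_dbh: float, neighbor_dbh) -> float:
    """Fraction of the four neighbours with DBH strictly above the reference.

    Equal DBH counts as "not larger" (deterministic tie rule)."""
    nd = np.asarray(neighbor_dbh, dtype=float)
    if nd.shape[-1] != N_NEIGHBORS or not np.all(np.isfinite(nd)) or not np.isfinite(ref_dbh):
        raise ValueError("dominance needs finite DBH for the reference and 4 neighbours")
    return float(np.sum(nd > ref_dbh) / N_NEIGHBORS)


def mingling(ref_species: str, neighbor_species) -> float:
    """Fraction of the four neighbours belonging to a different species."""
    ns = np.asarray(neighbor_species)
    if ns.shape[-1] != N_NEIGHBORS:
        raise ValueError("mingling needs 4 neighbour species")
    return float(np.sum(ns != ref_species) / N_NEIGHBORS)


def compute_structure(
    census,
    buffer: float = 5.0,
    alpha0: float = STANDARD_ANGLE,
    convention: str = "gap",
) -> StructureTable:
    """Per-tree W, U, M for every reference tree of a census.

    Every alive tree is a candidate neighbour; only trees at least
    ``buffer`` metres from each plot edge are reference trees.
    """
    geom = census.geometry
    alive, nbr = neighbor_table(census, k=N_NEIGHBORS)
    xy = alive[["x", "y"]].to_numpy(float)
    ref_mask = (
        (xy[:, 0] >= buffer)
        & (xy[:, 0] <= geom.width - buffer)
        & (xy[:, 1] >= buffer)
        & (xy[:, 1] <= geom.height - buffer)
    )
    if not ref_mask.any():
        raise EmptyResultError("buffer excludes every tree; no reference trees remain")

    refs = np.flatnonzero(ref_mask)
    dbh = alive["dbh"].to_numpy(float)
    spp = alive["species"].to_numpy(str)
    js = nbr[refs]  # (m, 4)
    dx = xy[js, 0] - xy[refs, 0][:, None]
    dy = xy[js, 1] - xy[refs, 1][:, None]
    az = np.sort(_azimuth(dx, dy), axis=1)
    gaps = np.diff(np.concatenate([az, az[:, :1] + 360.0], axis=1), axis=1)
    if convention == "minor_arc":
        gaps = np.minimum(gaps, 360.0 - gaps)
    elif convention != "gap":
        raise ValueError("convention must be 'gap' or 'minor_arc'")
    W = np.sum(gaps < alpha0, axis=1) / N_NEIGHBORS
    U = np.sum(dbh[js] > dbh[refs][:, None], axis=1) / N_NEIGHBORS
    M = np.sum(spp[js] != spp[refs][:, None], axis=1) / N_NEIGHBORS

    table = pd.DataFrame(
        {
            "tree_id": alive["tree_id"].iloc[refs].to_numpy(),
            "x": xy[refs, 0],
            "y": xy[refs, 1],
            "species": spp[refs],
            "dbh": dbh[refs],
            "W": W,
            "U": U,
            "M": M,
        }
    )
    return StructureTable(table=table, buffer=buffer)


def level_index(values) -> np.ndarray:
    """Map index values in {0, .25, .5, .75, 1} to level positions 0..4."""
    idx = np.rint(np.asarray(values, dtype=float) / 0.25).astype(int)
    if np.any((idx < 0) | (idx > 4)):
        raise ValueError("index values outside the five levels")
    return idx


def marginal_distribution(table: StructureTable, params) -> LevelDistribution:
    """Uni-, bi- or trivariate relative-frequency distribution of levels.

    ``params`` is an ordered subset of ("W", "U", "M"); the result has
    5**arity cells (including empty combinations) summing to one.
    """
    params = tuple(params)
    if not params or any(p not in PARAM_NAMES for p in params) or len(set(params)) != len(params):
        raise ValueError("params must be a non-empty ordered subset of W, U, M")
    if table.n == 0:
        raise EmptyResultError("empty structure table")
    idx = [level_index(table.table[p]) for p in params]
    counts = np.zeros((5,) * len(params))
    np.add.at(counts, tuple(idx), 1)
    return LevelDistribution(params=params, freq=counts / table.n, n=table.n)
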