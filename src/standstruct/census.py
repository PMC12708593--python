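"""Reading, validation, and pairing of mapped stem-census tables.

A census is one row per stem: an opaque tree id, a species code, map
coordinates in metres (origin at the south-west plot corner, x eastward,
y northward), DBH in cm, and an alive/dead status.  Two censuses of the
same plot are joined on tree id to follow individuals through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["tree_id", "species", "x", "y", "dbh", "status"]
VALID_STATUS = frozenset({"alive", "dead"})

#: Minimum DBH (cm) for a stem to count as an adult tree in the
#: structural analysis; smaller stems form the sapling layer.
DEFAULT_DBH_THRESHOLD = 5.0


class CensusFormatError(ValueError):
    """The input table is structurally unusable (missing columns etc.)."""


class CensusValidationError(ValueError):
    """One or more rows violate census invariants.

    Attributes
    ----------
    report : list of dict
        One entry per offending row with keys ``line`` (1-based data row
        number), ``tree_id`` and ``problem``.
    """

    def __init__(self, message: str, report: list[dict]):
        super().__init__(message)
        self.report = report


class ConsistencyError(ValueError):
    """Censuses of the same plot disagree on an immutable attribute."""


@dataclass(frozen=True)
class PlotGeometry:
    """Rectangular plot extent in metres; (0, 0) is the south-west corner."""

    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot width and height must be positive")

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


@dataclass
class Census:
    """A validated set of stem records plus plot geometry and a year label."""

    records: pd.DataFrame
    geometry: PlotGeometry
    year: str = ""

    def __post_init__(self):
        self.records = self.records.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.records)

    def alive(self) -> pd.DataFrame:
        return self.records[self.records["status"] == "alive"]

    def adults(self, threshold_dbh: float = DEFAULT_DBH_THRESHOLD) -> pd.DataFrame:
        """Alive stems at or above the adult DBH threshold."""
        r = self.records
        return r[(r["status"] == "alive") & (r["dbh"] >= threshold_dbh)]


@dataclass
class MatchedCensusPair:
    """Id-join of two censuses of the same plot."""

    census_a: Census
    census_b: Census
    both: set = field(default_factory=set)
    a_only: set = field(default_factory=set)
    b_only: set = field(default_factory=set)

    def counts(self) -> dict:
        return {
            "both": len(self.both),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
        }


def validate_records(df: pd.DataFrame, geometry: PlotGeometry) -> list[dict]:
    """Collect invariant violations, one report entry per bad row.

    ``line`` is the 1-based position of the row in the data section of the
    file (header excluded), so it can be quoted back at the user.
    """
    report: list[dict] = []

    def flag(mask: pd.Series, problem: str):
        for pos in np.flatnonzero(mask.to_numpy()):
            report.append(
                {
                    "line": int(pos) + 1,
                    "tree_id": str(df["tree_id"].iloc[pos]),
                    "problem": problem,
                }
            )

    flag(df["tree_id"].isna() | (df["tree_id"].astype(str).str.len() == 0), "empty tree_id")
    dup = df["tree_id"].duplicated(keep=False) & df["tree_id"].notna()
    flag(dup, "duplicated tree_id")
    flag(~np.isfinite(df["x"]) | ~np.isfinite(df["y"]), "non-finite coordinate")
    inb = geometry.contains(df["x"], df["y"])
    flag(pd.Series(~inb & np.isfinite(df["x"]) & np.isfinite(df["y"])), "coordinate outside plot")
    flag(~np.isfinite(df["dbh"]) | (df["dbh"] <= 0), "non-positive dbh")
    flag(~df["status"].isin(VALID_STATUS), "status not in {alive, dead}")
    return report


def read_census(
    path,
    geometry: PlotGeometry,
    year: str = "",
    delimiter: str = ",",
    column_map: dict | None = None,
) -> Census:
    """Read and validate a delimited census table.

    Parameters
    ----------
    path : str or file-like
        Delimited text with a header row naming the six record fields.
    geometry : PlotGeometry
        Plot extent used for the coordinate bounds check.
    year : str
        Census year label carried on the returned object.
    delimiter : str
        Field delimiter, default comma.
    column_map : dict, optional
        Mapping from file column names to canonical field names, for
        inputs whose headers differ from ``tree_id,species,x,y,dbh,status``.

    Raises
    ------
    CensusFormatError
        If a required column is missing.
    CensusValidationError
        If any row violates an invariant; the exception carries a
        line-numbered report of every offending row.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"tree_id": str, "species": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CensusFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df[REQUIRED_COLUMNS].copy()
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    df["dbh"] = pd.to_numeric(df["dbh"], errors="coerce")
    df["status"] = df["status"].astype(str).str.strip().str.lower()

    report = validate_records(df, geometry)
    if report:
        ids = sorted({r["tree_id"] for r in report})
        raise CensusValidationError(
            f"{len(report)} invalid row(s); offending tree_id(s): {', '.join(ids[:20])}",
            report,
        )
    return Census(records=df, geometry=geometry, year=year)


def write_census(census: Census, path) -> None:
    """Write a census as a normalized CSV (canonical column order)."""
    census.records[REQUIRED_COLUMNS].to_csv(path, index=False)


def census_from_frame(df: pd.DataFrame, geometry: PlotGeometry, year: str = "") -> Census:
    """Build a validated Census from an in-memory frame (same checks as read)."""
    df = df[REQUIRED_COLUMNS].copy()
    df["tree_id"] = df["tree_id"].astype(str)
    df["species"] = df["species"].astype(str)
    report = validate_records(df, geometry)
    if report:
        ids = sorted({r["tree_id"] for r in report})
        raise CensusValidationError(
            f"{len(report)} invalid row(s); offending tree_id(s): {', '.join(ids[:20])}",
            report,
        )
    return Census(records=df, geometry=geometry, year=year)


def pair_censuses(census_a: Census, census_b: Census) -> MatchedCensusPair:
    """Join two censuses on tree id and partition ids into both/a-only/b-only.

    A tree present in both censuses must carry the same species code;
    disagreement raises :class:`ConsistencyError`.
    """
    if census_a.geometry != census_b.geometry:
        raise ConsistencyError("censuses do not share plot geometry")
    ids_a = set(census_a.records["tree_id"])
    ids_b = set(census_b.records["tree_id"])
    both = ids_a & ids_b
    if both:
        sp_a = census_a.records.set_index("tree_id")["species"]
        sp_b = census_b.records.set_index("tree_id")["species"]
        shared = sorted(both)
        mism = [t for t in shared if sp_a[t] != sp_b[t]]
        if mism:
            raise ConsistencyError(
                f"species mismatch for shared tree_id(s): {', '.join(mism[:20])}"
            )
    return MatchedCensusPair(
        census_a=census_a,
        census_b=census_b,
        both=both,
        a_only=ids_a - ids_b,
        b_only=ids_b - ids_a,
    )
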