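"""Census-to-census fate classification and structural flow distributions.

Between two censuses a decade apart every adult stem is a *survivor*
(alive and above the DBH threshold in both), *dead* (adult in the first,
dead — or missing, flagged — in the second), or a *recruit* (absent or
sub-threshold in the first, adult in the second).

For each structure index the level transition of each tree is binned
into signed step categories (one level = 0.25):

* survivors: Flow+4 … Flow0 … Flow−4 (nine categories);
* mortality: Dead0 … Dead−4 — a dead tree's value flows from its
  first-census level to 0;
* recruitment: Reg0 … Reg+4 — a recruit's value rises from 0 to its
  second-census level.

Distributions are percentages over the trees of that process and always
enumerate every category, including empty ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census import DEFAULT_DBH_THRESHOLD, ConsistencyError, MatchedCensusPair
from .structure import PARAM_NAMES, EmptyResultError, StructureTable, level_index

SURVIVOR_CATEGORIES = tuple(
    f"Flow+{k}" for k in range(4, 0, -1)
) + ("Flow0",) + tuple(f"Flow-{k}" for k in range(1, 5))
MORTALITY_CATEGORIES = ("Dead0",) + tuple(f"Dead-{k}" for k in range(1, 5))
RECRUITMENT_CATEGORIES = ("Reg0",) + tuple(f"Reg+{k}" for k in range(1, 5))

PROCESSES = ("survivor", "mortality", "recruitment")


@dataclass
class FateTable:
    """Per-tree fate labels plus a disclosure of ambiguous records.

    ``fates`` maps tree_id to one of survivor/dead/recruit;
    ``missing_assumed_dead`` lists adults of the first census absent from
    the second without a dead record (treated as dead, flagged here).
    """

    fates: pd.Series
    missing_assumed_dead: list = field(default_factory=list)

    def ids(self, fate: str) -> list:
        return list(self.fates.index[self.fates == fate])

    def counts(self) -> dict:
        return self.fates.value_counts().to_dict()


@dataclass
class FlowDistribution:
    """Percentage distribution of level-step categories for one process."""

    process: str
    parameter: str
    percentages: pd.Series  # index = categories, values sum to 100
    n: int


def classify_fates(
    pair: MatchedCensusPair, threshold_dbh: float = DEFAULT_DBH_THRESHOLD
) -> FateTable:
    """Label every tree of a matched census pair as survivor, dead or recruit."""
    a = pair.census_a.records.set_index("tree_id")
    b = pair.census_b.records.set_index("tree_id")

    adult_a = set(a.index[(a["status"] == "alive") & (a["dbh"] >= threshold_dbh)])
    adult_b = set(b.index[(b["status"] == "alive") & (b["dbh"] >= threshold_dbh)])
    dead_b = set(b.index[b["status"] == "dead"])
    dead_a = set(a.index[a["status"] == "dead"])

    revived = sorted(dead_a & set(b.index[b["status"] == "alive"]))
    if revived:
        raise ConsistencyError(
            f"tree(s) dead in first census but alive in second: {', '.join(revived[:20])}"
        )

    fates: dict[str, str] = {}
    missing: list[str] = []
    for tid in adult_a:
        if tid in adult_b:
            fates[tid] = "survivor"
        elif tid in dead_b:
            fates[tid] = "dead"
        else:
            # alive adult that vanished without a dead record: assumed dead
            fates[tid] = "dead"
            missing.append(tid)
    for tid in adult_b - adult_a:
        fates[tid] = "recruit"

    s = pd.Series(fates, name="fate", dtype=object)
    return FateTable(fates=s.sort_index(), missing_assumed_dead=sorted(missing))


def _levels_by_id(struct: StructureTable, parameter: str) -> pd.Series:
    return pd.Series(
        level_index(struct.table[parameter].to_numpy()),
        index=struct.table["tree_id"].to_numpy(),
    )


def flow_distributions(
    fates: FateTable,
    struct_a: StructureTable,
    struct_b: StructureTable,
    process: str,
    parameter: str,
) -> FlowDistribution:
    """Percentage distribution of level transitions for one process and index.

    Survivor flows need the tree to be a reference tree in both censuses
    (edge-buffer effects can censor one side; such trees are excluded).
    Mortality uses first-census levels, recruitment second-census levels.
    """
    if parameter not in PARAM_NAMES:
        raise ValueError(f"parameter must be one of {PARAM_NAMES}")
    lev_a = _levels_by_id(struct_a, parameter)
    lev_b = _levels_by_id(struct_b, parameter)

    if process == "survivor":
        cats = SURVIVOR_CATEGORIES
        ids = [t for t in fates.ids("survivor") if t in lev_a.index and t in lev_b.index]
        steps = lev_b.loc[ids].to_numpy() - lev_a.loc[ids].to_numpy()
        names = [f"Flow{k:+d}" if k else "Flow0" for k in steps]
    elif process == "mortality":
        cats = MORTALITY_CATEGORIES
        ids = [t for t in fates.ids("dead") if t in lev_a.index]
        steps = lev_a.loc[ids].to_numpy()
        names = [f"Dead-{k}" if k else "Dead0" for k in steps]
    elif process == "recruitment":
        cats = RECRUITMENT_CATEGORIES
        ids = [t for t in fates.ids("recruit") if t in lev_b.index]
        steps = lev_b.loc[ids].to_numpy()
        names = [f"Reg+{k}" if k else "Reg0" for k in steps]
    else:
        raise ValueError(f"process must be one of {PROCESSES}")

    if len(ids) == 0:
        raise EmptyResultError(f"no eligible trees for process={process}")
    counts = pd.Series(0, index=list(cats), dtype=float)
    vc = pd.Series(names).value_counts()
    counts.loc[vc.index] = vc.to_numpy(dtype=float)
    return FlowDistribution(
        process=process,
        parameter=parameter,
        percentages=100.0 * counts / len(ids),
        n=len(ids),
    )


def flow_table(
    fates: FateTable,
    struct_a: StructureTable,
    struct_b: StructureTable,
    process: str,
) -> pd.DataFrame:
    """Flow percentages of all three indices for one process, one row per
    category (columns ``category, W_pct, U_pct, M_pct``)."""
    cols = {}
    for p in PARAM_NAMES:
        fd = flow_distributions(fates, struct_a, struct_b, process, p)
        cols[f"{p}_pct"] = fd.percentages
    out = pd.DataFrame(cols)
    out.insert(0, "category", out.index)
    return out.reset_index(drop=True)


def sankey_links(
    fates: FateTable,
    struct_a: StructureTable,
    struct_b: StructureTable,
    parameter: str,
) -> list[dict]:
    """(source level, target level, count) triples for Sankey rendering.

    Survivors link their first-census level to their second-census level;
    dead trees link to the sink level "dead"; recruits enter from the
    source level "recruit".
    """
    lev_a = _levels_by_id(struct_a, parameter)
    lev_b = _levels_by_id(struct_b, parameter)
    links: dict[tuple, int] = {}

    def add(src, dst):
        links[(src, dst)] = links.get((src, dst), 0) + 1

    for t in fates.ids("survivor"):
        if t in lev_a.index and t in lev_b.index:
            add(float(lev_a[t] * 0.25), float(lev_b[t] * 0.25))
    for t in fates.ids("dead"):
        if t in lev_a.index:
            add(float(lev_a[t] * 0.25), "dead")
    for t in fates.ids("recruit"):
        if t in lev_b.index:
            add("recruit", float(lev_b[t] * 0.25))

    return [
        {"parameter": parameter, "source": s, "target": d, "count": c}
        for (s, d), c in sorted(links.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
    ]
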