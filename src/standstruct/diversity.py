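"""Sapling diversity indices per quadrat.

From the abundance vector of sub-threshold stems (DBH < 5 cm) of each
quadrat, four classical indices are computed with natural logarithms:

* Shannon–Wiener  H = −Σ p_i ln p_i
* Simpson         D = 1 − Σ p_i²
* Pielou evenness J = H / ln S      (0 when S = 1)
* Margalef richness F = (S − 1) / ln N  (0 when N = 1)
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def diversity_indices(counts) -> dict:
    """H, D, J, F from a species-abundance vector (zeros are dropped).

    Raises ``ValueError`` on an empty vector; callers record such
    quadrats as missing.
    """
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, float)
    c = c[c > 0]
    n_total = c.sum()
    if n_total < 1:
        raise ValueError("empty abundance vector: diversity undefined")
    s = len(c)
    p = c / n_total
    h = float(-(p * np.log(p)).sum())
    d = float(1.0 - (p**2).sum())
    j = 0.0 if s == 1 else h / np.log(s)
    f = 0.0 if n_total <= 1 else (s - 1) / np.log(n_total)
    return {"H": h, "D": d, "J": float(j), "F": float(f), "S": s, "N": int(n_total)}


def sapling_diversity_table(saplings: pd.DataFrame) -> pd.DataFrame:
    """Per-quadrat diversity from a sapling abundance table.

    ``saplings`` has columns ``row, col, species, count`` (or one row per
    stem without ``count``).  Quadrats absent from the table are simply
    absent from the result.
    """
    df = saplings.copy()
    if "count" not in df.columns:
        df["count"] = 1
    rows = []
    for (r, c), g in df.groupby(["row", "col"]):
        ab = g.groupby("species")["count"].sum()
        ab = ab[ab > 0]
        if ab.empty:
            continue
        rec = diversity_indices(ab.to_dict())
        rec["row"], rec["col"] = r, c
        rows.append(rec)
    return pd.DataFrame(rows, columns=["row", "col", "S", "N", "H", "D", "J", "F"])
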