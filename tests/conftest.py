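import numpy as np
import pandas as pd
import pytest

from standstruct.census import Census, PlotGeometry, census_from_frame


def make_census(xy, species=None, dbh=None, status=None, width=100.0, height=100.0,
                year="a", ids=None):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    df = pd.DataFrame(
        {
            "tree_id": ids if ids is not None else [f"t{i:04d}" for i in range(n)],
            "species": species if species is not None else ["sp1"] * n,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "dbh": dbh if dbh is not None else np.full(n, 10.0),
            "status": status if status is not None else ["alive"] * n,
        }
    )
    return census_from_frame(df, PlotGeometry(width, height), year=year)


@pytest.fixture
def random_census():
    """200 random alive trees of 5 species on a 100 m square."""
    rng = np.random.default_rng(42)
    xy = rng.uniform(0, 100, size=(200, 2))
    species = [f"sp{s}" for s in rng.integers(0, 5, 200)]
    dbh = rng.lognormal(2.3, 0.5, 200) + 5
    return make_census(xy, species=species, dbh=dbh)


@pytest.fixture
def geometry():
    return PlotGeometry(100.0, 100.0)
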