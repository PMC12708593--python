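import numpy as np
import pandas as pd
import pytest

from standstruct.census import ConsistencyError, pair_censuses
from standstruct.dynamics import (
    MORTALITY_CATEGORIES,
    RECRUITMENT_CATEGORIES,
    SURVIVOR_CATEGORIES,
    classify_fates,
    flow_distributions,
    flow_table,
    sankey_links,
)
from standstruct.structure import compute_structure
from tests.conftest import make_census


def _pair():
    """Tiny pair: survivor, a dead tree, a threshold-crossing recruit,
    a brand-new recruit, and a vanished adult (flagged dead)."""
    a = make_census(
        [(10, 10), (20, 20), (30, 30), (40, 40)],
        dbh=[12.0, 8.0, 4.2, 15.0],
        ids=["srv", "die", "grow", "gone"],
    )
    b = make_census(
        [(10, 10), (20, 20), (30, 30), (50, 50)],
        dbh=[13.0, 8.0, 6.1, 5.5],
        status=["alive", "dead", "alive", "alive"],
        ids=["srv", "die", "grow", "new"],
        year="b",
    )
    return pair_censuses(a, b)


class TestClassifyFates:
    def test_fate_definitions(self):
        fates = classify_fates(_pair())
        assert fates.fates["srv"] == "survivor"
        assert fates.fates["die"] == "dead"
        assert fates.fates["grow"] == "recruit"   # 4.2 -> 6.1 cm crosses threshold
        assert fates.fates["new"] == "recruit"

    def test_missing_adult_assumed_dead_and_flagged(self):
        fates = classify_fates(_pair())
        assert fates.fates["gone"] == "dead"
        assert fates.missing_assumed_dead == ["gone"]

    def test_resurrection_is_inconsistent(self):
        a = make_census([(1, 1)], status=["dead"], ids=["z"])
        b = make_census([(1, 1)], status=["alive"], ids=["z"], year="b")
        with pytest.raises(ConsistencyError):
            classify_fates(pair_censuses(a, b))

    def test_partition_invariants(self):
        """survivors+dead cover first-census adults; survivors+recruits the second's."""
        fates = classify_fates(_pair())
        n_srv, n_dead, n_rec = (len(fates.ids(f)) for f in ("survivor", "dead", "recruit"))
        assert n_srv + n_dead == 3   # adults alive in census a
        assert n_srv + n_rec == 3    # adults alive in census b


def _structures(seed=0, n=300, move=0.0):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 100, (n, 2))
    species = [f"sp{s}" for s in rng.integers(0, 6, n)]
    dbh = rng.lognormal(2.2, 0.4, n) + 5
    a = make_census(xy, species=species, dbh=dbh)
    xy_b = np.clip(xy + move * rng.normal(size=(n, 2)), 0, 100)
    b = make_census(xy_b, species=species, dbh=dbh + 1.0, year="b")
    return a, b


class TestFlowDistributions:
    def test_category_enumeration(self):
        assert len(SURVIVOR_CATEGORIES) == 9
        assert len(MORTALITY_CATEGORIES) == 5
        assert len(RECRUITMENT_CATEGORIES) == 5
        a, b = _structures()
        fates = classify_fates(pair_censuses(a, b))
        sa, sb = compute_structure(a), compute_structure(b)
        fd = flow_distributions(fates, sa, sb, "survivor", "W")
        assert list(fd.percentages.index) == list(SURVIVOR_CATEGORIES)

    def test_no_change_concentrates_in_flow0(self):
        a, b = _structures(move=0.0)
        fates = classify_fates(pair_censuses(a, b))
        sa, sb = compute_structure(a), compute_structure(b)
        for p in ("W", "U", "M"):
            fd = flow_distributions(fates, sa, sb, "survivor", p)
            assert fd.percentages["Flow0"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        a, b = _structures(move=1.5)
        fates = classify_fates(pair_censuses(a, b))
        sa, sb = compute_structure(a), compute_structure(b)
        fd = flow_distributions(fates, sa, sb, "survivor", "U")
        assert fd.percentages.sum() == pytest.approx(100.0, abs=1e-9)

    def test_mortality_and_recruitment_step_mapping(self):
        """A dead tree at level 1 lands in Dead-4; a recruit at 0.5 in Reg+2."""
        pts = [(50, 50), (49, 50), (51, 50), (50, 49), (50, 51), (80, 80), (82, 80)]
        spp = ["r", "o1", "o2", "o3", "o4", "f1", "f2"]
        ids = ["ref", "n1", "n2", "n3", "n4", "f1", "f2"]
        a = make_census(pts, species=spp, dbh=[5.0, 20, 20, 20, 20, 30, 30], ids=ids)
        # ref dies; everything else survives unchanged
        b = make_census(
            pts, species=spp, dbh=[5.0, 21, 21, 21, 21, 31, 31],
            status=["dead"] + ["alive"] * 6, ids=ids, year="b",
        )
        fates = classify_fates(pair_censuses(a, b))
        sa = compute_structure(a, buffer=5)
        sb = compute_structure(b, buffer=5)
        # ref is smallest and fully mingled: U level 4, M level 4 in census a
        fd_u = flow_distributions(fates, sa, sb, "mortality", "U")
        assert fd_u.percentages["Dead-4"] == 100.0
        fd_m = flow_distributions(fates, sa, sb, "mortality", "M")
        assert fd_m.percentages["Dead-4"] == 100.0

    def test_flow_table_layout(self):
        a, b = _structures(move=1.0)
        fates = classify_fates(pair_censuses(a, b))
        sa, sb = compute_structure(a), compute_structure(b)
        t = flow_table(fates, sa, sb, "survivor")
        assert list(t.columns) == ["category", "W_pct", "U_pct", "M_pct"]
        assert len(t) == 9
        for c in ("W_pct", "U_pct", "M_pct"):
            assert t[c].sum() == pytest.approx(100.0, abs=1e-9)


class TestSankey:
    def test_source_side_totals(self):
        """Census-a side of the links covers every survivor and dead
        reference tree exactly once."""
        a, b = _structures(move=1.0)
        fates = classify_fates(pair_censuses(a, b))
        sa, sb = compute_structure(a), compute_structure(b)
        links = sankey_links(fates, sa, sb, "W")
        ids_a = set(sa.table["tree_id"])
        ids_b = set(sb.table["tree_id"])
        n_srv = sum(1 for t in fates.ids("survivor") if t in ids_a and t in ids_b)
        n_dead = sum(1 for t in fates.ids("dead") if t in ids_a)
        from_a = sum(l["count"] for l in links if l["source"] != "recruit")
        assert from_a == n_srv + n_dead
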