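import numpy as np
import pytest

from standstruct.census import Census
from standstruct.structure import (
    EmptyResultError,
    compute_structure,
    dominance,
    marginal_distribution,
    mingling,
    neighbor_set,
    uniform_angle,
)
from tests.conftest import make_census


def brute_force_neighbors(census, ref_id, k=4):
    """Exhaustive pairwise-distance search with the (distance, id) order."""
    alive = census.alive()
    ref = alive[alive["tree_id"] == ref_id].iloc[0]
    others = alive[alive["tree_id"] != ref_id]
    d = np.hypot(others["x"] - ref["x"], others["y"] - ref["y"])
    order = sorted(zip(d, others["tree_id"]))
    return [t for _, t in order[:k]]


class TestNeighborSet:
    def test_four_nearest_chosen(self):
        pts = [(50, 50)] + [(50 + d, 50) for d in (1, 2, 3, 4, 5)]
        c = make_census(pts)
        unit = neighbor_set(c, "t0000")
        assert unit["neighbor_ids"] == ["t0001", "t0002", "t0003", "t0004"]

    def test_distance_tie_broken_by_id(self):
        # two candidates at identical distance 5; 'a...' sorts before 'b...'
        pts = [(50, 50), (51, 50), (52, 50), (53, 50), (50, 55), (55, 50)]
        ids = ["ref", "n1", "n2", "n3", "b_tie", "a_tie"]
        c = make_census(pts, ids=ids)
        unit = neighbor_set(c, "ref")
        assert unit["neighbor_ids"][3] == "a_tie"

    def test_matches_brute_force_on_random_map(self, random_census):
        ids = random_census.records["tree_id"].sample(25, random_state=0)
        for rid in ids:
            unit = neighbor_set(random_census, rid)
            assert unit["neighbor_ids"] == brute_force_neighbors(random_census, rid)

    def test_unknown_reference_raises(self, random_census):
        with pytest.raises(KeyError):
            neighbor_set(random_census, "nope")


class TestUniformAngle:
    def test_square_cross_is_fully_uniform(self):
        assert uniform_angle([0, 90, 180, 270]) == 0.0

    def test_tight_cluster(self):
        # gaps 10,10,10,330: three below the standard angle
        assert uniform_angle([0, 10, 20, 30]) == 0.75
        # minor-arc convention scores the 330 gap as 30 and reaches 1
        assert uniform_angle([0, 10, 20, 30], convention="minor_arc") == 1.0

    def test_exact_standard_angle_counts_as_uniform(self):
        # gaps 72,72,72,144: none strictly below the standard angle
        assert uniform_angle([0, 72, 144, 216]) == 0.0
        # gaps 71,73,72,144: only the 71 gap counts
        assert uniform_angle([0, 71, 144, 216]) == 0.25

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            az = rng.uniform(0, 360, 4)
            rot = rng.uniform(0, 360)
            assert uniform_angle(az) == uniform_angle((az + rot) % 360)

    def test_matches_direct_gap_count_on_random_units(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            az = rng.uniform(0, 360, 4)
            srt = np.sort(az)
            gaps = [srt[1] - srt[0], srt[2] - srt[1], srt[3] - srt[2],
                    360 - srt[3] + srt[0]]
            expected = sum(1 for g in gaps if g < 72) / 4
            assert uniform_angle(az) == expected


class TestDominanceMingling:
    def test_two_larger_neighbors(self):
        assert dominance(30, [10, 20, 40, 50]) == 0.5

    def test_largest_tree_is_predominant(self):
        assert dominance(60, [10, 20, 40, 50]) == 0.0

    def test_equal_dbh_counts_as_not_larger(self):
        assert dominance(30, [30, 30, 30, 30]) == 0.0

    def test_smallest_tree_absolutely_disadvantaged(self):
        assert dominance(5, [10, 20, 40, 50]) == 1.0

    @pytest.mark.parametrize(
        "neigh,expected",
        [(["a", "a", "a", "a"], 0.0), (["b", "c", "d", "e"], 1.0),
         (["a", "b", "c", "d"], 0.75)],
    )
    def test_mingling_counts_heterospecifics(self, neigh, expected):
        assert mingling("a", neigh) == expected


class TestComputeStructure:
    def test_buffer_excludes_edge_references(self, random_census):
        st = compute_structure(random_census, buffer=5)
        t = st.table
        assert (t["x"] >= 5).all() and (t["x"] <= 95).all()
        assert (t["y"] >= 5).all() and (t["y"] <= 95).all()

    def test_buffer_zero_keeps_all_alive_trees(self, random_census):
        st = compute_structure(random_census, buffer=0)
        assert st.n == len(random_census.alive())

    def test_buffer_tree_still_serves_as_neighbor(self):
        # reference mid-plot; one of its 4 nearest is inside the buffer strip
        pts = [(50, 50), (50, 47), (53, 50), (50, 53), (3, 50), (47, 50)]
        c = make_census(pts, width=100, height=100)
        st = compute_structure(c, buffer=5)
        assert "t0004" not in set(st.table["tree_id"])  # x=3 < buffer
        unit = neighbor_set(c, "t0000")
        assert set(unit["neighbor_ids"]) == {"t0001", "t0002", "t0003", "t0005"}

    def test_oversized_buffer_raises(self, random_census):
        with pytest.raises(EmptyResultError):
            compute_structure(random_census, buffer=60)

    def test_stand_means_equal_per_tree_recomputation(self, random_census):
        st = compute_structure(random_census, buffer=5)
        recomputed = {p: st.table[p].mean() for p in ("W", "U", "M")}
        for p, v in st.stand_means().items():
            assert v == pytest.approx(recomputed[p], abs=1e-12)

    def test_per_tree_values_vs_direct_indicator_counting(self, random_census):
        """W, U, M of every reference tree equal direct per-unit counting."""
        st = compute_structure(random_census, buffer=5)
        alive = random_census.alive().set_index("tree_id")
        for _, row in st.table.sample(30, random_state=1).iterrows():
            unit = neighbor_set(random_census, row["tree_id"])
            assert row["W"] == uniform_angle(unit["azimuths"])
            nd = alive.loc[unit["neighbor_ids"], "dbh"].to_numpy()
            assert row["U"] == dominance(alive.loc[row["tree_id"], "dbh"], nd)
            ns = alive.loc[unit["neighbor_ids"], "species"].to_numpy()
            assert row["M"] == mingling(alive.loc[row["tree_id"], "species"], ns)

    def test_levels_are_quarter_steps(self, random_census):
        st = compute_structure(random_census)
        for p in ("W", "U", "M"):
            assert set(st.table[p]).issubset({0, 0.25, 0.5, 0.75, 1.0})


class TestDistributions:
    def test_cell_counts_by_arity(self, random_census):
        st = compute_structure(random_census)
        assert marginal_distribution(st, ("W",)).freq.size == 5
        assert marginal_distribution(st, ("W", "U")).freq.size == 25
        assert marginal_distribution(st, ("W", "U", "M")).freq.size == 125

    def test_frequencies_sum_to_one(self, random_census):
        st = compute_structure(random_census)
        for params in [("W",), ("U", "M"), ("W", "U", "M")]:
            assert marginal_distribution(st, params).freq.sum() == pytest.approx(
                1.0, abs=1e-12
            )

    def test_marginalization_identity(self, random_census):
        st = compute_structure(random_census)
        tri = marginal_distribution(st, ("W", "U", "M"))
        uni = marginal_distribution(st, ("W",))
        bi = marginal_distribution(st, ("W", "U"))
        np.testing.assert_allclose(tri.freq.sum(axis=(1, 2)), uni.freq, atol=1e-15)
        np.testing.assert_allclose(tri.freq.sum(axis=2), bi.freq, atol=1e-15)

    def test_monoculture_mingling_mass_at_zero(self):
        rng = np.random.default_rng(3)
        c = make_census(rng.uniform(0, 100, (150, 2)))
        st = compute_structure(c)
        uni = marginal_distribution(st, ("M",))
        assert uni.freq[0] == 1.0
        assert st.stand_means()["M"] == 0.0

    def test_all_distinct_species_complete_mingling(self):
        rng = np.random.default_rng(4)
        n = 120
        c = make_census(rng.uniform(0, 100, (n, 2)), species=[f"sp{i}" for i in range(n)])
        st = compute_structure(c)
        assert marginal_distribution(st, ("M",)).freq[4] == 1.0
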