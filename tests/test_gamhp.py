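from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from standstruct.gamhp import (
    TermSpec,
    collinearity_screen,
    fit_gam,
    hierarchical_partition,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(100)


class TestCollinearityScreen:
    def test_duplicated_predictor_dropped(self, rng):
        a = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=100)})
        kept, report = collinearity_screen(X)
        assert len(kept) == 2 and "c" in kept
        assert report["flagged_pairs"][0]["r"] == pytest.approx(1.0)

    def test_orthogonal_predictors_all_kept_vif_one(self):
        n = 64
        X = pd.DataFrame(
            {
                "a": np.tile([1.0, -1.0], n // 2),
                "b": np.repeat([1.0, -1.0], n // 2),
            }
        )
        kept, report = collinearity_screen(X)
        assert kept == ["a", "b"]
        assert report["vif"]["a"] == pytest.approx(1.0)

    def test_vif_matches_auxiliary_regression(self, rng):
        z = rng.normal(size=200)
        X = pd.DataFrame(
            {
                "a": z + 0.6 * rng.normal(size=200),
                "b": z + 0.6 * rng.normal(size=200),
                "c": rng.normal(size=200),
            }
        )
        kept, report = collinearity_screen(X, r_thresh=0.95)
        for c in kept:
            others = [k for k in kept if k != c]
            A = np.column_stack([np.ones(200), X[others].to_numpy()])
            yv = X[c].to_numpy()
            res = yv - A @ np.linalg.lstsq(A, yv, rcond=None)[0]
            r2 = 1 - res @ res / np.sum((yv - yv.mean()) ** 2)
            assert report["vif"][c] == pytest.approx(1 / (1 - r2))

    def test_constant_predictor_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="constant"):
            kept, _ = collinearity_screen(X)
        assert kept == ["b"]


class TestFitGam:
    def test_noiseless_linear_signal_fully_explained(self, rng):
        n = 200
        X = pd.DataFrame({"a": rng.uniform(0, 1, n)})
        y = 2.0 + 3.0 * X["a"] + rng.normal(0, 1e-6, n)
        fit = fit_gam(y, X, [TermSpec("a")])
        assert fit.deviance_explained > 0.999

    def test_pure_noise_explains_little(self):
        n = 375
        devs = []
        for seed in (0, 1, 2):
            r = np.random.default_rng(seed)
            X = pd.DataFrame({"a": r.uniform(0, 1, n), "b": r.uniform(0, 1, n)})
            y = r.normal(size=n)
            devs.append(fit_gam(y, X, [TermSpec("a"), TermSpec("b")]).deviance_explained)
        assert max(devs) < 0.1

    def test_sine_recovery(self, rng):
        n = 300
        X = pd.DataFrame({"a": rng.uniform(0, 2 * np.pi, n)})
        signal = np.sin(X["a"].to_numpy())
        y = signal + rng.normal(0, 0.05, n)
        fit = fit_gam(y, X, [TermSpec("a")])
        assert np.corrcoef(fit.result.fittedvalues, signal)[0, 1] > 0.99

    def test_term_tests_reported(self):
        r = np.random.default_rng(12)
        n = 250
        X = pd.DataFrame({"a": r.uniform(0, 1, n), "b": r.uniform(0, 1, n)})
        y = np.sin(6 * X["a"]) + r.normal(0, 0.2, n)
        fit = fit_gam(y, X, [TermSpec("a"), TermSpec("b")], alphas=[1.0, 1.0])
        t = fit.term_tests.set_index("term")
        assert t.loc["a", "p"] < 1e-6
        assert t.loc["b", "p"] > 0.01

    def test_too_few_observations(self, rng):
        X = pd.DataFrame({"a": rng.uniform(0, 1, 8)})
        with pytest.raises(ValueError):
            fit_gam(rng.normal(size=8), X, [TermSpec("a")])


def ordering_oracle(y, X, terms, alphas):
    """Average incremental deviance explained over every ordering,
    reusing the package's subset-fit machinery for the raw R^2 values."""
    from standstruct.gamhp import _subset_r2

    alpha_by_name = {t.name: a for t, a in zip(terms, alphas)}
    cache = {}

    def r2(sub):
        return _subset_r2(y, X, list(sub), alpha_by_name, cache)

    totals = {t.name: 0.0 for t in terms}
    orders = list(permutations(terms))
    for order in orders:
        for i, t in enumerate(order):
            totals[t.name] += r2(order[: i + 1]) - r2(order[:i])
    return {k: v / len(orders) for k, v in totals.items()}


class TestHierarchicalPartition:
    def test_single_term_gets_everything(self, rng):
        n = 150
        X = pd.DataFrame({"a": rng.uniform(0, 1, n)})
        y = X["a"] ** 2 + rng.normal(0, 0.1, n)
        part = hierarchical_partition(y, X, [TermSpec("a")])
        assert part.table["I_perc"].iloc[0] == pytest.approx(100.0)

    def test_symmetric_orthogonal_terms_split_evenly(self):
        r = np.random.default_rng(4)
        n = 400
        X = pd.DataFrame({"a": r.uniform(-1, 1, n), "b": r.uniform(-1, 1, n)})
        y = X["a"] + X["b"] + r.normal(0, 0.1, n)
        part = hierarchical_partition(y, X, [TermSpec("a"), TermSpec("b")])
        v = part.table.set_index("term")["I_perc"]
        assert v["a"] == pytest.approx(50, abs=5)
        assert v["b"] == pytest.approx(50, abs=5)

    def test_three_terms_match_ordering_enumeration(self, rng):
        n = 220
        X = pd.DataFrame(
            {
                "a": rng.uniform(0, 1, n),
                "b": rng.uniform(0, 1, n),
                "c": rng.uniform(0, 1, n),
            }
        )
        y = np.sin(4 * X["a"]) + 0.5 * X["b"] + rng.normal(0, 0.2, n)
        terms = [TermSpec("a"), TermSpec("b"), TermSpec("c")]
        alphas = [1.0, 1.0, 1.0]
        part = hierarchical_partition(y, X, terms, alphas=alphas)
        oracle = ordering_oracle(y.to_numpy(), X, terms, alphas)
        got = part.table.set_index("term")["independent"]
        for name, val in oracle.items():
            assert got[name] == pytest.approx(val, abs=1e-10)

    def test_percentages_sum_to_100_and_order_invariant(self, rng):
        n = 260
        X = pd.DataFrame(
            {
                "a": rng.uniform(0, 1, n),
                "b": rng.uniform(0, 1, n),
                "c": rng.uniform(0, 1, n),
            }
        )
        y = X["a"] ** 2 + 0.3 * X["c"] + rng.normal(0, 0.2, n)
        terms = [TermSpec("a"), TermSpec("b", group="biotic"), TermSpec("c")]
        alphas = [1.0, 1.0, 1.0]
        p1 = hierarchical_partition(y, X, terms, alphas=alphas)
        assert p1.table["I_perc"].sum() == pytest.approx(100.0, abs=1e-6)
        rev = list(reversed(terms))
        p2 = hierarchical_partition(y, X, rev, alphas=list(reversed(alphas)))
        a1 = p1.table.set_index("term")["I_perc"]
        a2 = p2.table.set_index("term")["I_perc"]
        for t in ("a", "b", "c"):
            assert a1[t] == pytest.approx(a2[t], abs=1e-9)
        # group totals also sum to 100
        assert p1.group_totals()["I_perc"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_term_limit(self, rng):
        X = pd.DataFrame({f"x{i}": rng.normal(size=30) for i in range(13)})
        with pytest.raises(ValueError):
            hierarchical_partition(
                rng.normal(size=30), X, [TermSpec(f"x{i}") for i in range(13)]
            )
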