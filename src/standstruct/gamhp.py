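"""Additive-model stage: collinearity screening, penalized-spline GAM
fits, and hierarchical partitioning of explained deviance.

Responses (quadrat structure means or sapling diversity indices) are
modelled as ``g(E[Y]) = b0 + f_1(x_1) + ... + f_n(x_n)`` with a Gaussian
family, identity link, and one penalized B-spline smooth per predictor
(basis dimension 8 by default; penalty weights chosen by generalized
cross-validation on the full model).

Hierarchical partitioning assigns each predictor its average incremental
explained deviance over all orderings of the predictors (the Shapley
value of the deviance-explained "game"), expressed as a percentage of
the full model's explained deviance (I.perc), and optionally summed over
predictor groups (biotic vs topographic).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines, GLMGam

MAX_HP_TERMS = 12


@dataclass(frozen=True)
class TermSpec:
    """One smooth term: a predictor, its basis size, and a factor group."""

    name: str
    df: int = 8
    group: str = "topographic"

    def __post_init__(self):
        if self.df < 3:
            raise ValueError("smooth basis size must be >= 3")


@dataclass
class GamFit:
    response: str
    terms: list
    deviance_explained: float
    term_tests: pd.DataFrame      # columns: term, F, p
    intercept: float
    result: object = field(repr=False, default=None)


@dataclass
class PartitionResult:
    response: str
    table: pd.DataFrame           # columns: term, group, independent, I_perc
    deviance_explained: float

    def group_totals(self) -> pd.DataFrame:
        g = self.table.groupby("group", as_index=False)["I_perc"].sum()
        return g.sort_values("group").reset_index(drop=True)


def collinearity_screen(
    X: pd.DataFrame, r_thresh: float = 0.7, vif_thresh: float = 10.0
) -> tuple[list, dict]:
    """Drop collinear predictors; report pairwise flags and VIFs.

    Constant columns are dropped first.  While any pair has |r| above
    the threshold, the member with the larger mean absolute correlation
    to the remaining predictors is removed.  VIF (1/(1-R^2) of the
    auxiliary regression of each survivor on the others) is reported,
    with a warning above the VIF threshold.
    """
    X = X.copy()
    report: dict = {"dropped": [], "flagged_pairs": [], "vif": {}}
    for c in list(X.columns):
        if X[c].nunique() <= 1:
            warnings.warn(f"constant predictor {c!r} dropped", stacklevel=2)
            report["dropped"].append({"name": c, "reason": "constant"})
            X = X.drop(columns=c)

    while len(X.columns) >= 2:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        if corr.values[i, j] <= r_thresh:
            break
        a, b = corr.columns[i], corr.columns[j]
        report["flagged_pairs"].append({"pair": (a, b), "r": float(corr.values[i, j])})
        victim = a if corr[a].mean() >= corr[b].mean() else b
        report["dropped"].append({"name": victim, "reason": f"|r|>{r_thresh}"})
        X = X.drop(columns=victim)

    kept = list(X.columns)
    for c in kept:
        others = [k for k in kept if k != c]
        if not others:
            report["vif"][c] = 1.0
            continue
        A = np.column_stack([np.ones(len(X)), X[others].to_numpy(float)])
        yv = X[c].to_numpy(float)
        r2 = 1.0 - np.sum((yv - A @ np.linalg.lstsq(A, yv, rcond=None)[0]) ** 2) / np.sum(
            (yv - yv.mean()) ** 2
        )
        vif = np.inf if r2 >= 1 else 1.0 / (1.0 - r2)
        report["vif"][c] = float(vif)
        if vif > vif_thresh:
            warnings.warn(f"predictor {c!r} has VIF {vif:.1f} > {vif_thresh}", stacklevel=2)
    return kept, report


def _spline_df(term: TermSpec, x: np.ndarray) -> int:
    # a term cannot carry more basis functions than distinct values
    return int(min(term.df, max(3, len(np.unique(x)) - 1)))


def _fit_once(y, X: pd.DataFrame, terms: list, alphas: list | None):
    degree = 3
    cols = [t.name for t in terms]
    dfs = [_spline_df(t, X[t.name].to_numpy()) for t in terms]
    bs = BSplines(X[cols], df=dfs, degree=[degree] * len(terms))
    model = GLMGam(
        np.asarray(y, float),
        exog=np.ones((len(X), 1)),
        smoother=bs,
        alpha=alphas if alphas is not None else [1.0] * len(terms),
    )
    if alphas is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit()  # select_penweight needs the scale from a first fit
            alpha = model.select_penweight()[0]
        model = GLMGam(
            np.asarray(y, float), exog=np.ones((len(X), 1)), smoother=bs, alpha=alpha
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return model, res


def select_alphas(y, X: pd.DataFrame, terms: list) -> list:
    """Per-term penalty weights by generalized cross-validation."""
    model, _ = _fit_once(np.asarray(y, float), X, terms, [1.0] * len(terms))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return list(model.select_penweight()[0])


def fit_gam(
    y,
    X: pd.DataFrame,
    terms: list,
    response_name: str = "y",
    alphas: list | None = None,
) -> GamFit:
    """Fit the additive model and report deviance explained and per-term
    approximate F-tests (Wald tests on each smooth's coefficient block,
    on the effective degrees of freedom)."""
    y = np.asarray(y, dtype=float)
    total_df = sum(t.df for t in terms) + 1
    if len(y) <= total_df:
        raise ValueError(f"n={len(y)} observations <= {total_df} basis dimensions")
    model, res = _fit_once(y, X, terms, alphas)
    dev_expl = 1.0 - res.deviance / res.null_deviance

    rows = []
    k_params = len(res.params)
    start = model.k_exog_linear
    for i, t in enumerate(terms):
        mask = model.smoother.mask[i]
        idx = start + np.nonzero(mask)[0][0]
        constraints = np.eye(int(mask.sum()), k_params, idx)
        dfc = res.edf[idx : idx + int(mask.sum())].sum()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = res.wald_test(constraints, df_constraints=dfc, use_f=True, scalar=True)
        rows.append({"term": t.name, "F": float(wt.statistic), "p": float(wt.pvalue)})
    return GamFit(
        response=response_name,
        terms=list(terms),
        deviance_explained=float(dev_expl),
        term_tests=pd.DataFrame(rows),
        intercept=float(res.params[0]),
        result=res,
    )


def _subset_r2(y, X, terms, alpha_by_name, cache) -> float:
    key = tuple(sorted(t.name for t in terms))
    if key in cache:
        return cache[key]
    if not terms:
        cache[key] = 0.0
        return 0.0
    alphas = [alpha_by_name[t.name] for t in terms]
    _, res = _fit_once(y, X, terms, alphas)
    r2 = float(1.0 - res.deviance / res.null_deviance)
    cache[key] = r2
    return r2


def hierarchical_partition(
    y,
    X: pd.DataFrame,
    terms: list,
    response_name: str = "y",
    alphas: list | None = None,
) -> PartitionResult:
    """Shapley decomposition of explained deviance over the smooth terms.

    For every subset of terms the model is refitted (penalty weights are
    selected once on the full model and reused, keyed by term) and each
    term's independent contribution is its ordering-averaged incremental
    deviance explained.  Contributions telescope to the full model's
    deviance explained, so I.perc sums to 100.
    """
    terms = list(terms)
    if len(terms) > MAX_HP_TERMS:
        raise ValueError(f"hierarchical partitioning limited to {MAX_HP_TERMS} terms")
    y = np.asarray(y, dtype=float)

    # GCV penalty selection on the full model, reused for all subsets
    if alphas is None:
        alphas = select_alphas(y, X, terms)
    alpha_by_name = {t.name: a for t, a in zip(terms, alphas)}

    cache: dict = {}
    p = len(terms)
    contrib = {}
    for t in terms:
        others = [u for u in terms if u.name != t.name]
        total = 0.0
        for k in range(p):
            wgt = math.factorial(k) * math.factorial(p - k - 1) / math.factorial(p)
            for sub in combinations(others, k):
                inc = _subset_r2(y, X, list(sub) + [t], alpha_by_name, cache) - _subset_r2(
                    y, X, list(sub), alpha_by_name, cache
                )
                total += wgt * inc
        contrib[t.name] = total

    full_r2 = _subset_r2(y, X, terms, alpha_by_name, cache)
    denom = full_r2 if full_r2 != 0 else np.nan
    table = pd.DataFrame(
        {
            "term": [t.name for t in terms],
            "group": [t.group for t in terms],
            "independent": [contrib[t.name] for t in terms],
        }
    )
    table["I_perc"] = 100.0 * table["independent"] / denom
    return PartitionResult(
        response=response_name, table=table, deviance_explained=float(full_r2)
    )
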