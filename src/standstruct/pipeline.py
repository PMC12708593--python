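"""Configuration-driven end-to-end analysis over a pair of censuses.

Stages: census input (files or simulation), per-census structural units
and level distributions, fate classification and flow distributions,
quadrat aggregation with terrain covariates, spatial autocorrelation and
spatial lag/error regressions, additive-model fits with hierarchical
partitioning for the structure indices, and sapling-diversity responses
to stand structure.  Every stage is isolated: a failing model stage is
recorded in the bundle's error log instead of aborting the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import census as census_io
from . import diversity as div
from . import dynamics as dyn
from . import gamhp, quadrat, spatial, structure
from .simulate import SimConfig, simulate_dynamics, simulate_environment, simulate_stem_map

BIOTIC = ("Ind", "meandbh", "maxdbh", "basal_area")
TOPOGRAPHIC = ("elevation", "slope", "TRASP", "convexity", "RBR")
# default additive-model factor set: two biotic and four topographic terms
GAM_BIOTIC = ("meandbh", "Ind")
GAM_TOPOGRAPHIC = ("elevation", "slope", "TRASP", "RBR")


@dataclass
class RunConfig:
    """Everything a full run needs; defaults mirror the analysis design."""

    # either simulate (default) or read census files
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    census_a_path: str | None = None
    census_b_path: str | None = None
    corner_elevation_path: str | None = None
    rbr_path: str | None = None
    sapling_path: str | None = None
    width: float = 500.0
    height: float = 300.0

    plot_buffer: float = 5.0
    quadrat_buffer: float = 2.0
    cell: float = 20.0
    dbh_threshold: float = 5.0
    weights_scheme: str = "queen"
    n_permutations: int = 999
    seed: int = 0
    run_gam: bool = True
    gam_df: int = 8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


@dataclass
class ReportBundle:
    """All run outputs keyed by table name, plus the run log."""

    tables: dict = field(default_factory=dict)
    jsons: dict = field(default_factory=dict)
    log: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        for name, obj in self.jsons.items():
            (out / f"{name}.json").write_text(json.dumps(obj, indent=1, default=_js))
        (out / "run_log.json").write_text(
            json.dumps({"log": self.log, "errors": self.errors}, indent=1, default=_js)
        )


def _js(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _stage(bundle: ReportBundle, name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                bundle.errors[name] = f"{exc_type.__name__}: {exc}"
                bundle.log.append(f"stage {name}: FAILED ({exc_type.__name__})")
                return True
            bundle.log.append(f"stage {name}: ok")
            return False

    return _Ctx()


def run_pipeline(cfg: RunConfig, out_dir=None) -> ReportBundle:
    bundle = ReportBundle()
    bundle.log.append(
        "defaults in force: plot buffer %.1f m, quadrat buffer %.1f m, DBH threshold "
        "%.1f cm, %s weights, %d permutations, seed %d"
        % (cfg.plot_buffer, cfg.quadrat_buffer, cfg.dbh_threshold,
           cfg.weights_scheme, cfg.n_permutations, cfg.seed)
    )

    # ---- inputs -------------------------------------------------------
    geom = census_io.PlotGeometry(cfg.width, cfg.height)
    if cfg.simulate:
        cfg.sim.seed = cfg.seed
        cen_a = simulate_stem_map(cfg.sim)
        cen_b = simulate_dynamics(cen_a, cfg.sim)
        geom = cen_a.geometry
    else:
        cen_a = census_io.read_census(cfg.census_a_path, geom, year="a")
        cen_b = census_io.read_census(cfg.census_b_path, geom, year="b")
    pair = census_io.pair_censuses(cen_a, cen_b)
    bundle.log.append(f"censuses paired: {pair.counts()}")

    # ---- structure ----------------------------------------------------
    struct = {}
    with _stage(bundle, "structure"):
        rows = []
        for cen in (cen_a, cen_b):
            adults = census_io.Census(
                cen.adults(cfg.dbh_threshold).copy(), cen.geometry, cen.year
            )
            st = structure.compute_structure(adults, buffer=cfg.plot_buffer)
            struct[cen.year] = st
            rows.append({"year": cen.year, "N": st.n, **st.stand_means()})
            for params in [("W",), ("U",), ("M",), ("W", "U"), ("W", "M"),
                           ("U", "M"), ("W", "U", "M")]:
                dist = structure.marginal_distribution(st, params)
                bundle.tables[f"dist_{''.join(params)}_{cen.year}"] = dist.to_frame()
            bundle.tables[f"structure_{cen.year}"] = st.table
        bundle.tables["stand_means"] = pd.DataFrame(rows)

    # ---- dynamics -----------------------------------------------------
    with _stage(bundle, "dynamics"):
        fates = dyn.classify_fates(pair, cfg.dbh_threshold)
        st_a, st_b = struct[cen_a.year], struct[cen_b.year]
        for process, key in [("survivor", "flows_survivor"),
                             ("mortality", "flows_mortality"),
                             ("recruitment", "flows_recruitment")]:
            bundle.tables[key] = dyn.flow_table(fates, st_a, st_b, process)
        bundle.jsons["sankey"] = {
            p: dyn.sankey_links(fates, st_a, st_b, p) for p in structure.PARAM_NAMES
        }
        bundle.jsons["fate_counts"] = {
            **fates.counts(), "missing_assumed_dead": len(fates.missing_assumed_dead)
        }

    # ---- quadrats and environment ------------------------------------
    qt = None
    with _stage(bundle, "quadrats"):
        if cfg.simulate:
            grid0, _ = quadrat.grid_and_biotics(cen_a, cfg.cell)
            st_a = struct[cen_a.year]
            qm = quadrat.quadrat_structure_means(st_a, grid0, cfg.quadrat_buffer)
            corner_z, rbr, saplings = simulate_environment(cfg.sim, qm)
        else:
            corner_z = (
                np.loadtxt(cfg.corner_elevation_path, delimiter=",")
                if cfg.corner_elevation_path else None
            )
            rbr = pd.read_csv(cfg.rbr_path) if cfg.rbr_path else None
            saplings = pd.read_csv(cfg.sapling_path) if cfg.sapling_path else None
        adults_a = census_io.Census(
            cen_a.adults(cfg.dbh_threshold).copy(), cen_a.geometry, cen_a.year
        )
        qt = quadrat.quadrat_table(
            adults_a, struct[cen_a.year], corner_z, rbr,
            cell=cfg.cell, inner_buffer=cfg.quadrat_buffer,
        )
        bundle.tables["quadrats"] = qt
        if saplings is not None and len(saplings):
            bundle.tables["sapling_diversity"] = div.sapling_diversity_table(saplings)

    # ---- spatial autocorrelation and SLM/SEM -------------------------
    with _stage(bundle, "spatial_models"):
        complete = qt.dropna(subset=["W", "U", "M"])
        covars = [c for c in (*BIOTIC, *TOPOGRAPHIC) if c in complete.columns]
        complete = complete.dropna(subset=covars)
        grid, _ = quadrat.grid_and_biotics(cen_a, cfg.cell)
        w = spatial.build_weights(grid, scheme=cfg.weights_scheme, keep=complete)
        rows = []
        for p in structure.PARAM_NAMES:
            yv = complete[p].to_numpy(float)
            mi = spatial.morans_i(yv, w, n_perm=cfg.n_permutations, seed=cfg.seed)
            X = np.column_stack(
                [np.ones(len(complete))] + [complete[c].to_numpy(float) for c in covars]
            )
            row = {"parameter": p, "moran_I": mi.I, "moran_p": mi.p_value}
            for kind in ("error", "lag"):
                fit = spatial.fit_spatial_model(
                    yv, X, w, kind=kind, beta_names=["const"] + covars,
                    moran_perm=cfg.n_permutations, moran_seed=cfg.seed,
                )
                tag = "SEM" if kind == "error" else "SLM"
                row[f"moran_I_{tag}"] = fit.moran_residuals.I
                row[f"p_{tag}"] = fit.moran_residuals.p_value
                row[f"coef_{tag}"] = fit.spatial_coef
                row[f"loglik_{tag}"] = fit.loglik
            rows.append(row)
        bundle.tables["autocorrelation"] = pd.DataFrame(rows)

    # ---- GAM + hierarchical partitioning ------------------------------
    if cfg.run_gam:
        with _stage(bundle, "gam_structure"):
            bundle.tables["gam_structure"], bundle.tables["gam_groups"] = _gam_structure(
                qt, cfg
            )
        with _stage(bundle, "gam_diversity"):
            if "sapling_diversity" in bundle.tables:
                bundle.tables["gam_diversity"] = _gam_diversity(
                    qt, bundle.tables["sapling_diversity"], cfg
                )
    else:
        bundle.log.append("gam stage disabled by config")

    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _gam_structure(qt: pd.DataFrame, cfg: RunConfig):
    """Tables mirroring the structure-index GAM + partition layout."""
    covars = [c for c in (*GAM_BIOTIC, *GAM_TOPOGRAPHIC) if c in qt.columns]
    data = qt.dropna(subset=["W", "U", "M", *covars]).reset_index(drop=True)
    kept, _ = gamhp.collinearity_screen(data[covars])
    terms = [
        gamhp.TermSpec(c, df=cfg.gam_df, group="biotic" if c in GAM_BIOTIC else "topographic")
        for c in kept
    ]
    rows, grows = [], []
    for resp in structure.PARAM_NAMES:
        alphas = gamhp.select_alphas(data[resp], data, terms)
        fit = gamhp.fit_gam(data[resp], data, terms, response_name=resp, alphas=alphas)
        part = gamhp.hierarchical_partition(
            data[resp], data, terms, response_name=resp, alphas=alphas
        )
        merged = fit.term_tests.merge(part.table, on="term")
        for _, r in merged.iterrows():
            rows.append(
                {
                    "response": resp, "term": r["term"], "group": r["group"],
                    "F": r["F"], "p": r["p"], "I_perc": r["I_perc"],
                    "deviance_explained": fit.deviance_explained,
                }
            )
        for _, r in part.group_totals().iterrows():
            grows.append({"response": resp, "group": r["group"], "I_perc": r["I_perc"]})
    return pd.DataFrame(rows), pd.DataFrame(grows)


def _gam_diversity(qt: pd.DataFrame, sap: pd.DataFrame, cfg: RunConfig):
    """Sapling diversity responses to the three structure indices."""
    data = sap.merge(qt[["row", "col", "W", "U", "M"]], on=["row", "col"]).dropna(
        subset=["W", "U", "M"]
    )
    terms = [gamhp.TermSpec(p, df=cfg.gam_df, group="structure") for p in ("W", "U", "M")]
    rows = []
    for resp in ("H", "D", "J", "F"):
        alphas = gamhp.select_alphas(data[resp], data, terms)
        fit = gamhp.fit_gam(data[resp], data, terms, response_name=resp, alphas=alphas)
        part = gamhp.hierarchical_partition(
            data[resp], data, terms, response_name=resp, alphas=alphas
        )
        merged = fit.term_tests.merge(part.table, on="term")
        for _, r in merged.iterrows():
            rows.append(
                {
                    "response": resp, "term": r["term"], "F": r["F"], "p": r["p"],
                    "I_perc": r["I_perc"],
                    "deviance_explained": fit.deviance_explained,
                }
            )
    return pd.DataFrame(rows)
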