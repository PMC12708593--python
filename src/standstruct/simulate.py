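"""Seeded synthetic stem maps, terrain, saplings, and two-census dynamics.

The generator emulates the statistical structure of a 15-ha (500 m x
300 m) mapped karst-forest plot: a species-rich adult layer (DBH >= 5
cm) with a reverse-J size distribution, a sub-threshold stem layer, a
peak-and-depression terrain surface spanning a configured elevation
range with rock-bareness increasing toward high ground, and a second
census a decade later linked to the first by survival, mortality and
recruitment.  It is a structural stand-in, not a fit to any real plot.

All randomness flows from one root seed through named substreams, so a
fixed seed and config reproduce every table bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census import Census, PlotGeometry, census_from_frame

_STREAMS = (
    "positions", "species", "dbh", "subthreshold",
    "terrain", "rbr", "saplings", "fates", "growth", "recruits",
)


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the study conditions.

    Units: metres for lengths, cm for DBH, decade^-1 for rates.
    """

    width: float = 500.0
    height: float = 300.0
    # adult stem layer
    process: str = "thomas"            # poisson | thomas | hardcore
    n_trees: int = 3000                # expected adult count on the plot
    cluster_parents_per_species: float = 3.0
    cluster_sd: float = 40.0           # Thomas offspring sd; smaller = stronger conspecific clumping
    hardcore_radius: float = 1.5
    n_species: int = 30
    abundance_concentration: float = 0.4   # Dirichlet concentration (log-series-like skew)
    dbh_meanlog: float = 0.9           # lognormal increment above the adult threshold
    dbh_sdlog: float = 0.9
    dbh_threshold: float = 5.0
    subthreshold_fraction: float = 0.25    # extra stems with DBH in (1, 5) cm
    # terrain
    elevation_range: tuple = (180.0, 370.0)
    terrain_amplitude: float = 1.0     # 0 gives a flat surface at the range midpoint
    rbr_elevation_coupling: float = 0.5
    cell: float = 20.0
    # decade dynamics
    mortality_baseline: float = 0.12
    mortality_size_coef: float = 0.8   # small stems die more
    recruitment_rate: float = 0.15     # new adults per surviving adult
    recruit_cluster_sd: float = 12.0   # dispersal around surviving conspecifics
    growth_mean: float = 2.0           # decade DBH increment, cm
    growth_sd: float = 1.2
    # sapling layer
    sapling_mean_per_quadrat: float = 40.0
    sapling_mingling_coupling: float = 0.8  # 0 = diversity independent of mingling
    seed: int = 0

    geometry: PlotGeometry = field(init=False)

    def __post_init__(self):
        if not (0 <= self.mortality_baseline <= 1):
            raise ValueError("mortality_baseline must be a probability")
        if self.n_trees < 6:
            raise ValueError("expected tree count too small for 4-neighbour units")
        self.geometry = PlotGeometry(self.width, self.height)

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator derived from the root seed."""
        idx = _STREAMS.index(stream)
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[idx])


def _species_abundances(config: SimConfig) -> np.ndarray:
    rng = config.rng("species")
    return rng.dirichlet(np.full(config.n_species, config.abundance_concentration))


def _draw_positions_poisson(rng, n_expected, geom):
    n = rng.poisson(n_expected)
    return rng.uniform([0, 0], [geom.width, geom.height], size=(n, 2))


def _draw_positions_hardcore(rng, n_expected, geom, radius):
    # simple sequential inhibition (dart throwing)
    pts = []
    attempts = 0
    target = rng.poisson(n_expected)
    grid = {}
    cell = radius
    while len(pts) < target and attempts < 50 * max(target, 1):
        attempts += 1
        p = rng.uniform([0, 0], [geom.width, geom.height])
        ci, cj = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for q in grid.get((ci + di, cj + dj), ()):
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < radius**2:
                        ok = False
                        break
        if ok:
            pts.append(p)
            grid.setdefault((ci, cj), []).append(p)
    return np.array(pts) if pts else np.empty((0, 2))


def simulate_stem_map(config: SimConfig) -> Census:
    """First census: adult stems plus a sub-threshold layer.

    Species labels come from a skewed abundance distribution; under the
    Thomas process each species is a parent-offspring cluster process,
    which lowers mingling relative to random labelling.
    """
    geom = config.geometry
    rng = config.rng("positions")
    abund = _species_abundances(config)

    if config.process == "poisson":
        xy = _draw_positions_poisson(rng, config.n_trees, geom)
        species = config.rng("species").choice(config.n_species, size=len(xy), p=abund)
    elif config.process == "hardcore":
        xy = _draw_positions_hardcore(rng, config.n_trees, geom, config.hardcore_radius)
        species = config.rng("species").choice(config.n_species, size=len(xy), p=abund)
    elif config.process == "thomas":
        pts, labels = [], []
        for s in range(config.n_species):
            n_exp = config.n_trees * abund[s]
            n_parents = max(1, rng.poisson(config.cluster_parents_per_species))
            parents = rng.uniform([0, 0], [geom.width, geom.height], size=(n_parents, 2))
            n_off = rng.poisson(n_exp)
            if n_off == 0:
                continue
            which = rng.integers(0, n_parents, n_off)
            off = parents[which] + rng.normal(0, config.cluster_sd, size=(n_off, 2))
            # wrap back into the plot (toroidal) to keep intensity uniform
            off[:, 0] %= geom.width
            off[:, 1] %= geom.height
            pts.append(off)
            labels.append(np.full(n_off, s))
        xy = np.vstack(pts)
        species = np.concatenate(labels)
    else:
        raise ValueError(f"unknown point process {config.process!r}")

    n = len(xy)
    if n < 5:
        raise ValueError("realized stem count too small; raise n_trees")
    rng_dbh = config.rng("dbh")
    dbh = config.dbh_threshold + rng_dbh.lognormal(config.dbh_meanlog, config.dbh_sdlog, n)

    # sub-threshold stems: uniform positions, DBH in (1, 5)
    rng_sub = config.rng("subthreshold")
    n_sub = rng_sub.poisson(config.subthreshold_fraction * config.n_trees)
    xy_sub = rng_sub.uniform([0, 0], [geom.width, geom.height], size=(n_sub, 2))
    sp_sub = rng_sub.choice(config.n_species, size=n_sub, p=abund)
    dbh_sub = rng_sub.uniform(1.0, config.dbh_threshold, n_sub)

    df = pd.DataFrame(
        {
            "tree_id": [f"t{i:06d}" for i in range(n + n_sub)],
            "species": [f"sp{s:02d}" for s in np.concatenate([species, sp_sub])],
            "x": np.concatenate([xy[:, 0], xy_sub[:, 0]]),
            "y": np.concatenate([xy[:, 1], xy_sub[:, 1]]),
            "dbh": np.concatenate([dbh, dbh_sub]),
            "status": "alive",
        }
    )
    return census_from_frame(df, geom, year="2011")


def simulate_dynamics(census: Census, config: SimConfig) -> Census:
    """Second census a decade later: growth, mortality, recruitment.

    Mortality probability falls with size (log-DBH effect on the logit of
    the baseline); survivors get positive DBH increments, so some
    sub-threshold stems cross the adult threshold; new recruits are
    placed around surviving conspecific adults (dispersal limitation).
    """
    geom = census.geometry
    rec = census.records
    rng_f = config.rng("fates")
    rng_g = config.rng("growth")
    rng_r = config.rng("recruits")

    alive = rec["status"] == "alive"
    dbh = rec["dbh"].to_numpy(float)
    base = config.mortality_baseline
    if base >= 1.0:
        p_die = np.ones(len(rec))
    elif base <= 0.0:
        p_die = np.zeros(len(rec))
    else:
        # size effect on the logit of the baseline, centred at 10 cm DBH
        logit = np.log(base / (1 - base)) + config.mortality_size_coef * (
            np.log(10.0) - np.log(np.maximum(dbh, 0.5))
        )
        p_die = 1.0 / (1.0 + np.exp(-logit))
    dies = alive.to_numpy() & (rng_f.uniform(size=len(rec)) < p_die)

    out = rec.copy()
    out.loc[dies, "status"] = "dead"
    grow = alive.to_numpy() & ~dies
    incr = np.maximum(rng_g.normal(config.growth_mean, config.growth_sd, len(rec)), 0.0)
    out.loc[grow, "dbh"] = dbh[grow] + incr[grow]

    # new recruits clustered around surviving conspecific adults
    parents = out[grow & (out["dbh"] >= config.dbh_threshold).to_numpy()]
    n_new = rng_r.poisson(config.recruitment_rate * len(parents))
    if len(parents) and n_new:
        pick = rng_r.integers(0, len(parents), n_new)
        px = parents["x"].to_numpy()[pick] + rng_r.normal(0, config.recruit_cluster_sd, n_new)
        py = parents["y"].to_numpy()[pick] + rng_r.normal(0, config.recruit_cluster_sd, n_new)
        newly = pd.DataFrame(
            {
                "tree_id": [f"r{i:06d}" for i in range(n_new)],
                "species": parents["species"].to_numpy()[pick],
                "x": np.clip(px, 0, geom.width),
                "y": np.clip(py, 0, geom.height),
                "dbh": rng_r.uniform(config.dbh_threshold, config.dbh_threshold + 2.0, n_new),
                "status": "alive",
            }
        )
        out = pd.concat([out, newly], ignore_index=True)
    return census_from_frame(out, geom, year="2021")


def simulate_environment(
    config: SimConfig, quadrat_mingling: pd.DataFrame | None = None
):
    """Terrain raster, rock-bareness table, and sapling table.

    Returns ``(corner_z, rbr, saplings)``: a (nrows+1, ncols+1) corner
    elevation array whose extremes hit the configured range (a peak and
    a depression over smooth undulations), a per-quadrat rock-bareness
    fraction increasing with elevation, and a per-quadrat sapling
    abundance table whose diversity rises with quadrat mingling when
    ``quadrat_mingling`` (columns ``row, col, M``) is supplied.
    """
    geom = config.geometry
    ncols = int(round(geom.width / config.cell))
    nrows = int(round(geom.height / config.cell))
    rng_t = config.rng("terrain")

    gx, gy = np.meshgrid(
        np.linspace(0, 1, ncols + 1), np.linspace(0, 1, nrows + 1)
    )
    lo, hi = config.elevation_range
    if config.terrain_amplitude == 0:
        corner_z = np.full((nrows + 1, ncols + 1), (lo + hi) / 2.0)
    else:
        peak = np.exp(-(((gx - 0.25) ** 2 + (gy - 0.3) ** 2) / 0.04))
        depression = -np.exp(-(((gx - 0.7) ** 2 + (gy - 0.65) ** 2) / 0.06))
        phx, phy = rng_t.uniform(0, 2 * np.pi, 2)
        waves = 0.25 * np.sin(3 * np.pi * gx + phx) * np.cos(2 * np.pi * gy + phy)
        z = peak + depression + waves
        corner_z = lo + (hi - lo) * (z - z.min()) / (z.max() - z.min())

    # per-quadrat RBR: monotone in elevation, noisy, clipped to [0, 1]
    elev_q = (corner_z[:-1, :-1] + corner_z[:-1, 1:] + corner_z[1:, :-1] + corner_z[1:, 1:]) / 4
    znorm = (
        (elev_q - elev_q.min()) / (elev_q.max() - elev_q.min())
        if elev_q.max() > elev_q.min()
        else np.zeros_like(elev_q)
    )
    rng_rbr = config.rng("rbr")
    c = config.rbr_elevation_coupling
    rbr_vals = np.clip(c * znorm + (1 - c) * rng_rbr.uniform(0, 1, znorm.shape), 0, 1)
    rows, cols = np.mgrid[0:nrows, 0:ncols]
    rbr = pd.DataFrame(
        {"row": rows.ravel(), "col": cols.ravel(), "RBR": rbr_vals.ravel()}
    )

    # sapling layer: richness and evenness increase with quadrat mingling
    rng_s = config.rng("saplings")
    if quadrat_mingling is not None:
        m = (
            quadrat_mingling.set_index(["row", "col"])["M"]
            .reindex(pd.MultiIndex.from_arrays([rows.ravel(), cols.ravel()]))
            .fillna(0.5)
            .to_numpy()
        )
    else:
        m = np.full(nrows * ncols, 0.5)
    cpl = config.sapling_mingling_coupling
    sap_rows = []
    for q in range(nrows * ncols):
        n_stems = rng_s.poisson(config.sapling_mean_per_quadrat)
        if n_stems == 0:
            continue
        # effective species pool grows with mingling under the coupling
        s_eff = max(1, int(round(1 + ((1 - cpl) * 0.5 + cpl * m[q]) * (config.n_species - 1))))
        pool = rng_s.choice(config.n_species, size=s_eff, replace=False)
        p = rng_s.dirichlet(np.full(s_eff, 1.0 + 4.0 * cpl * m[q]))
        draws = rng_s.choice(pool, size=n_stems, p=p)
        ab = pd.Series(draws).value_counts()
        for sp, cnt in ab.items():
            sap_rows.append(
                {
                    "row": int(rows.ravel()[q]),
                    "col": int(cols.ravel()[q]),
                    "species": f"sp{sp:02d}",
                    "count": int(cnt),
                }
            )
    saplings = pd.DataFrame(sap_rows, columns=["row", "col", "species", "count"])
    return corner_z, rbr, saplings
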