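"""Shared input loading for the numbered analysis scripts.

Running ``01_simulate.py`` writes the simulated census pair and
environment tables under ``results/data/``; later scripts read them from
there, regenerating on the fly (same seed) if the files are absent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from standstruct.census import Census, PlotGeometry, read_census, write_census
from standstruct.quadrat import make_grid, quadrat_structure_means
from standstruct.simulate import SimConfig, simulate_dynamics, simulate_environment, simulate_stem_map
from standstruct.structure import compute_structure

SEED = 0
ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"


def config(seed: int = SEED) -> SimConfig:
    return SimConfig(seed=seed)


def generate(seed: int = SEED):
    cfg = config(seed)
    cen_a = simulate_stem_map(cfg)
    cen_b = simulate_dynamics(cen_a, cfg)
    st_a = compute_structure(Census(cen_a.adults().copy(), cen_a.geometry, "2011"))
    grid = make_grid(cen_a.geometry, cfg.cell)
    qm = quadrat_structure_means(st_a, grid, 2.0)
    corner_z, rbr, saplings = simulate_environment(cfg, qm)
    return cfg, cen_a, cen_b, corner_z, rbr, saplings


def save_inputs(cfg, cen_a, cen_b, corner_z, rbr, saplings):
    DATA.mkdir(parents=True, exist_ok=True)
    write_census(cen_a, DATA / "census_2011.csv")
    write_census(cen_b, DATA / "census_2021.csv")
    np.savetxt(DATA / "corner_elevation.csv", corner_z, delimiter=",")
    rbr.to_csv(DATA / "rbr.csv", index=False)
    saplings.to_csv(DATA / "saplings.csv", index=False)


def load_inputs(seed: int = SEED):
    cfg = config(seed)
    if not (DATA / "census_2011.csv").exists():
        parts = generate(seed)
        save_inputs(*parts)
        return parts
    geom = PlotGeometry(cfg.width, cfg.height)
    cen_a = read_census(DATA / "census_2011.csv", geom, year="2011")
    cen_b = read_census(DATA / "census_2021.csv", geom, year="2021")
    corner_z = np.loadtxt(DATA / "corner_elevation.csv", delimiter=",")
    rbr = pd.read_csv(DATA / "rbr.csv")
    saplings = pd.read_csv(DATA / "saplings.csv")
    return cfg, cen_a, cen_b, corner_z, rbr, saplings


def adults(census) -> Census:
    return Census(census.adults().copy(), census.geometry, census.year)
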