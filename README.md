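# standstruct

Nearest-neighbour stand spatial structure, census-to-census dynamics, and
quadrat-level driver analysis for fully mapped forest plots.

The package is written for forest and community ecologists working with
stem-mapped census data (one row per stem: id, species, coordinates, DBH,
status). It targets the classical structural-unit framework: each reference
tree *i* and its four nearest neighbours define a unit on which three
indices are computed, each taking one of the five levels
0, 0.25, 0.5, 0.75, 1:

- **Uniform angle index** `W_i = (1/4) Σ_j z_ij`, where `z_ij = 1` if the
  j-th circular gap between the sorted neighbour azimuths is below the
  standard angle α₀ = 72°. `W ≈ 0.5` indicates random spacing; low values
  uniform, high values irregular spacing.
- **Dominance** `U_i = (1/4) Σ_j k_ij`, `k_ij = 1` if neighbour j's DBH
  strictly exceeds the reference tree's (0 = predominant, 1 = absolutely
  disadvantaged).
- **Mingling** `M_i = (1/4) Σ_j v_ij`, `v_ij = 1` if neighbour j is
  heterospecific (0 = no mingling, 1 = complete mingling).

Stand means are averages over reference trees after a 5 m edge buffer;
uni-, bi- and trivariate level distributions enumerate the 5, 25 and 125
level combinations. Between two censuses, trees are classified as
survivors, dead, or recruits (crossing the 5 cm DBH threshold), and each
index's level transitions are binned into flow categories
(Flow±k, Dead−k, Reg+k). At the 20 m quadrat scale the package provides
biotic summaries, terrain metrics (elevation, slope, aspect/TRASP,
convexity) from a corner-elevation raster, global Moran's *I* with
permutation inference, maximum-likelihood spatial lag and spatial error
models, penalized-spline additive models with hierarchical partitioning
of explained deviance, and sapling diversity indices (Shannon *H*,
Simpson *D*, Pielou *J*, Margalef *F*). A seeded generator simulates
stem maps, terrain, saplings and decade dynamics so the entire pipeline
runs without any external data.

## Worked example

The numbered scripts under `analysis/` run the full study design on a
simulated 500 m × 300 m plot (seed 0) and write their tables under
`results/`:

```
cd analysis
python 01_simulate.py
python 02_structure.py
python 03_dynamics.py
python 04_spatial_models.py
python 05_gam_partition.py
python 06_sapling_diversity.py
```

Output from a run:

```
census 2011: 3821 stems (3082 adults >= 5.0 cm)
census 2021: 4264 stems (3396 adults)

2011: N=2908 reference trees | W=0.49 U=0.50 M=0.69
2021: N=3188 reference trees | W=0.49 U=0.50 M=0.72

fates: {'survivor': 2657, 'recruit': 739, 'dead': 425}
survivor: modal categories W=Flow0 U=Flow0 M=Flow0

W: I=+0.021 (p=0.423) | residual I after SEM +0.001 (p=0.91), after SLM +0.002 (p=0.87)
M: I=+0.364 (p=0.001) | residual I after SEM -0.030 (p=0.29), after SLM -0.026 (p=0.37)

M: deviance explained 22.0%; leading factor elevation (I.perc 44.6%)
H: deviance explained 83.3%; dominant structure index M (I.perc 99.4%)
```

Reading this: the simulated stand is randomly spaced (`W ≈ 0.5`), shows
balanced competition (`U ≈ 0.5`) and high mingling; most survivors keep
their index level (`Flow0` modal). Mingling is the only index with strong
spatial autocorrelation, which the spatial error/lag models absorb
(non-significant residual Moran's *I*). Elevation leads the drivers of
mingling, and quadrat mingling dominates sapling diversity (I.perc ≈ 99%
for the Shannon index) — the diversity signal built into the generator.

A `standstruct` console command exposes the same steps
(`simulate`, `structure`, `dynamics`, `models`, `run-all`), e.g.
`standstruct run-all --seed 0 --out results/run`.

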