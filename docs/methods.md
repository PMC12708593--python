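# Methods

## Structural units and indices

Every alive stem is a candidate neighbour; a stem is a *reference tree*
only if it lies at least 5 m (configurable) inside every plot edge, the
standard edge correction that avoids censored neighbour sets. Neighbour
sets are the four alive stems at smallest Euclidean distance, distance
ties broken by ascending tree id so results are reproducible. Azimuths
are measured clockwise from north (+y); the uniform angle index is
rotation-invariant, so the convention only fixes exports.

The uniform angle index counts, among the four circular gaps between the
sorted neighbour azimuths (summing to 360°), those strictly below the
standard angle α₀ = 72°. Under this raw-gap rule the level W = 1 is
unattainable (four gaps below 72° cannot sum to 360°); the alternative
convention that scores each gap by its minor arc min(gap, 360° − gap),
under which a tightly clustered neighbour set reaches W = 1, is available
via `uniform_angle(..., convention="minor_arc")` and
`compute_structure(..., convention="minor_arc")`. Both give stand means
within [0.47, 0.53] under complete spatial randomness at n ≥ 2000.
Dominance counts neighbours with strictly larger DBH — equal DBH counts
as "not larger", a deterministic tie rule conservative toward dominance.
Mingling counts heterospecific neighbours.

Level distributions enumerate all 5, 25 or 125 level combinations
(including empty cells) as relative frequencies over reference trees;
marginalising a higher-arity distribution reproduces the lower-arity one
exactly.

## Census dynamics

With a 5 cm adult DBH threshold: survivors are alive adults in both
censuses; dead trees are first-census adults recorded dead — or missing
without a dead record, in which case they are treated as dead and listed
in a disclosure field — by the second census; recruits are stems absent
or sub-threshold in the first census and adult in the second. A stem
recorded dead and later alive is a consistency error.

Flow categories are defined strictly as level steps of 0.25: survivors
move Flow+k / Flow−k when their level changes by exactly k steps (nine
categories including Flow0), a dead tree's value flows from its level to
zero (Dead0…Dead−4), a recruit's from zero to its level (Reg0…Reg+4).
Survivor flows require the tree to be a reference tree in both censuses;
trees censored by the edge buffer on one side are excluded from flows
(their count is recoverable from the structure tables). Percentages are
over the trees of each process and always sum to 100.

## Quadrat aggregation and terrain

Quadrats are 20 m cells indexed from the south-west corner; stems are
assigned by half-open intervals, so boundary stems belong to the cell
that starts at the boundary. Quadrat structure means average reference
trees lying at least 2 m inside the quadrat; neighbour relations remain
plot-wide — the inner buffer only decides which trees a quadrat averages.
Quadrats with no eligible tree are missing and are dropped from all
downstream models rather than imputed.

Terrain follows the common large-plot convention from a corner-elevation
raster: quadrat elevation is the mean of its four corners; slope is the
mean angular slope of the four planes through three of the four corners;
aspect is the downslope azimuth of the least-squares plane (NaN on flat
quadrats, where TRASP defaults to its minimum); convexity is the quadrat
elevation minus the mean of its up-to-eight neighbours. The transformed
aspect TRASP = {1 − cos[(π/180)(aspect − 30°)]}/2 maps the coolest
exposure (30°, NNE) to 0 and the hottest (210°, SSW) to 1. Rock-bareness
rate, topographic wetness and elevation-above-channel are accepted as
input columns only, never derived.

## Spatial models

Weights are queen contiguity on the quadrat grid by default (rook and
centroid distance-band available), row-standardized; missing quadrats
are dropped before construction and isolates raise a warning. Moran's
*I* uses the cross-product form with S₀ the total weight; inference is a
two-sided label-permutation test, p = (1 + #{|I* − E| ≥ |I − E|})/(1 +
n_perm) with E = −1/(n − 1), 999 permutations and an explicit seed.

The spatial lag model y = ρWy + Xβ + ε and spatial error model
y = Xβ + u, u = λWu + ε are fitted by maximum likelihood via the
concentrated log-likelihood in the spatial coefficient. The
log-determinant ln|I − cW| is evaluated from the eigenvalues of the
row-standardized weights (real, because W = D⁻¹A is similar to the
symmetric D^(−1/2)AD^(−1/2)); the coefficient is found by bounded Brent
search inside (1/ω_min + 10⁻⁶, 1/ω_max − 10⁻⁶) with tolerance 10⁻⁸, and
a warning is raised at the interval boundary. Each fit reports the
residual Moran's *I* with its permutation p — under a correct
specification it sits at the permutation-null expectation.

## Additive models and hierarchical partitioning

Responses are modelled as g(E[Y]) = β₀ + f₁(x₁) + … + fₙ(xₙ) with a
Gaussian family and identity link; the structure indices and diversity
values are bounded but treated as continuous. Each smooth is a penalized
cubic B-spline with basis dimension 8 (reduced automatically when a
predictor has few distinct values), penalty weights chosen by
generalized cross-validation on the full model. Per-term significance is
an approximate F-test: a Wald test on the smooth's coefficient block
with its effective degrees of freedom. Before fitting, predictors are
screened for collinearity: pairs with |r| > 0.7 lose the member with the
larger mean absolute correlation, and survivors' VIFs are reported with
a warning above 10.

Hierarchical partitioning refits the model on every subset of terms and
assigns each term its ordering-averaged incremental deviance explained
(the Shapley value), expressed as a percentage of the full model's
explained deviance (I.perc). The GCV penalty weights from the full model
are reused for subset fits, keyed by term — selection per subset would be
combinatorially expensive and would not change the telescoping identity
by which contributions sum exactly to the full model's deviance
explained. Subset fits are cached by term set; more than 12 terms (2¹²
fits) is refused. Percentage shares can individually exceed 100 or fall
below 0 when increments are negative; their sum is always 100.

## Synthetic data generator

The generator emulates the study system — a 500 m × 300 m stem-mapped
plot on peak-and-depression karst terrain — so the whole analysis runs
with no download. Defaults, chosen once as field-realistic values:

- **Adults:** expected 3,000 stems ≥ 5 cm DBH (2 stems/100 m², typical of
  subtropical/tropical plots at this threshold), from a per-species
  Thomas cluster process (3 parents per species, offspring σ = 40 m,
  toroidal wrapping) so conspecifics clump and mingling falls below the
  random-labelling level, as in real stands. Poisson and hard-core
  (sequential inhibition) processes are available.
- **Species:** 30 species with Dirichlet(0.4) abundances, giving the
  strongly skewed abundance distribution of species-rich forests.
- **DBH:** threshold + lognormal(0.9, 0.9) cm, a reverse-J size
  distribution; a sub-threshold layer (25 % of the adult count, DBH
  1–5 cm) feeds threshold-crossing recruitment.
- **Terrain:** a Gaussian peak and depression plus low-frequency
  undulation, rescaled exactly to the 180–370 m elevation range;
  rock-bareness is 0.5·(normalized elevation) + 0.5·noise, clipped to
  [0, 1] — high ground is rockier, but not deterministically (the
  coupling keeps |r| with elevation below the collinearity threshold).
- **Decade dynamics:** baseline mortality 0.12 with a log-size effect
  (smaller stems die more), growth increments N(2.0, 1.2) cm truncated
  at zero, recruitment at 0.15 new adults per surviving adult placed
  around surviving conspecifics (σ = 12 m dispersal limitation, making
  recruit flow distributions non-trivial).
- **Saplings:** ~40 stems per quadrat; the effective species pool and
  abundance evenness rise with quadrat mingling (coupling 0.8), creating
  the positive mingling–diversity association the diversity stage is
  designed to detect.

All randomness derives from one root seed through named substreams
(positions, species, DBH, terrain, fates, growth, recruits, saplings),
so components vary independently and runs are bitwise reproducible.

What the generator does **not** emulate: demographic rates tied to
terrain (mortality is independent of topography), multi-stemmed
individuals, measurement error in coordinates or DBH, and any attempt to
match a particular real plot's numbers. Passing tests therefore
demonstrate that the estimators and the pipeline behave correctly under
a known, realistic data-generating process — not that any ecological
conclusion transfers to a specific forest.

## Problem sizes and numerical choices

The analysis scripts use the full simulated plot (≈3,000 adults, 375
quadrats). Test simulations use 2,000–2,500 stems for the
spatial-randomness checks, 50 replicates at n = 375 for spatial-model
parameter recovery, and a 10 × 10 quadrat grid with 999 permutations ×
1,000 null datasets for the permutation-test calibration check — sizes at
which the checked quantities are stable while the suite stays quick.
Distribution cells are validated to sum to 1 within 10⁻¹², flow
percentages to 100 within 10⁻⁹. Index levels are mapped to integer
level positions by rounding to the nearest multiple of 0.25, exact for
values produced by the count/4 formulas.

## Known limitations

- Survivor flows silently exclude trees that are reference trees in only
  one census (edge-buffer churn); their count is disclosed but no
  correction is applied.
- The SLM/SEM eigenvalue log-determinant is dense (O(n³) once per
  weights matrix), fine for hundreds-to-thousands of quadrats but not
  for very large lattices.
- Deviance-explained differences between penalized fits are not
  guaranteed non-negative, so individual partition shares can leave
  [0, 100] even though they sum to 100.
- The pairwise census join assumes stable tree ids; no spatial matching
  of unidentified stems is attempted.
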