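# Methods

This note documents the models and procedures `invafun` implements, the
choices made where the design was genuinely open, and what the synthetic data
generator does and does not emulate.

## Abundance model

Field abundances are ordinal Moyle classes: 1 (1–2 individuals per site) up to
5 (more than 50); 0 encodes absence. Numerical classes overweight small-bodied
species, so each species carries a 3-level adult body-mass class (1 ≈ ≤150 g,
2 ≈ 150–400 g, 3 ≈ >400 g) and the working abundance is the elementwise
product, an integer in {0..15}. All multivariate analyses use the Hellinger
transform of this matrix, `y′_ij = sqrt(y_ij / y_i+)`: rows become unit-norm
square-rooted relative abundances, which removes community-size differences
while preserving zeros.

**Invasion degree** is the percentage of a site's total corrected abundance
contributed by exotic species: 0 at fully native sites, 100 at fully exotic
ones, undefined (NaN) for empty sites. It is computed on corrected (not
Hellinger) abundances because the correction defines the working abundance
measure; a `raw` Moyle mode exists for sensitivity analysis, and FDis itself
is invariant to the per-site rescaling the Hellinger transform applies.

Environmental predictors are variance-stabilised before regression:
land-cover shares `p ∈ [0,1]` become `arcsin(√p)` (the standard proportion
transform), altitude and the eight physicochemical variables become `log x`
when strictly positive, else `log(x+1)` (offset recorded in run metadata —
nutrient non-detects make exact zeros realistic). Coordinates pass through
untransformed.

## Functional dispersion

Species are described by one categorical guild per ecological function
(feeding, reproduction, migration, tolerance, habitat use; vocabularies are
configurable data). Gower dissimilarity between two species reduces, for
purely categorical traits, to the mean per-function mismatch, in [0,1].

The trait space is a PCoA of the **element-wise square root** of the Gower
matrix. For categorical traits √Gower is exactly Euclidean (each function
embeds as a scaled one-hot simplex), so no meaningfully negative eigenvalues
arise; axes with |eigenvalue| ≤ 1e-8 are dropped, and negative eigenvalues
below −1e-8 — possible only for user-supplied non-Gower input — trigger a
warning. `none` and `cailliez` corrections are available and recorded in the
output. The embedding is built **once per species subset (all / native /
exotic) on that subset's full pool**, so per-site FDis values share one
geometry and are comparable across sites; a site contributes only its weights.

FDis is the abundance-weighted mean distance to the abundance-weighted
centroid. Degenerate cases: one species → 0; a site where the subset is absent
→ missing (NaN), excluded from downstream regressions rather than recorded as
0, since a zero would conflate "no exotics" with "functionally uniform
exotics". The metric is invariant to positive rescaling of the weights and to
duplicating a species while splitting its weight; both are tested, and the
whole computation is checked against a distance-only oracle that derives
centroid distances from the pairwise dissimilarities alone (no
eigendecomposition), to 1e-8 over 200 random pools.

## Boosted regression trees

Drivers of per-site FDis are attributed with a Gaussian-loss boosted ensemble
written for exact reproducibility: at each stage a bag of ⌊0.75·n⌋ rows is
drawn **without replacement**, a depth-limited least-squares tree is fit to
the current residuals on the bag, and the fit is updated with shrinkage
0.001. Split search is exhaustive over midpoints of adjacent distinct values;
ties resolve to the first variable in column order, then the lowest
threshold. Defaults: 10,000 stumps (interaction depth 1) at shrinkage 0.001 —
the tree count such a small learning rate needs — both configurable; the
pipeline default of 3,000 trees keeps multi-replicate property checks cheap
while leaving the influence ranking stable. An out-of-bag improvement curve
is recorded per stage for inspection; no automatic early stopping or
cross-validated tree selection is applied.

**Relative influence** of a variable is the sum of squared-error reductions
over all splits on it across all trees, normalised to percentages summing
to 100. The **direction** of a variable's effect is the sign of a straight
line fit by least squares to its partial-dependence curve (100 grid points,
mean prediction over training rows with the variable pinned), weighted by the
empirical density of the variable so the trend reflects where data actually
lie; |slope| < 1e-12 is reported as flat. A straight-line summary is
appropriate when responses are monotone-dominated rather than unimodal, which
is what the synthetic generator produces and what the influence sign is meant
to capture. With bagging off and depth 1, the ensemble coincides with
scikit-learn's gradient boosting to float precision; that equivalence is a
test, not the implementation.

## Spatial analysis

Coordinates in decimal degrees are projected to a local equirectangular plane
(`x = R·cos(lat̄)·λ`, `y = R·φ`, R = 6371 km) — adequate for extents of a few
degrees. The empirical semivariogram bins half squared differences by
separation distance (15 bins over the observed range by default); a linear
variogram `γ(h) = b·h` is fit through the origin by least squares, with a
non-positive slope rejected as a degenerate field. Ordinary kriging solves
the standard constrained system (weights sum to 1, Lagrange multiplier) with
a global neighbourhood — for a few hundred sites one factorisation serves all
grid nodes. With zero nugget the predictor interpolates exactly, and
predictions are invariant to rescaling the variogram slope (only the kriging
variance changes), so the surface is robust to the slope estimate. Duplicate
locations are averaged with a warning. The default grid is the site bounding
box at 100×100 (50×50 in the pipeline); surfaces are rectangular, with no
basin masking.

Stream order uses the Strahler rule on an explicit reach network (directed
tree to the outlet; a cycle or a braided reach is an error): headwaters are
order 1, a junction increments the maximum tributary order only when it is
attained at least twice. Orders map to four size classes (1–2, 3–4, 5–6, >6);
man-made canals form a separate class regardless of order. Manual order
corrections, where hydrology demands them, are applied by editing the edge
list or overriding orders, not inside the algorithm.

## Curve selection

Relationships (FDis vs invasion degree; FDis vs richness) are summarised by
bounded nonlinear least squares over a registry of seven families: linear,
quadratic, power `a·x^b`, Michaelis–Menten `a·x/(b+x)`, negative exponential
`a(1−e^{−bx})`, logistic `a/(1+b·e^{−cx})`, and rational `(a+bx)/(1+cx)`.
Each fit starts from a family-specific initializer plus four seeded jittered
restarts to reduce local-minimum risk; non-convergent families are excluded
from the weights with a warning. Ranking uses AICc
(`AIC = n·ln(RSS/n) + 2(k+1)`, error variance counted in `k+1`; AICc adds the
small-sample correction), ties broken by higher R², then name. Akaike
weights are `exp(−Δ/2)` normalised. AICc is the default because per-analysis
sample sizes range from a few dozen to a few hundred. The five best fits are
reported.

## Pipeline

The orchestrated run validates the dataset, computes abundance codings and
FDis for all three subsets, fits both BRT influence tables, kriges the
invasion field (all scored sites) and the FDis field (invaded subset), ranks
FDis–invasion curves on the invaded subset, summarises richness and FDis by
stream class (type-7 linear-interpolation quartiles; notch-style 95 % CI of
the median, `median ± 1.57·IQR/√n` — stated because box hinges depend on the
quartile convention), and ranks FDis–richness curves per subset over sites
with subset richness ≥ 1. The **invaded subset** is the sites where natives
and exotics co-occur (0 < degree < 100) at altitude ≤ 400 m, confining
inference to a geographically uniform lowland where least-invaded communities
approximate baseline conditions. The FDis–invasion analysis uses that subset;
the FDis–richness analyses use all sites with subset richness ≥ 1, a choice
recorded in the run manifest. Per-stage seeds derive from the master seed by
a stable hash of the stage name, so stages are independently reproducible;
the manifest plus the data reproduce every output.

## Synthetic data generator

The generator emulates the qualitative structure the analysis assumes, with
every structural knob exposed in `SynthConfig`; it makes no attempt to match
any real drainage's unpublished parameter values. Defaults mirror the study
dimensions: 335 sites on a random dendritic network, 37 native and 22 exotic
species. Its structure:

- **Exotic trait restriction**: native guilds are uniform over the full
  vocabularies; exotic guilds come from a random subset of ⌈ρ·|vocab|⌉ labels
  per function (ρ = 0.3 by default), encoding introduction of species with a
  limited trait repertoire.
- **Invasion–altitude coupling**: per-site invasion propensity is
  `expit(α + β·altitude)` with β = −0.01 /m (α = 1.5), so exotic occupancy
  collapses above ~400 m and the lowlands act as an invasion reservoir.
  Native occupancy (base 0.35 per species) is suppressed proportionally to
  the propensity (0.85 at propensity 1), letting invasion degree span
  0–100 %; headwater reaches thin occupancy of both origins equally (×0.85),
  shrinking communities without biasing composition — so with β = 0 invasion
  degree decorrelates from altitude.
- **Environment**: altitudes from a lowland-exponential + upland-beta mixture
  (62 % lowland mass, scale 60 m, tail to 1200 m) assigned in order of
  network depth; temperature falls linearly with altitude, conductivity and
  nutrient loads decay exponentially with log-normal noise; land-cover shares
  are Dirichlet draws conditioned on altitude band (forest-heavy uplands,
  agricultural/urban lowlands, brackish mass near the outlet).
- **Abundances**: occupied species draw Moyle classes from a fixed
  categorical distribution (0.35, 0.30, 0.20, 0.10, 0.05 for classes 1–5);
  empty draws are repaired with one origin-appropriate species.

Each generator stage draws from its own RNG stream spawned from the master
seed, so pool, sites and communities regenerate independently. Ground truth
(per-site propensity, exotic pool membership, parameters) is stored apart
from the dataset and never consumed by analysis code.

**What passing tests show, and what they do not.** The generator produces
monotone, noisy, spatially autocorrelated structure with a known dominant
driver; recovery tests therefore demonstrate that the pipeline detects such
structure when present and correctly ranks its drivers. Real survey data add
features the generator omits — sampling-method bias across habitats,
temporal turnover, correlated trait syndromes, basin-shaped dispersal limits,
non-monotone environmental responses — so passing tests do not certify
effect sizes on real data, only the correctness and sensitivity of the
machinery. In particular, published influence magnitudes from any real study
depend on unstated boosting hyperparameters (tree count, depth) and are not
expected to be numerically reproduced; the checks here are property-based
(ranking, sign, normalisation) by design.

## Numerical conventions and limitations

- PCoA eigen-tolerance 1e-8; embedding distances reproduce corrected
  dissimilarities to 1e-8 (tested).
- BRT split-improvement threshold 1e-12 (a node with no improving split
  becomes a leaf); all tie-breaks deterministic as above.
- Kriging deduplicates identical locations by averaging; the linear variogram
  has zero nugget by default, making surfaces exact interpolators.
- Curve fits use `scipy.optimize.least_squares` (TRF, bounded), max 2000
  function evaluations per start.
- Problem sizes in the test and acceptance runs — 335 sites, 3000 trees,
  20-replicate property checks, 200-instance oracles, 50×50 kriging grids —
  were chosen to make every stochastic claim cheap to re-verify while keeping
  each property's detection power high.
- Known limitations: no fuzzy (multi-guild) trait membership; no continuous
  traits in the Gower step; no anisotropic or nonlinear variograms; no basin
  masking of kriged surfaces; BRT offers Gaussian loss only.
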