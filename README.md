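# invafun

Trait-based functional diversity and invasion-gradient analysis for stream
fish communities.

## The scientific problem

Exotic fish invasions rarely cause outright regional extinctions, but they can
still erode the *functional* structure of communities: introduced species tend
to carry a narrower set of ecological traits than the natives they displace,
so heavily invaded communities may end up functionally impoverished even when
species counts look healthy. `invafun` implements the full analysis chain used
to test this in drainage-scale survey data, for community ecologists working
with site × species abundance matrices, categorical guild traits and site
environmental tables.

The core quantity is **functional dispersion (FDis)**: the abundance-weighted
mean distance of a community's species to their abundance-weighted centroid in
trait space,

```
c    = Σ_j a_j x_j / Σ_j a_j
FDis = Σ_j a_j ‖x_j − c‖ / Σ_j a_j
```

where `x_j` are species coordinates from a principal-coordinate (PCoA)
embedding of Gower dissimilarities over five categorical ecological functions
(feeding, reproduction, migration, tolerance, habitat use), and `a_j` are
Hellinger-transformed, body-mass-corrected Moyle abundance classes. Around
FDis the package provides:

- **Abundance coding** — Moyle classes (1–5) × a 3-level adult body-mass
  weight; Hellinger transform; per-site **invasion degree** (% of corrected
  abundance contributed by exotic species).
- **Driver attribution** — Gaussian-loss boosted regression trees (bag
  fraction 0.75, shrinkage 0.001) with per-variable relative influence (%)
  and a signed direction of effect from density-weighted partial dependence.
- **Spatial analysis** — ordinary kriging with a linear variogram for
  invasion and FDis surfaces; Strahler ordering of an explicit stream network
  and stream-order size classes (canals kept separate).
- **Model selection** — nonlinear least squares over a registry of
  saturation-curve families, ranked by AICc with Akaike weights and R².
- **Synthetic data** — a generator producing communities with known ground
  truth (restricted exotic guild pool, invasion coupled negatively to
  altitude) for end-to-end recovery testing.

## Worked example

```python
from invafun import (SynthConfig, generate_dataset, correct_abundance,
                     hellinger, invasion_degree, site_fdis, select_invaded_sites,
                     select_best)

species, traits, abundance, env, network, truth = generate_dataset(SynthConfig(rng_seed=1))
corrected = correct_abundance(abundance, species)
degree = invasion_degree(corrected, species)
fd_all = site_fdis(hellinger(corrected), traits, species, "all").fdis

invaded = select_invaded_sites(degree, env)          # natives + exotics co-occur, ≤ 400 m
table = select_best(degree[invaded].to_numpy(), fd_all[invaded].to_numpy(), seed=0)
print(table[["family", "aicc", "aic_weight", "r_squared"]].head(3))
```

prints

```
      family         aicc    aic_weight  r_squared
0   rational -1958.510191  5.287250e-01   0.766901
1  quadratic -1958.280138  4.712750e-01   0.766693
2     linear -1895.875767  1.325371e-14   0.700173
```

i.e. on the default synthetic study the invaded lowland subset holds 257 of
335 sites, and the best-supported FDis–invasion curve (a declining rational
function, AICc weight 0.53, R² 0.77) falls from 0.542 at 55 % invasion to
0.428 at 95 % — about a fifth of community functional diversity lost across
the upper invasion range, driven by the trait-restricted exotic pool the
generator plants. The `examples/` directory has one short script per
capability (simulation, FDis, BRT attribution, kriging, curve selection, full
pipeline); each prints the numbers it computes and what they mean.

A thin CLI mirrors the library for shell use:

```sh
invafun simulate --out data/ --seed 7
invafun validate data/
invafun run data/ --out results/ --seed 7
```

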