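"""Interpolate the invasion-degree field with ordinary linear kriging.

Projects site coordinates to a local plane, fits a linear variogram to the
empirical semivariogram, and solves the ordinary-kriging system on a regular
grid. With a zero nugget the surface passes exactly through the observations.
"""

import numpy as np

from invafun import (
    SynthConfig,
    correct_abundance,
    empirical_semivariogram,
    fit_linear_variogram,
    generate_dataset,
    invasion_degree,
    ordinary_krige,
)
from invafun.spatial import make_grid, project_coords

species, traits, abundance, env, network, truth = generate_dataset(SynthConfig(rng_seed=1))
degree = invasion_degree(correct_abundance(abundance, species), species)

pts = project_coords(env.data["longitude"].to_numpy(), env.data["latitude"].to_numpy())
z = degree.to_numpy()

sv = empirical_semivariogram(pts, z)
vario = fit_linear_variogram(sv)
print(f"linear variogram slope: {vario.slope:.3f} (%^2 per km)")

surface = ordinary_krige(pts, z, vario, make_grid(pts, 40, 40))
print(f"kriged grid: {len(surface.value)} nodes, "
      f"range {surface.value.min():.1f} .. {surface.value.max():.1f} % invasion")

check = ordinary_krige(pts, z, vario, pts)
print(f"max |prediction - observation| at the data sites: "
      f"{np.abs(check.value - z).max():.2e}  (exact interpolation)")
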