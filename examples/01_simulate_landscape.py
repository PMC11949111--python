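"""Generate a synthetic forest-reserve landscape with known ground truth.

Builds a 128x128 grid at 30 m resolution: ~90% forest, a settlement with
cropland/impervious land around it, and three decadal land-cover snapshots
in which cropland expands into forest and impervious land into cropland
along an 8-neighbour frontier.  Every conversion is recorded exactly.
"""

import numpy as np

from hqscape import CLASS_NAMES, LandscapeConfig, generate_covariates, \
    generate_landuse_series

config = LandscapeConfig(
    grid_rows=128, grid_cols=128, cell_size=30.0, seed=1,
    forest_fraction_target=0.9, n_years=3,
    settlement_centers=[(96, 32)],
    transition_rates={(1, 2): 0.05, (2, 6): 0.10, (3, 1): 0.03},
)

covariates = generate_covariates(config)
series, truth = generate_landuse_series(config, covariates)

print("covariates:", ", ".join(covariates.codes()))
for raster in series:
    shares = {CLASS_NAMES[c]: f"{(raster.values == c).mean():.1%}"
              for c in np.unique(raster.values)}
    print(f"{raster.label}: {shares}")

changed = {(i, j): n for (i, j, t), n in truth.transition_counts.items()
           if i != j and t == 0}
print("\nplanted conversions in the first decade (cells):")
for (i, j), n in sorted(changed.items(), key=lambda kv: -kv[1]):
    print(f"  {CLASS_NAMES[i]:>9} -> {CLASS_NAMES[j]:<10} {n}")
# Each line is an exact count of converted cells -- the ground truth that
# the transition-matrix stage must reproduce cell for cell.
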