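# hqscape

Raster-based analysis of habitat quality in forested protected areas:
land-use change accounting, an InVEST-style habitat-quality model, global
and local spatial-autocorrelation (hotspot) analysis, and an
optimal-parameters geographical-detector driver analysis — wired together
into one reproducible pipeline, with a seeded synthetic-landscape generator
that plants fully known ground truth so every stage can be verified.

## Who it is for

Landscape ecologists and ecosystem-service modellers who want the full
methodological chain of a reserve habitat-quality assessment — normally
spread across ArcGIS toolboxes, InVEST, and the R `GD` package — as one
scriptable, testable Python library. Land-cover series are categorical
rasters over a seven-class legend (forest, cropland, shrub, grassland,
water, impervious, wasteland); covariates are co-registered continuous
rasters (elevation, slope, temperature, precipitation, GDP, population
density). Rasters travel as plain-text ESRI ASCII grids with JSON sidecars.

## The models

**Land-use change.** A transition matrix S cross-tabulates area by class
between two dates (S_ij = hectares moving from class i to class j). Two
annualized rates summarize it: the signed single-class dynamic degree
K_i = (A_i(t2) − A_i(t1)) / A_i(t1) · 1/T · 100 and the integrated degree
L_c = Σ_i outflow_i / (2 Σ_i A_i(t1)) · 1/T · 100.

**Habitat quality.** Threat classes degrade surrounding habitat with
distance-decaying intensity i_r(d) = 1 − d/d_rmax (linear) or
exp(−2.99 d / d_rmax) (exponential), hard-cut beyond the maximum influence
distance d_rmax. Degradation at cell x of class j sums decayed impacts
over all threat cells, weighted by normalized threat weights w_r and class
sensitivities S_jr:

    D_x = Σ_r Σ_y (w_r / Σw) · i_r(d(x,y)) · S_jr

and quality follows the half-saturation law Q = H_j · [1 − D^z/(D^z + k^z)]
with suitability H_j, exponent z = 2.5, and k set to half the maximum D.
Scores are graded into four equal 0.25-wide intervals.

**Hotspots.** Global Moran's I (cross-product form, analytic randomization
inference plus an optional seeded permutation test) and local Getis-Ord
Gi* z-scores classified at |z| ≥ 1.65 / 1.96 / 2.58 into 90/95/99%
hotspot and coldspot tiers.

**Drivers (OPGD).** The geographical-detector q statistic
q = 1 − Σ_h N_h σ_h² / (N σ²) measures how much response variance a
stratification explains. The optimal-parameters variant searches five
discretization methods (equal, quantile, Fisher–Jenks natural breaks,
geometric, standard-deviation bands) × 3–8 classes per continuous factor
and keeps the argmax-q split; the interaction detector overlays factor
pairs and classifies the joint q against q1, q2 (nonlinear/dual-factor
enhancement, independence, diminishing).

## Worked example

```python
from hqscape import (DEFAULT_THREATS, LandscapeConfig, default_sensitivity,
                     degradation, generate_covariates,
                     generate_landuse_series, habitat_quality, hq_summary)

config = LandscapeConfig(grid_rows=128, grid_cols=128, seed=1, n_years=3,
                         settlement_centers=[(96, 32)],
                         transition_rates={(1, 2): 0.05, (2, 6): 0.10})
series, truth = generate_landuse_series(config, generate_covariates(config))
sens = default_sensitivity()
for lu in series:
    Q = habitat_quality(lu, degradation(lu, list(DEFAULT_THREATS), sens), sens)
    print(lu.label, *["%.4f" % v for v in hq_summary(Q)])
```

prints

```
year0 0.3743 0.1390
year1 0.3823 0.1424
year2 0.3852 0.1438
```

— the masked mean and standard deviation of the habitat-quality score per
snapshot. On this landscape the mean sits near 0.38: the settlement's
cropland ring saturates degradation locally while the forest interior
stays near its suitability ceiling. The `examples/` directory holds one
short script per capability (simulation, change accounting, habitat
quality, hotspots, drivers, full pipeline), each printing the numbers it
computes; `examples/05_drivers_opgd.py`, for instance, ranks a planted
elevation driver first with q ≈ 0.86 against noise factors at q < 0.01.

The same workflow runs from a shell:

```bash
hqscape run-all --config examples/config.yaml --seed 1
```

writing fixed-name CSVs and ASCII grids under the run directory plus a
`manifest.json` with a SHA-256 per output; reruns with the same config and
seed are byte-identical.

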