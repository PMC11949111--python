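# Methods

This note documents the models implemented in `hqscape`, the choices made
where the underlying methods leave room, and what the synthetic-data tests
do and do not establish.

## Synthetic landscapes

The generator emulates the input side of a forest-reserve habitat-quality
study without any external data. Elevation is low-pass-filtered white
noise (Gaussian kernel, default correlation length 6 cells) rescaled to
400–2400 m — any spatially autocorrelated surface serves the purpose of a
DEM here. Slope is the central-difference gradient magnitude in degrees.
Temperature falls with elevation at 6.5 °C/km and precipitation rises at
0.25 mm/m, each plus Gaussian noise (defaults 0.3 °C, 25 mm); GDP and
population density decay exponentially with distance to the nearest
settlement center. These defaults are one realistic mountainous-subtropics
parameterization; all are configurable per run.

The year-0 land cover realizes the forest-fraction target (default 0.9,
the share reported for forest reserve systems of this kind) exactly up to
rounding, placing forest on high-elevation, settlement-remote cells, an
impervious core and cropland ring around each settlement, and
water/shrub/grassland/wasteland on the remainder by elevation band. Later
snapshots apply per-(from, to) conversion probabilities, but a cell may
only convert to a class it is 8-adjacent to ("frontier growth"). This rule
is not a claim about real land-cover dynamics; it produces spatially
coherent, exactly countable conversions. The emitted truth records the
full per-period class-change cross-tabulation, so transition accounting
can be checked cell for cell. The class codebook is fixed internally
(1=forest … 7=wasteland); external codings are remapped on ingestion.

What passing tests on these landscapes show: the accounting, kernels and
detectors are computed correctly and recover planted structure. What they
do not show: realism of any particular geography, projection handling
(the pipeline requires one shared equal-area grid and never reprojects),
or behaviour under classification noise in real land-cover products.

## Transition accounting

Areas are reported in hectares. Cells that are nodata in either year are
excluded from both marginals, so row/column conservation holds exactly.
The integrated dynamic degree divides total outflow by twice the total
start area and by the period length (percent per year, nonnegative). The
per-class rate is the standard signed single dynamic degree
(end − start)/start/T × 100; a class with zero start area has no defined
rate and is reported as missing with a warning. Both rates are invariant
to class relabelling. No Markov projection of future cover is attempted.

## Habitat-quality model

Only the decay law i_r(d) and the half-saturation law for Q are fixed by
the method family; the degradation summation is implemented as the
standard InVEST-style weighted sum with the accessibility factor fixed at
1 (no accessibility layer is modelled):
D_x = Σ_r Σ_y (w_r/Σw) · i_r(d) · S_jr. Weight normalization by Σw_r can
be switched off. Distances are Euclidean between cell centers in projected
metres. Both decay forms are hard-cut to zero at d ≥ d_rmax (the
exponential kernel is at exp(−2.99) ≈ 5% of its peak there), giving
bounded kernels consistent with a "maximum influence distance".

The cutwise sum is evaluated by FFT convolution of the binary threat grid
with the radial decay kernel — algebraically identical to the all-pairs
sum, and verified against a brute-force double loop to < 1e−9. Values
below 1e−12 after convolution are snapped to zero (FFT round-off; genuine
contributions are orders of magnitude larger). Threat cells outside the
analysis mask but inside the raster extent remain active sources, since
pressure from just outside a reserve boundary is real; callers can buffer
the mask to change this.

D as a raw sum over threat cells depends on cell size (twice the
resolution means four times the sources). `area_weight=True` multiplies
each source by its cell area, making D a Riemann sum that converges under
grid refinement (verified to < 2% at interior cells when the kernel spans
≥ 12 cells). Because k is set to half the maximum D, quality Q is
invariant to this uniform rescaling, so the default keeps the raw sum,
under which single-source hand calculations are exact.

z defaults to 2.5 (the model family's customary default). k follows the
half-of-maximum-D rule per raster; if several years must share a scale,
pass k explicitly (computed once) — per-raster k makes each year's Q
relative to its own worst degradation, which slightly compresses
between-year differences. A threat-free landscape has max D = 0; the
half-saturation term is then defined as 0 and Q = H_j exactly. Grades use
half-open intervals [0, 0.25), [0.25, 0.5), [0.5, 0.75) and closed
[0.75, 1], so a score of exactly 0.25 is "medium". Summary statistics are
the plain masked mean and population standard deviation.

## Spatial autocorrelation

Moran's I is the canonical cross-product statistic; inference uses the
analytic mean and variance under the randomization (permutation-moment)
null, with an optional seeded permutation test whose two-sided pseudo
p-value is (1 + #{|I* − E| ≥ |I − E|}) / (1 + nperm). Gi* uses the
self-inclusive convention and is reported directly as a z-score; cells
whose denominator degenerates (neighbourhood covering the whole mask) get
z = 0. Weight schemes: rook/queen contiguity and a distance band on cell
centers; binary or row standardization. Defaults mirror common desktop-GIS
practice — row-standardized queen weights for Moran's I, binary
self-inclusive queen weights for Gi*. Significance tiers are two-sided at
|z| ≥ 1.65, 1.96, 2.58 (90/95/99%); the middle tier completes the standard
three-tier hotspot map around the outer two thresholds. Constant fields
are rejected rather than returned as zeros.

## Geographical detector

q = 1 − Σ_h N_h σ_h² / (N σ²) with population variances, computed with a
two-pass (centered) within-group sum of squares for numerical stability.
q is exactly invariant to affine transforms of the response and to
stratum relabelling, and never decreases under stratum refinement — the
basis for the guarantee that a pair's joint q is at least each factor's
own q. No significance test for q is attached (the classic noncentral-F
test is out of scope).

Discretization methods: equal width; equal-count quantiles; exact
Fisher–Jenks natural breaks by dynamic programming (O(k n²), computed on
a deterministic quantile-spaced subsample above 1000 distinct values, with
the cut table cached so a 3–8-class search pays for one DP); geometric
intervals on a shifted-log scale; and mean ± k·σ bands. Breaks are
right-closed; empty classes are merged so labels stay contiguous. The
search grid defaults to all five methods × 3–8 classes; invalid
combinations (too few distinct values, strata below the minimum size) are
skipped, and ties break toward fewer classes, then method order.
Categorical factors (e.g. the land-use intensity recode: natural covers
1, cropland 2, impervious 3 — wasteland counted natural, as it carries no
active human use) are used as-is.

Interaction classification follows the standard five-type taxonomy with
explicit precedence: q12 > q1 + q2 is nonlinear enhancement even though it
also exceeds max(q1, q2); independence (q12 = q1 + q2) is declared only
within 1e−12, since exact equality is measure-zero in floating point.
Empty product strata simply do not occur as labels (dropped, not imputed).
Detection operates on masked cells; aggregating to sampling points is left
to the caller.

## Pipeline

One config drives simulate → transitions → habitat quality → autocorrelation
→ driver detection. All stages share one grid; grid mismatches fail
loudly, and a failed stage leaves a `FAILED` marker naming the stage. The
manifest records the config hash, package version and a SHA-256 per output
file; identical config + seed reproduce identical CSVs byte for byte. The
OPGD stage pairs the final-year habitat quality with the covariate stack
plus the same-year land-use intensity recode by default.

## Problem sizes and test design

Oracle equivalences run on 32×32 (degradation) and 15×15 (Moran/Gi*)
fixtures, where brute-force double loops are exact and fast; generator
truth-recovery runs at 128×128 × 3 snapshots; driver recovery uses 50
replicates of a 100×100 grid with a planted monotone driver (noise sd 0.1)
against four white-noise factors. Permutation calibration uses 500
shuffles × 199 permutations on a 15×15 field and checks the rejection rate
at the 0.1 level against the exact binomial 95% band. These sizes make
every oracle exhaustive or exact while each module remains the same code
path used at larger scales.

## Known limitations

- No reprojection, geodesic distances, or shapefile geoprocessing; inputs
  must share one projected equal-area grid.
- The InVEST accessibility layer and habitat-rarity module are not
  modelled; no parity testing against the InVEST binary is attempted.
- Local Moran (LISA) and the risk/ecological detectors of the geodetector
  family are out of scope.
- The synthetic generator's frontier rule yields conservative conversion
  volumes; it is a verification harness, not a land-change forecast model.
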