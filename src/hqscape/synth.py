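"""Seeded synthetic landscapes with planted, fully known structure.

Generates what a desk study of forest nature reserves needs as input: a
multi-year categorical land-cover series dominated by forest (~90% by
default), with cropland and impervious surfaces expanding around settlement
seeds, plus spatially structured covariate surfaces (elevation-driven
climate, settlement-driven GDP and population density).  Every conversion
is recorded cell-by-cell, so downstream transition accounting and driver
detection can be checked against exact planted truth.

The elevation surface is low-pass-filtered white noise — any spatially
autocorrelated surrogate for a real DEM serves here; growth of cropland
and impervious land follows an 8-neighbour frontier rule so conversions
are spatially coherent and countable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .grid import CLASS_CODES, LandUseRaster, Raster
from .opgd import FactorStack

FOREST = CLASS_CODES["forest"]
CROPLAND = CLASS_CODES["cropland"]
SHRUB = CLASS_CODES["shrub"]
GRASSLAND = CLASS_CODES["grassland"]
WATER = CLASS_CODES["water"]
IMPERVIOUS = CLASS_CODES["impervious"]
WASTELAND = CLASS_CODES["wasteland"]

COVARIATE_NAMES = ("elevation", "slope", "temperature", "precipitation",
                   "gdp", "population_density")

#: default per-covariate additive noise standard deviations
DEFAULT_NOISE_SD = {
    "temperature": 0.3,     # °C
    "precipitation": 25.0,  # mm
    "gdp": 0.05,            # billion yuan (relative units)
    "population_density": 0.1,  # persons / ha
}


@dataclass
class LandscapeConfig:
    """Parameters of one synthetic study area.

    Defaults emulate the study conditions: a 30 m grid, ~90% forest cover,
    cropland and impervious expansion near settlements over 3 time points.
    """

    grid_rows: int = 128
    grid_cols: int = 128
    cell_size: float = 30.0
    seed: int = 0
    forest_fraction_target: float = 0.9
    n_years: int = 3
    #: None -> one default settlement in the lower-left quadrant; an explicit
    #: empty list means a landscape with no settlements at all
    settlement_centers: list[tuple[int, int]] | None = None
    #: (from_class, to_class) -> per-step conversion probability
    transition_rates: dict[tuple[int, int], float] = field(default_factory=dict)
    covariate_noise_sd: dict[str, float] = field(default_factory=dict)
    smooth_sigma: float = 6.0  # cells; elevation correlation length

    def __post_init__(self) -> None:
        if self.grid_rows < 16 or self.grid_cols < 16:
            raise ValueError("grid too small: need at least 16x16 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not 0 < self.forest_fraction_target < 1:
            raise ValueError("forest_fraction_target must be in (0,1)")
        if self.n_years < 2:
            raise ValueError("need at least 2 years")
        outgoing: dict[int, float] = {}
        for (i, j), p in self.transition_rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"transition rate ({i}->{j}) = {p} outside [0,1]")
            outgoing[i] = outgoing.get(i, 0.0) + p
        for i, total in outgoing.items():
            if total > 1 + 1e-12:
                raise ValueError(f"outgoing rates from class {i} sum to {total} > 1")
        sd = dict(DEFAULT_NOISE_SD)
        sd.update(self.covariate_noise_sd)
        self.covariate_noise_sd = sd
        if self.settlement_centers is None:
            self.settlement_centers = [(3 * self.grid_rows // 4,
                                        self.grid_cols // 4)]

    def default_settlements(self) -> list[tuple[int, int]]:
        return list(self.settlement_centers)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the generated rasters."""

    #: (from_class, to_class, period_index) -> exact cell count; includes the
    #: diagonal (unchanged cells), so counts per period sum to the mask size.
    transition_counts: dict[tuple[int, int, int], int]
    dominant_driver: str | None = None
    driver_effect: dict | None = None

    def to_jsonable(self) -> dict:
        return {
            "transition_counts": {
                f"{i}->{j}@{t}": int(n)
                for (i, j, t), n in sorted(self.transition_counts.items())
            },
            "dominant_driver": self.dominant_driver,
            "driver_effect": self.driver_effect,
        }


def parse_transition_rates(raw: dict) -> dict[tuple[int, int], float]:
    """Normalize transition-rate keys: tuples, lists or ``"i->j"`` strings
    (the YAML-friendly form) all map to (from_class, to_class) tuples."""
    out: dict[tuple[int, int], float] = {}
    for key, p in raw.items():
        if isinstance(key, str):
            i, j = key.split("->")
            key = (int(i), int(j))
        else:
            key = tuple(int(c) for c in key)
        out[key] = float(p)
    return out


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardized low-pass-filtered white noise (correlation length ~ sigma)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="reflect")
    return (f - f.mean()) / f.std()


def _settlement_distance(config: LandscapeConfig) -> np.ndarray:
    """Euclidean distance (metres) from each cell to the nearest settlement."""
    shape = (config.grid_rows, config.grid_cols)
    centers = config.default_settlements()
    if not centers:
        # settlement-free landscape: uniform maximal remoteness
        return np.full(shape, np.hypot(*shape) * config.cell_size)
    seeds = np.ones(shape, dtype=bool)
    for r, c in centers:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"settlement center {(r, c)} outside grid")
        seeds[r, c] = False
    return ndimage.distance_transform_edt(seeds) * config.cell_size


def generate_covariates(config: LandscapeConfig) -> FactorStack:
    """Emit the six covariate surfaces on the configured grid.

    Elevation is a smooth random field rescaled to 400–2400 m; slope is its
    central-difference gradient magnitude in degrees; temperature falls and
    precipitation rises with elevation (lapse-rate style linear maps plus
    noise); GDP and population density decay with distance to the nearest
    settlement center.
    """
    shape = (config.grid_rows, config.grid_cols)
    ss = np.random.SeedSequence([config.seed, 0xC0FA])
    streams = [np.random.default_rng(s) for s in ss.spawn(5)]
    sd = config.covariate_noise_sd

    elev = 1400.0 + 1000.0 * np.tanh(_smooth_field(streams[0], shape,
                                                   config.smooth_sigma) / 1.5)
    gy, gx = np.gradient(elev, config.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gy, gx)))

    temp = 24.0 - 0.0065 * elev + sd["temperature"] * streams[1].standard_normal(shape)
    precip = 900.0 + 0.25 * elev + sd["precipitation"] * streams[2].standard_normal(shape)

    dist = _settlement_distance(config)
    extent = max(shape) * config.cell_size
    gdp = 1.0 * np.exp(-dist / (0.25 * extent)) + sd["gdp"] * streams[3].standard_normal(shape)
    pop = 2.0 * np.exp(-dist / (0.20 * extent)) + sd["population_density"] * streams[4].standard_normal(shape)

    mask = np.ones(shape, dtype=bool)
    layers = {
        "elevation": elev, "slope": slope, "temperature": temp,
        "precipitation": precip, "gdp": gdp, "population_density": pop,
    }
    rasters = {
        name: Raster(values=vals.astype(float), cell_size=config.cell_size,
                     mask=mask, label=name)
        for name, vals in layers.items()
    }
    return FactorStack(layers=rasters,
                       metadata={"seed": config.seed,
                                 "settlements": config.default_settlements()})


def _initial_landuse(config: LandscapeConfig, covariates: FactorStack,
                     rng: np.random.Generator) -> np.ndarray:
    shape = (config.grid_rows, config.grid_cols)
    n_cells = shape[0] * shape[1]
    elev = covariates["elevation"].values
    dist = _settlement_distance(config)

    def z(a):
        return (a - a.mean()) / (a.std() + 1e-12)

    # settlement cores: impervious disk, cropland annulus
    lu = np.zeros(shape, dtype=np.int64)
    rr, cc = np.indices(shape)
    for r, c in config.default_settlements():
        d = np.hypot(rr - r, cc - c)
        lu[(d <= 5) & (lu == 0)] = CROPLAND
        lu[d <= 2] = IMPERVIOUS

    # forest on high-elevation / far-from-settlement cells, exact count
    score = z(elev) + z(dist) + 0.1 * rng.standard_normal(shape)
    score[lu != 0] = -np.inf
    n_forest = int(round(config.forest_fraction_target * n_cells))
    order = np.argsort(score.ravel())[::-1]
    forest_idx = order[:n_forest]
    lu.ravel()[forest_idx] = FOREST

    # remaining cells: water in valley bottoms, shrub near forest edge,
    # wasteland on high dry cells, grassland elsewhere
    rest = lu == 0
    if rest.any():
        e = elev[rest]
        lo, hi = np.quantile(e, [0.15, 0.85])
        fill = np.full(e.shape, GRASSLAND, dtype=np.int64)
        fill[e <= lo] = WATER
        fill[e >= hi] = WASTELAND
        near_forest = ndimage.binary_dilation(lu == FOREST,
                                              structure=np.ones((3, 3)))[rest]
        fill[(e > lo) & (e < hi) & near_forest] = SHRUB
        lu[rest] = fill
    return lu


_EIGHT = np.ones((3, 3), dtype=bool)


def _step_landuse(lu: np.ndarray, rates: dict[tuple[int, int], float],
                  rng: np.random.Generator) -> np.ndarray:
    """One frontier-growth step: a cell may convert to class j only if it is
    8-adjacent to an existing j cell; per-cell destination chosen by a single
    uniform draw partitioned by the outgoing rates of its current class."""
    new = lu.copy()
    u = rng.random(lu.shape)
    by_from: dict[int, list[tuple[int, float]]] = {}
    for (i, j), p in rates.items():
        if p > 0:
            by_from.setdefault(i, []).append((j, p))
    adjacency = {
        j: ndimage.binary_dilation(lu == j, structure=_EIGHT)
        for j in {j for lst in by_from.values() for j, _ in lst}
    }
    for i, dests in by_from.items():
        lower = 0.0
        for j, p in sorted(dests):
            upper = lower + p
            convert = (lu == i) & (u >= lower) & (u < upper) & adjacency[j]
            new[convert] = j
            lower = upper
    return new


def generate_landuse_series(
    config: LandscapeConfig, covariates: FactorStack
) -> tuple[list[LandUseRaster], SyntheticTruth]:
    """Generate ``n_years`` land-cover rasters plus exact transition truth.

    Year 0 realizes the forest-fraction target exactly (up to rounding) with
    cropland/impervious seeded around settlements; later years apply the
    configured frontier transition rates.  The returned truth records the
    full per-period class-change cross-tabulation.
    """
    shape = (config.grid_rows, config.grid_cols)
    if covariates.mask.shape != shape:
        raise ValueError("covariates not on the configured grid")
    urban_rates = any(
        p > 0 and j in (CROPLAND, IMPERVIOUS)
        for (i, j), p in config.transition_rates.items()
    )
    if urban_rates and not config.default_settlements():
        raise ValueError(
            "nonzero cropland/impervious transition rates need settlement centers")

    ss = np.random.SeedSequence([config.seed, 0x1A2D])
    rng_init, rng_step = (np.random.default_rng(s) for s in ss.spawn(2))
    lu = _initial_landuse(config, covariates, rng_init)
    mask = np.ones(shape, dtype=bool)
    series = [lu]
    for _ in range(config.n_years - 1):
        series.append(_step_landuse(series[-1], config.transition_rates, rng_step))

    counts: dict[tuple[int, int, int], int] = {}
    for t in range(len(series) - 1):
        a, b = series[t], series[t + 1]
        pairs, n = np.unique(np.stack([a.ravel(), b.ravel()]), axis=1,
                             return_counts=True)
        for (i, j), c in zip(pairs.T, n):
            counts[(int(i), int(j), t)] = int(c)

    rasters = [
        LandUseRaster(values=v, cell_size=config.cell_size, mask=mask,
                      label=f"year{t}")
        for t, v in enumerate(series)
    ]
    return rasters, SyntheticTruth(transition_counts=counts)


# ---------------------------------------------------------------------------
# Planted habitat-quality driver
# ---------------------------------------------------------------------------

_EFFECTS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda s: s,
    "negative": lambda s: 1.0 - s,
    "sqrt": np.sqrt,
    "square": lambda s: s**2,
}


def plant_hq_driver(covariates: FactorStack, driver: str,
                    effect: str | Callable[[np.ndarray], np.ndarray] = "identity",
                    noise_sd: float = 0.1, seed: int = 0) -> Raster:
    """Build a response surface that is a known monotone function of one
    covariate plus Gaussian noise, clipped to [0, 1].

    The driver is min-max scaled to [0, 1] before the monotone map is
    applied, so the planted signal is comparable across covariates.
    """
    if driver not in covariates:
        raise ValueError(f"unknown driver {driver!r}; have {covariates.codes()}")
    if isinstance(effect, str):
        if effect not in _EFFECTS:
            raise ValueError(f"unknown effect {effect!r}")
        g = _EFFECTS[effect]
    else:
        g = effect
    x = covariates[driver].values.astype(float)
    s = (x - x.min()) / (x.max() - x.min() + 1e-300)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD21F]))
    resp = np.clip(g(s) + noise_sd * rng.standard_normal(x.shape), 0.0, 1.0)
    return Raster(values=resp, cell_size=covariates.cell_size,
                  mask=covariates.mask.copy(), label=f"response({driver})")
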