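"""InVEST-style habitat-quality model.

Each threat r (here: cropland and construction/impervious land) degrades
surrounding habitat with a distance-decaying intensity

    i_r(d) = 1 - d / d_rmax                      (linear decay)
    i_r(d) = exp(-(2.99 / d_rmax) * d)           (exponential decay)

hard-cut to 0 beyond the maximum influence distance d_rmax.  The
degradation index at cell x of habitat class j sums decayed impacts from
every threat cell y, weighted by the (optionally sum-normalized) threat
weight w_r and the class sensitivity S_jr, with accessibility fixed at 1:

    D_xj(x) = sum_r sum_{y : r_y = 1} (w_r / sum_r w_r) i_r(d(x, y)) S_jr

Habitat quality combines intrinsic suitability H_j with degradation via a
half-saturation response:

    Q_xj = H_j * [1 - D^z / (D^z + k^z)]

with z = 2.5 by default and k set to half the maximum D over the mask.
Distances are Euclidean between cell centers in projected metres; the sum
over threat cells is evaluated with an FFT convolution of the binary threat
grid against the decay kernel, which is exactly the all-pairs sum.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .grid import CLASS_CODES, LandUseRaster, Raster

#: Exponential kernels are scaled so intensity falls to exp(-2.99) ≈ 5% of
#: the source value at the maximum influence distance.
EXP_DECAY_CONSTANT = 2.99

DEFAULT_Z = 2.5


@dataclass
class ThreatSpec:
    """One threat factor: where it sits and how its impact decays."""

    name: str
    source_classes: frozenset[int]
    d_rmax_km: float
    weight: float
    decay: str  # "linear" | "exponential"

    def __post_init__(self) -> None:
        self.source_classes = frozenset(int(c) for c in self.source_classes)
        if self.d_rmax_km <= 0:
            raise ValueError("d_rmax must be positive")
        if self.weight < 0:
            raise ValueError("threat weight must be nonnegative")
        if self.decay not in ("linear", "exponential"):
            raise ValueError("decay must be 'linear' or 'exponential'")

    @property
    def d_rmax_m(self) -> float:
        return self.d_rmax_km * 1000.0


#: Study parameterization: cropland threat (6 km, weight 0.7, linear) and
#: construction-land threat (5 km, weight 1, exponential).
DEFAULT_THREATS = (
    ThreatSpec("cropland", frozenset({CLASS_CODES["cropland"]}), 6.0, 0.7, "linear"),
    ThreatSpec("construction", frozenset({CLASS_CODES["impervious"]}), 5.0, 1.0,
               "exponential"),
)


@dataclass
class SensitivityTable:
    """Habitat suitability H_j and per-threat sensitivity S_jr by class."""

    suitability: dict[int, float]
    sensitivity: dict[tuple[int, str], float]  # (class code, threat name)

    def __post_init__(self) -> None:
        for c, h in self.suitability.items():
            if not 0 <= h <= 1:
                raise ValueError(f"suitability H[{c}] = {h} outside [0,1]")
        for key, s in self.sensitivity.items():
            if not 0 <= s <= 1:
                raise ValueError(f"sensitivity S[{key}] = {s} outside [0,1]")

    def H(self, class_code: int) -> float:
        return self.suitability.get(int(class_code), 0.0)

    def S(self, class_code: int, threat: str, warn_missing: bool = False) -> float:
        key = (int(class_code), threat)
        if key not in self.sensitivity:
            if warn_missing:
                warnings.warn(f"missing sensitivity for {key}; defaulting to 0",
                              stacklevel=2)
            return 0.0
        return self.sensitivity[key]

    def digest(self) -> str:
        payload = repr((sorted(self.suitability.items()),
                        sorted(self.sensitivity.items())))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_frame(self, threats: list[str]) -> pd.DataFrame:
        rows = []
        from .grid import CLASS_NAMES
        for c in sorted(self.suitability):
            row = {"class": CLASS_NAMES.get(c, str(c)),
                   "habitat_suitability": self.suitability[c]}
            for t in threats:
                row[t] = self.S(c, t)
            rows.append(row)
        return pd.DataFrame(rows)


def default_sensitivity() -> SensitivityTable:
    """The study's suitability/sensitivity parameterization."""
    C = CLASS_CODES
    suit = {C["forest"]: 1.0, C["cropland"]: 0.5, C["shrub"]: 1.0,
            C["grassland"]: 0.7, C["water"]: 0.8, C["wasteland"]: 0.2,
            C["impervious"]: 0.0}
    sens = {
        (C["cropland"], "cropland"): 0.0, (C["cropland"], "construction"): 0.6,
        (C["forest"], "cropland"): 0.7, (C["forest"], "construction"): 0.65,
        (C["shrub"], "cropland"): 0.65, (C["shrub"], "construction"): 0.6,
        (C["grassland"], "cropland"): 0.55, (C["grassland"], "construction"): 0.5,
        (C["water"], "cropland"): 0.6, (C["water"], "construction"): 0.4,
        (C["wasteland"], "cropland"): 0.0, (C["wasteland"], "construction"): 0.0,
        (C["impervious"], "cropland"): 0.0, (C["impervious"], "construction"): 0.0,
    }
    return SensitivityTable(suitability=suit, sensitivity=sens)


# ---------------------------------------------------------------------------
# Decay and degradation
# ---------------------------------------------------------------------------

def decay_factor(d_xy, spec: ThreatSpec):
    """Decayed impact intensity i_r(d) in [0, 1] at distance ``d_xy`` metres.

    Accepts scalars or arrays.  Both decay forms are hard-cut to 0 beyond
    d_rmax (the exponential form is at ~5% of its peak there).
    """
    d = np.asarray(d_xy, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    dmax = spec.d_rmax_m
    if spec.decay == "linear":
        i = np.maximum(0.0, 1.0 - d / dmax)
    else:
        i = np.exp(-(EXP_DECAY_CONSTANT / dmax) * d)
    i = np.where(d < dmax, i, 0.0)
    return float(i) if np.isscalar(d_xy) else i


def threat_raster(landuse: LandUseRaster, spec: ThreatSpec) -> np.ndarray:
    """Binary presence grid r_y of one threat over the full raster extent.

    Threat cells outside the analysis mask still act as sources (pressure
    from just outside a reserve boundary is real), so the mask is not
    applied here.
    """
    unknown = spec.source_classes - set(landuse.codebook.values())
    if unknown:
        raise ValueError(f"threat source classes {sorted(unknown)} not in codebook")
    return np.isin(landuse.values, list(spec.source_classes)).astype(float)


def _decay_kernel(spec: ThreatSpec, cell_size: float) -> np.ndarray:
    """Radially symmetric kernel of decayed intensities on the cell grid."""
    radius = int(np.floor(spec.d_rmax_m / cell_size))
    offsets = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    d = np.hypot(dy, dx) * cell_size
    return decay_factor(d, spec)


@dataclass
class DegradationRaster(Raster):
    provenance: dict = field(default_factory=dict)


def degradation(landuse: LandUseRaster, threats: list[ThreatSpec],
                sens: SensitivityTable, normalize_weights: bool = True,
                area_weight: bool = False) -> DegradationRaster:
    """Total degradation index D_xj over the land-use raster.

    For each threat the binary source grid is convolved with its decay
    kernel (equivalent to the all-pairs sum over threat cells within
    d_rmax), scaled by the normalized weight, then modulated cellwise by
    the sensitivity of the receiving cell's class.

    With ``area_weight=True`` each source contribution carries its cell
    area (hectares), making D a Riemann sum that converges under grid
    refinement.  This is a uniform rescaling of D, so the habitat-quality
    score is unaffected whenever k follows the half-of-max rule.
    """
    if not threats:
        raise ValueError("need at least one threat")
    w_total = sum(t.weight for t in threats) if normalize_weights else 1.0
    if w_total == 0:
        raise ValueError("threat weights sum to zero")
    D = np.zeros(landuse.shape, dtype=float)
    for spec in threats:
        sources = threat_raster(landuse, spec)
        kernel = _decay_kernel(spec, landuse.cell_size)
        if sources.any():
            impact = signal.fftconvolve(sources, kernel, mode="same")
            # zero out FFT round-off dust (true contributions are >= ~1e-4)
            impact[impact < 1e-12] = 0.0
        else:
            impact = np.zeros_like(D)
        s_lookup = np.array([
            sens.S(c, spec.name, warn_missing=True)
            if c in set(landuse.codebook.values()) else 0.0
            for c in range(int(landuse.values.max()) + 2)
        ])
        D += (spec.weight / w_total) * impact * s_lookup[landuse.values]
    if area_weight:
        D *= landuse.cell_area_ha
    return DegradationRaster(
        values=D, cell_size=landuse.cell_size, nodata=-9999.0,
        mask=landuse.mask.copy(),
        provenance={
            "threats": [vars(t) | {"source_classes": sorted(t.source_classes)}
                        for t in threats],
            "sensitivity_sha": sens.digest(),
            "normalize_weights": normalize_weights,
        },
    )


def degradation_bruteforce(landuse: LandUseRaster, threats: list[ThreatSpec],
                           sens: SensitivityTable,
                           normalize_weights: bool = True,
                           area_weight: bool = False) -> np.ndarray:
    """All-pairs reference evaluation of D (independent of the kernel path).

    Quadratic in cell count; intended for validation on small grids.
    """
    w_total = sum(t.weight for t in threats) if normalize_weights else 1.0
    nrows, ncols = landuse.shape
    rr, cc = np.indices((nrows, ncols))
    D = np.zeros((nrows, ncols))
    for spec in threats:
        sources = np.argwhere(threat_raster(landuse, spec) > 0)
        s_map = np.vectorize(lambda c: sens.S(c, spec.name))(landuse.values)
        acc = np.zeros((nrows, ncols))
        for (yr, yc) in sources:
            d = np.hypot(rr - yr, cc - yc) * landuse.cell_size
            acc += decay_factor(d, spec)
        D += (spec.weight / w_total) * acc * s_map
    if area_weight:
        D *= landuse.cell_area_ha
    return D


# ---------------------------------------------------------------------------
# Habitat quality, grading, summaries
# ---------------------------------------------------------------------------

@dataclass
class HabitatQualityRaster(Raster):
    z_exponent: float = DEFAULT_Z
    k_half_saturation: float = 0.0


def habitat_quality(landuse: LandUseRaster, degr: DegradationRaster,
                    sens: SensitivityTable, z: float = DEFAULT_Z,
                    k: float | None = None) -> HabitatQualityRaster:
    """Half-saturation habitat-quality score Q = H_j [1 - D^z/(D^z + k^z)].

    ``k`` defaults to half the maximum degradation over the mask (the
    study's rule).  A threat-free landscape (max D = 0) gives Q = H_j
    everywhere.  Pass ``k`` explicitly to share one half-saturation constant
    across years.
    """
    landuse.require_same_grid(degr)
    if z <= 0:
        raise ValueError("z must be positive")
    D = degr.values
    if k is None:
        dmax = float(D[degr.mask].max()) if degr.mask.any() else 0.0
        k = 0.5 * dmax
    H_lookup = np.array([sens.H(c) for c in range(int(landuse.values.max()) + 2)])
    H = H_lookup[landuse.values]
    if k == 0:
        Q = H.astype(float)
    else:
        Dz = np.power(D, z)
        Q = H * (1.0 - Dz / (Dz + k**z))
    return HabitatQualityRaster(
        values=Q, cell_size=landuse.cell_size, nodata=-9999.0,
        mask=landuse.mask.copy(), label=landuse.label,
        z_exponent=z, k_half_saturation=float(k),
    )


#: equal-interval grade bins; the last interval is closed at 1.0
HQ_GRADES = (
    ("low", 0.00, 0.25),
    ("medium", 0.25, 0.50),
    ("moderately_high", 0.50, 0.75),
    ("high", 0.75, 1.00),
)


def grade_hq(hq: HabitatQualityRaster) -> pd.DataFrame:
    """Area (ha) and proportion of the mask in each of the four grades.

    Bins are half-open [lo, hi) except the top bin, which is [0.75, 1.0].
    """
    q = hq.masked()
    n = q.size
    rows = []
    for name, lo, hi in HQ_GRADES:
        if hi >= 1.0:
            count = int(np.sum((q >= lo) & (q <= hi)))
        else:
            count = int(np.sum((q >= lo) & (q < hi)))
        rows.append({"grade": name, "lower": lo, "upper": hi,
                     "area_ha": count * hq.cell_area_ha,
                     "proportion": count / n})
    return pd.DataFrame(rows)


def hq_summary(hq: HabitatQualityRaster) -> tuple[float, float]:
    """Masked mean and population standard deviation of habitat quality."""
    q = hq.masked()
    if q.size == 0:
        raise ValueError("empty mask")
    return float(q.mean()), float(q.std())
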