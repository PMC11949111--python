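"""Global Moran's I and local Getis-Ord Gi* hotspot analysis on rasters.

Global Moran's I in the canonical cross-product form, for deviations
z_i = x_i - x̄ and spatial weights w_ij with S0 = sum w_ij:

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2)

Inference uses the analytic moments under the randomization null, with an
optional seeded permutation test.  The local Gi* statistic (self-inclusive
by convention) is reported directly as a z-score:

    Gi*(i) = [sum_j w_ij x_j - x̄ W_i] / (S * sqrt[(n S1_i - W_i^2)/(n-1)])

with W_i = sum_j w_ij, S1_i = sum_j w_ij^2 and S the population standard
deviation of x.  Cells are classified into hotspot/coldspot tiers at
|z| >= 1.65 (90%), 1.96 (95%) and 2.58 (99%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from scipy.spatial import cKDTree

SIGNIFICANCE_THRESHOLDS = (1.65, 1.96, 2.58)

#: class codes: sign = direction, magnitude = tier (1=90%, 2=95%, 3=99%)
CLASS_LABELS = {
    -3: "coldspot99", -2: "coldspot95", -1: "coldspot90",
    0: "not_significant",
    1: "hotspot90", 2: "hotspot95", 3: "hotspot99",
}


@dataclass
class SpatialWeights:
    """Sparse spatial weights over the masked cells of a grid."""

    matrix: sparse.csr_matrix    # n_masked x n_masked
    cell_index: np.ndarray       # grid of flat ids, -1 outside mask
    mask: np.ndarray
    scheme: str
    standardization: str
    include_self: bool
    band_distance: float | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_weights(mask: np.ndarray, scheme: str = "queen",
                  band_distance: float | None = None,
                  standardization: str = "row",
                  include_self: bool = False,
                  cell_size: float = 1.0) -> SpatialWeights:
    """Build contiguity or distance-band weights restricted to a mask.

    ``scheme`` is one of ``rook`` (4-neighbour), ``queen`` (8-neighbour) or
    ``distance_band`` (all cells with center distance <= ``band_distance``
    metres).  ``standardization`` is ``binary`` or ``row``; ``include_self``
    adds w_ii = 1 before standardization (the Gi* convention).
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 masked cells")
    idx = np.full(mask.shape, -1, dtype=np.int64)
    idx[mask] = np.arange(n)

    rows_l: list[np.ndarray] = []
    cols_l: list[np.ndarray] = []
    if scheme in ("rook", "queen"):
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        H, Wd = mask.shape
        for dr, dc in offsets:
            # pair cell (r, c) with neighbour (r + dr, c + dc)
            shifted = np.full_like(idx, -1)
            r_lo, r_hi = max(0, -dr), H - max(0, dr)
            c_lo, c_hi = max(0, -dc), Wd - max(0, dc)
            shifted[r_lo:r_hi, c_lo:c_hi] = idx[r_lo + dr:r_hi + dr,
                                                c_lo + dc:c_hi + dc]
            valid = (idx >= 0) & (shifted >= 0)
            rows_l.append(idx[valid])
            cols_l.append(shifted[valid])
    elif scheme == "distance_band":
        if band_distance is None:
            raise ValueError("distance_band scheme requires band_distance")
        rr, cc = np.nonzero(mask)
        pts = np.column_stack([rr, cc]).astype(float) * cell_size
        tree = cKDTree(pts)
        pairs = tree.query_pairs(band_distance, output_type="ndarray")
        rows_l = [pairs[:, 0], pairs[:, 1]]
        cols_l = [pairs[:, 1], pairs[:, 0]]
    else:
        raise ValueError(f"unknown weights scheme: {scheme}")

    rows = np.concatenate(rows_l) if rows_l else np.array([], dtype=np.int64)
    cols = np.concatenate(cols_l) if cols_l else np.array([], dtype=np.int64)
    data = np.ones(rows.size)
    W = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    W.data[:] = 1.0  # collapse duplicates from the per-offset construction
    if include_self:
        W = (W + sparse.identity(n, format="csr")).tocsr()
        W.data[:] = 1.0
    if standardization == "row":
        rs = np.asarray(W.sum(axis=1)).ravel()
        scale = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
        W = sparse.diags(scale) @ W
    elif standardization != "binary":
        raise ValueError("standardization must be 'binary' or 'row'")
    return SpatialWeights(matrix=W.tocsr(), cell_index=idx, mask=mask,
                          scheme=scheme, standardization=standardization,
                          include_self=include_self,
                          band_distance=band_distance)


# ---------------------------------------------------------------------------
# Global Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    expected_I: float
    z_score: float
    p_value: float          # two-sided, analytic randomization null
    n: int
    permutations: int = 0
    p_permutation: float | None = None  # two-sided pseudo p


def morans_i(values: np.ndarray, weights: SpatialWeights,
             permutations: int = 0, seed: int | None = None) -> MoranResult:
    """Global Moran's I with analytic randomization inference.

    ``values`` is a grid (masked by the weights' mask) or a 1-D vector over
    masked cells.  With ``permutations`` > 0 a seeded permutation test adds
    a two-sided pseudo p-value (``(1 + #{|I*-E| >= |I-E|}) / (1 + nperm)``).
    """
    x = np.asarray(values, dtype=float)
    x = x[weights.mask] if x.ndim == 2 else x
    n = weights.n
    if x.size != n:
        raise ValueError("values do not match weights")
    if x.var() == 0:
        raise ValueError("zero variance: Moran's I undefined")
    W = weights.matrix
    z = x - x.mean()
    S0 = W.sum()
    cross = float(z @ (W @ z))
    I = n / S0 * cross / float(z @ z)

    # analytic moments under the randomization assumption
    E = -1.0 / (n - 1)
    Wt = W.T.tocsr()
    S1 = 0.5 * float(((W + Wt).power(2)).sum())
    row = np.asarray(W.sum(axis=1)).ravel()
    col = np.asarray(W.sum(axis=0)).ravel()
    S2 = float(np.sum((row + col) ** 2))
    b2 = n * float(np.sum(z**4)) / float(np.sum(z**2)) ** 2
    num = (n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2)
           - b2 * ((n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2))
    den = (n - 1) * (n - 2) * (n - 3) * S0**2
    var_I = num / den - E**2
    zscore = (I - E) / np.sqrt(var_I)
    p = 2 * stats.norm.sf(abs(zscore))

    p_perm = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        scale = n / S0 / float(z @ z)
        extreme = 0
        for _ in range(permutations):
            zp = rng.permutation(z)
            Ip = scale * float(zp @ (W @ zp))
            if abs(Ip - E) >= abs(I - E) - 1e-15:
                extreme += 1
        p_perm = (1 + extreme) / (1 + permutations)
    return MoranResult(I=float(I), expected_I=E, z_score=float(zscore),
                       p_value=float(p), n=n, permutations=permutations,
                       p_permutation=p_perm)


# ---------------------------------------------------------------------------
# Local Gi*
# ---------------------------------------------------------------------------

@dataclass
class GiStarField:
    z_values: np.ndarray     # grid; NaN outside mask
    class_codes: np.ndarray  # grid of CLASS_LABELS codes; 0 outside mask
    n: int

    def class_names(self) -> np.ndarray:
        out = np.empty(self.class_codes.shape, dtype=object)
        for code, name in CLASS_LABELS.items():
            out[self.class_codes == code] = name
        return out


def classify_significance(z: float | np.ndarray) -> np.ndarray | int:
    """Signed significance tier for a Gi* z-score.

    |z| >= 2.58 -> tier 3 (99%), >= 1.96 -> 2 (95%), >= 1.65 -> 1 (90%),
    else 0; sign follows the z direction (+ hotspot, - coldspot).
    """
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ValueError("z must be finite")
    tier = np.zeros(z_arr.shape, dtype=np.int64)
    a = np.abs(z_arr)
    tier += (a >= SIGNIFICANCE_THRESHOLDS[0]).astype(np.int64)
    tier += (a >= SIGNIFICANCE_THRESHOLDS[1]).astype(np.int64)
    tier += (a >= SIGNIFICANCE_THRESHOLDS[2]).astype(np.int64)
    out = np.sign(z_arr).astype(np.int64) * tier
    return int(out) if np.isscalar(z) else out


def gi_star(values: np.ndarray, weights: SpatialWeights) -> GiStarField:
    """Per-cell Getis-Ord Gi* z-scores and hotspot/coldspot classes.

    Pass self-inclusive binary weights for the standard Gi* (the default
    produced by ``build_weights(..., standardization="binary",
    include_self=True)``); row-standardized weights are accepted and give
    the same classification structure.
    """
    x = np.asarray(values, dtype=float)
    x = x[weights.mask] if x.ndim == 2 else x
    n = weights.n
    if x.size != n:
        raise ValueError("values do not match weights")
    xbar = x.mean()
    S = np.sqrt(np.mean(x**2) - xbar**2)
    if S == 0:
        raise ValueError("constant field: Gi* undefined")
    W = weights.matrix
    lag = W @ x
    Wi = np.asarray(W.sum(axis=1)).ravel()
    S1i = np.asarray(W.power(2).sum(axis=1)).ravel()
    denom_inner = (n * S1i - Wi**2) / (n - 1)
    denom = S * np.sqrt(np.maximum(denom_inner, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = np.where(denom > 0, (lag - xbar * Wi) / denom, 0.0)
    z_grid = np.full(weights.mask.shape, np.nan)
    z_grid[weights.mask] = zvals
    classes = np.zeros(weights.mask.shape, dtype=np.int64)
    classes[weights.mask] = classify_significance(zvals)
    return GiStarField(z_values=z_grid, class_codes=classes, n=n)
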