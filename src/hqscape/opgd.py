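"""Optimal-parameters geographical detector (OPGD).

The geographical detector measures how much of the spatial variance of a
response surface is explained by a categorical stratification of the same
area.  For strata h = 1..L with N_h cells, within-stratum population
variance sigma_h^2, and N cells of total population variance sigma^2:

    q = 1 - sum_h N_h * sigma_h^2 / (N * sigma^2)

q is in [0, 1]; q = 1 means the strata capture all spatial variance, q = 0
means none.  The optimal-parameters variant discretizes each continuous
factor under several classification methods and class counts and keeps the
discretization with the largest q before running the factor and interaction
detectors.  The interaction detector overlays two stratifications
(Cartesian product of strata) and classifies the joint explanatory power
against the single-factor q values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .grid import Raster

DISCRETIZATION_METHODS = (
    "equal",
    "quantile",
    "natural_breaks",
    "geometric",
    "standard_deviation",
)

INTERACTION_TYPES = (
    "nonlinear diminishing",
    "single-factor nonlinear diminishing",
    "dual-factor enhancement",
    "independent",
    "nonlinear enhancement",
)


# ---------------------------------------------------------------------------
# Factor stack
# ---------------------------------------------------------------------------

@dataclass
class FactorStack:
    """A set of co-registered explanatory layers sharing one grid and mask.

    ``layers`` maps a factor code (e.g. ``"elevation"``, ``"X5"``) to a
    :class:`~hqscape.grid.Raster`; ``categorical`` names the layers whose
    values are already strata and must not be discretized.
    """

    layers: dict[str, Raster]
    categorical: set[str] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rasters = list(self.layers.values())
        if not rasters:
            raise ValueError("factor stack needs at least one layer")
        ref = rasters[0]
        for r in rasters[1:]:
            ref.require_same_grid(r)
            if not np.array_equal(ref.mask, r.mask):
                raise ValueError("all layers must share the same mask")

    @property
    def mask(self) -> np.ndarray:
        return next(iter(self.layers.values())).mask

    @property
    def cell_size(self) -> float:
        return next(iter(self.layers.values())).cell_size

    def __contains__(self, code: str) -> bool:
        return code in self.layers

    def __getitem__(self, code: str) -> Raster:
        return self.layers[code]

    def codes(self) -> list[str]:
        return list(self.layers)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class Discretization:
    """Interior break points defining ordered classes over a continuous layer."""

    method: str
    n_classes: int
    break_points: np.ndarray  # strictly ascending interior breaks

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Class index (0-based) for each value; breaks are right-closed
        (value <= break -> lower class)."""
        return np.searchsorted(self.break_points, values, side="left")


@lru_cache(maxsize=16)
def _jenks_cut_table(data: bytes, kmax: int) -> np.ndarray:
    """Fisher–Jenks dynamic program on sorted doubles (as raw bytes).

    Returns the cut-point table for every class count up to ``kmax``:
    row c holds, for each prefix length j, the start index of the last
    class in the optimal (c+1)-class split of x[0:j].  Cached so a search
    over class counts pays for one DP only.
    """
    x = np.frombuffer(data, dtype=float)
    n = x.size
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    j_all = np.arange(n + 1)
    # cost[c, j] = minimal SSE splitting x[0:j] into c+1 classes
    cost = np.full((kmax, n + 1), np.inf)
    cut = np.zeros((kmax, n + 1), dtype=np.int64)
    with np.errstate(invalid="ignore"):
        cost[0, 1:] = cs2[1:] - cs[1:] ** 2 / j_all[1:]
    for c in range(1, kmax):
        # last class is x[i:j]; i ranges over admissible cut points
        i = np.arange(c, n)
        m = j_all[None, :] - i[:, None]
        s = cs[None, :] - cs[i, None]
        s2 = cs2[None, :] - cs2[i, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            total = cost[c - 1, i, None] + s2 - s * s / m
        total[m < 1] = np.inf
        best = np.argmin(total, axis=0)
        cost[c] = total[best, j_all]
        cut[c] = i[best]
        cost[c, : c + 1] = np.inf  # too short to hold c+1 classes
    return cut


def _fisher_jenks_breaks(sorted_vals: np.ndarray, k: int,
                         kmax: int | None = None) -> np.ndarray:
    """Exact variance-minimizing (Fisher–Jenks) partition of sorted data
    into k contiguous classes.

    Returns interior break values (k-1 of them), each the midpoint between
    the last value of one class and the first of the next.
    """
    x = np.ascontiguousarray(sorted_vals, dtype=float)
    n = x.size
    cut = _jenks_cut_table(x.tobytes(), max(k, kmax or 0))
    bounds = []
    j = n
    for c in range(k - 1, 0, -1):
        i = int(cut[c, j])
        bounds.append(i)
        j = i
    bounds = bounds[::-1]
    return np.array([(x[b - 1] + x[b]) / 2.0 for b in bounds])


def compute_breaks(values: np.ndarray, method: str, n_classes: int,
                   max_jenks_n: int = 1000,
                   jenks_kmax: int | None = None) -> np.ndarray:
    """Interior break points for one classification method.

    Natural breaks above ``max_jenks_n`` distinct values are computed on a
    deterministic quantile-spaced subsample (standard practice for the
    O(k n^2) Fisher–Jenks program on large rasters).
    """
    v = np.asarray(values, dtype=float)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    lo, hi = float(v.min()), float(v.max())
    if method == "equal":
        return np.linspace(lo, hi, n_classes + 1)[1:-1]
    if method == "quantile":
        qs = np.linspace(0, 1, n_classes + 1)[1:-1]
        breaks = np.quantile(v, qs)
    elif method == "natural_breaks":
        u = np.unique(v)
        if u.size < n_classes:
            raise ValueError("fewer distinct values than classes")
        if u.size > max_jenks_n:
            sub = np.quantile(v, np.linspace(0, 1, max_jenks_n))
            sub = np.unique(sub)
        else:
            sub = u
        breaks = _fisher_jenks_breaks(np.sort(sub), n_classes, kmax=jenks_kmax)
    elif method == "geometric":
        # widths in geometric progression on the shifted-log scale
        shifted = v - lo + 1.0
        breaks = np.exp(np.linspace(0.0, np.log(shifted.max()),
                                    n_classes + 1))[1:-1] + lo - 1.0
    elif method == "standard_deviation":
        mu, sd = float(v.mean()), float(v.std())
        if sd == 0:
            raise ValueError("zero variance; sd bands undefined")
        offsets = np.arange(1, n_classes) - (n_classes - 1) / 2.0
        breaks = mu + offsets * sd
    else:
        raise ValueError(f"unknown discretization method: {method}")
    breaks = np.unique(breaks)
    breaks = breaks[(breaks > lo) & (breaks < hi)]
    return breaks


def discretize(raster: Raster, method: str, n_classes: int,
               jenks_kmax: int | None = None) -> tuple[Discretization, np.ndarray]:
    """Classify a continuous layer into ordered strata.

    Returns the discretization and an integer class grid (nodata cells are
    left at -1).  Empty classes (possible with quantile breaks on tied data
    or sd bands outside the data range) are merged into their neighbour, so
    class labels are always contiguous and the realized class count may be
    below ``n_classes``.
    """
    vals = raster.masked().astype(float)
    distinct = np.unique(vals).size
    if method in ("quantile", "natural_breaks") and distinct < n_classes:
        raise ValueError(
            f"{method} with {n_classes} classes needs >= {n_classes} distinct values"
        )
    breaks = compute_breaks(vals, method, n_classes, jenks_kmax=jenks_kmax)
    disc = Discretization(method=method, n_classes=len(breaks) + 1,
                          break_points=breaks)
    labels = disc.assign(vals)
    # merge away empty labels -> contiguous codes
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("discretization collapsed to a single class")
    labels = np.searchsorted(present, labels)
    disc.n_classes = int(np.unique(labels).size)
    grid = np.full(raster.shape, -1, dtype=np.int64)
    grid[raster.mask] = labels
    return disc, grid


# ---------------------------------------------------------------------------
# q statistic
# ---------------------------------------------------------------------------

@dataclass
class QResult:
    factor: str
    q: float
    discretization: Discretization | None
    n_strata: int
    strata_summary: pd.DataFrame  # per-stratum count, mean, variance


def q_statistic(response: np.ndarray, strata: np.ndarray,
                factor: str = "", disc: Discretization | None = None) -> QResult:
    """Variance-decomposition q of a stratification of a response.

    ``response`` and ``strata`` are 1-D aligned arrays over masked cells
    (2-D grids are accepted and flattened with strata >= 0 as the mask).
    Population (ddof=0) variances are used throughout.
    """
    response = np.asarray(response, dtype=float)
    strata = np.asarray(strata)
    if response.ndim == 2:
        keep = strata >= 0
        response, strata = response[keep], strata[keep]
    if response.shape != strata.shape:
        raise ValueError("response and strata must align")
    n = response.size
    total_var = response.var()
    if total_var == 0:
        raise ValueError("response has zero variance; q undefined")
    codes, inv = np.unique(strata, return_inverse=True)
    if codes.size < 2:
        raise ValueError("q needs at least 2 nonempty strata")
    counts = np.bincount(inv)
    means = np.bincount(inv, weights=response) / counts
    # two-pass within-group SS (stable against cancellation)
    within_ss = np.bincount(inv, weights=(response - means[inv]) ** 2)
    variances = within_ss / counts
    q = 1.0 - float(within_ss.sum()) / (n * total_var)
    summary = pd.DataFrame(
        {"stratum": codes, "count": counts, "mean": means, "variance": variances}
    )
    return QResult(factor=factor, q=float(q), discretization=disc,
                   n_strata=int(codes.size), strata_summary=summary)


def optimize_discretization(
    response: Raster,
    factor: Raster,
    methods: tuple[str, ...] = DISCRETIZATION_METHODS,
    n_classes_range: range = range(3, 9),
    factor_code: str = "",
    min_stratum_size: int = 1,
) -> tuple[Discretization, QResult]:
    """Search (method, class count) pairs and return the argmax-q pair.

    Invalid combinations (too few distinct values, degenerate bands, strata
    smaller than ``min_stratum_size``) are skipped.  Ties break toward fewer
    classes, then method order as listed in ``methods``.
    """
    response.require_same_grid(factor)
    resp = response.masked().astype(float)
    best: tuple[float, int, int, Discretization, QResult] | None = None
    kmax = max(n_classes_range)
    for n in n_classes_range:
        for m_idx, method in enumerate(methods):
            try:
                disc, grid = discretize(factor, method, n, jenks_kmax=kmax)
                qr = q_statistic(resp, grid[factor.mask], factor=factor_code, disc=disc)
            except ValueError:
                continue
            if qr.strata_summary["count"].min() < min_stratum_size:
                continue
            key = (-qr.q, n, m_idx)
            if best is None or key < best[:3]:
                best = (*key, disc, qr)
    if best is None:
        raise ValueError("no valid (method, n_classes) combination in search grid")
    return best[3], best[4]


# ---------------------------------------------------------------------------
# Interaction detector
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    factor_a: str
    factor_b: str
    q1: float
    q2: float
    q12: float
    type: str


def classify_interaction(q1: float, q2: float, q12: float,
                         tol: float = 1e-12) -> str:
    """Dual-factor interaction taxonomy.

    Precedence: nonlinear enhancement (q12 > q1 + q2) before dual-factor
    enhancement (q12 > max); independence only on |q12 - (q1+q2)| <= tol.
    """
    s = q1 + q2
    if abs(q12 - s) <= tol:
        return "independent"
    if q12 > s:
        return "nonlinear enhancement"
    if q12 > max(q1, q2):
        return "dual-factor enhancement"
    if q12 < min(q1, q2):
        return "nonlinear diminishing"
    return "single-factor nonlinear diminishing"


def interaction_detect(response: np.ndarray, strata_a: np.ndarray,
                       strata_b: np.ndarray, factor_a: str = "A",
                       factor_b: str = "B") -> InteractionResult:
    """Overlay two stratifications and classify the joint explanatory power.

    q12 is the q statistic of the Cartesian-product strata (only nonempty
    combinations form strata; empty combinations simply do not occur in the
    product labels).
    """
    response = np.asarray(response, dtype=float).ravel()
    a = np.asarray(strata_a).ravel()
    b = np.asarray(strata_b).ravel()
    q1 = q_statistic(response, a).q
    q2 = q_statistic(response, b).q
    _, a_inv = np.unique(a, return_inverse=True)
    _, b_inv = np.unique(b, return_inverse=True)
    product = a_inv * (b_inv.max() + 1) + b_inv
    if np.unique(product).size < 2:
        raise ValueError("product stratification collapsed to one stratum")
    q12 = q_statistic(response, product).q
    return InteractionResult(
        factor_a=factor_a, factor_b=factor_b, q1=q1, q2=q2, q12=q12,
        type=classify_interaction(q1, q2, q12),
    )


# ---------------------------------------------------------------------------
# Factor report
# ---------------------------------------------------------------------------

@dataclass
class FactorReport:
    factors: pd.DataFrame          # factor, q, method, n_classes — q-descending
    interactions: pd.DataFrame     # pair, q1, q2, q12, type
    strata: dict[str, np.ndarray]  # optimal class grid per factor (over mask)
    discretizations: dict[str, Discretization | None]

    def top_interactions(self, k: int = 4) -> pd.DataFrame:
        """The k interactions with the largest joint q."""
        return self.interactions.nlargest(k, "q12").reset_index(drop=True)


def factor_report(
    response: Raster,
    stack: FactorStack,
    methods: tuple[str, ...] = DISCRETIZATION_METHODS,
    n_classes_range: range = range(3, 9),
    min_stratum_size: int = 1,
) -> FactorReport:
    """Factor detector + full pairwise interaction detector over a stack.

    Continuous layers get the optimal-parameters discretization search;
    categorical layers (e.g. land-use intensity) are used as-is.
    """
    if len(stack.layers) < 2:
        raise ValueError("factor report needs at least 2 factors")
    if 1 < min_stratum_size < 10:
        warnings.warn(
            f"minimum stratum size {min_stratum_size} < 10; per-stratum "
            "variances may be noisy", stacklevel=2,
        )
    resp = response.masked().astype(float)
    rows = []
    strata: dict[str, np.ndarray] = {}
    discs: dict[str, Discretization | None] = {}
    for code, layer in stack.layers.items():
        if code in stack.categorical:
            labels = layer.masked().astype(np.int64)
            qr = q_statistic(resp, labels, factor=code)
            discs[code] = None
        else:
            disc, qr = optimize_discretization(
                response, layer, methods, n_classes_range, factor_code=code,
                min_stratum_size=min_stratum_size)
            labels = disc.assign(layer.masked().astype(float))
            _, labels = np.unique(labels, return_inverse=True)
            discs[code] = disc
        strata[code] = labels
        rows.append({
            "factor": code,
            "q": qr.q,
            "method": discs[code].method if discs[code] else "categorical",
            "n_classes": qr.n_strata,
        })
    factors = (pd.DataFrame(rows)
               .sort_values("q", ascending=False, kind="mergesort")
               .reset_index(drop=True))
    inter_rows = []
    codes = list(stack.layers)
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            res = interaction_detect(resp, strata[a], strata[b], a, b)
            inter_rows.append({
                "factor_a": a, "factor_b": b, "q1": res.q1, "q2": res.q2,
                "q12": res.q12, "type": res.type,
            })
    interactions = pd.DataFrame(
        inter_rows,
        columns=["factor_a", "factor_b", "q1", "q2", "q12", "type"])
    return FactorReport(factors=factors, interactions=interactions,
                        strata=strata, discretizations=discs)
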