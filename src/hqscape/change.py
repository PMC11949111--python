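"""Land-use transition matrices and land-use dynamic degrees.

A transition matrix S cross-tabulates area (hectares) by class at the start
and end of a period: S_ij is the area initially of class i that is class j
at the end.  Two annualized rates summarize the matrix:

* single land-use dynamic degree of class i (signed, % per year):
      K_i = (A_i(end) - A_i(start)) / A_i(start) * (1/T) * 100
* integrated land-use dynamic degree (nonnegative, % per year):
      L_c = [ sum_i outflow_i / (2 * sum_i A_i(start)) ] * (1/T) * 100
  where outflow_i is the area leaving class i over the period.

Cells that are nodata in either year are excluded from both marginals so
row/column conservation holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CLASS_NAMES, LandUseRaster


@dataclass
class TransitionMatrix:
    """Start-to-end class areas in hectares for one period."""

    entries: pd.DataFrame  # index = start class code, columns = end class code
    period: tuple[str, str]
    cell_size: float
    n_cells: int  # jointly valid masked cells

    @property
    def classes(self) -> list[int]:
        return list(self.entries.index)

    @property
    def total_area_ha(self) -> float:
        return float(self.entries.values.sum())

    def start_areas(self) -> pd.Series:
        return self.entries.sum(axis=1)

    def end_areas(self) -> pd.Series:
        return self.entries.sum(axis=0)

    def changed_area_ha(self) -> float:
        off = self.entries.values.copy()
        np.fill_diagonal(off, 0.0)
        return float(off.sum())

    def labelled(self) -> pd.DataFrame:
        """Entries with class-name labels, for export."""
        names = [CLASS_NAMES.get(c, str(c)) for c in self.classes]
        out = self.entries.copy()
        out.index = names
        out.columns = names
        return out


def compute_transition_matrix(start: LandUseRaster,
                              end: LandUseRaster) -> TransitionMatrix:
    """Cross-tabulate class membership between two co-registered rasters.

    Entry (i, j) = count of jointly masked cells with class i at start and
    class j at end, times the cell area in hectares.
    """
    start.require_same_grid(end)
    joint = start.mask & end.mask
    if not joint.any():
        raise ValueError("empty joint mask: no cell is valid in both years")
    a = start.values[joint]
    b = end.values[joint]
    classes = sorted(set(np.unique(a)) | set(np.unique(b)))
    index = {c: k for k, c in enumerate(classes)}
    n = len(classes)
    ai = np.vectorize(index.get)(a)
    bi = np.vectorize(index.get)(b)
    counts = np.bincount(ai * n + bi, minlength=n * n).reshape(n, n)
    entries = pd.DataFrame(counts * start.cell_area_ha,
                           index=classes, columns=classes)
    return TransitionMatrix(
        entries=entries,
        period=(start.label or "start", end.label or "end"),
        cell_size=start.cell_size,
        n_cells=int(joint.sum()),
    )


@dataclass
class DynamicsReport:
    per_class: dict[int, float | None]  # % per year, signed; None if undefined
    integrated: float                   # % per year
    T: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": CLASS_NAMES.get(c, str(c)), "dynamics_pct_per_yr": v}
            for c, v in self.per_class.items()
        ]
        rows.append({"class": "integrated", "dynamics_pct_per_yr": self.integrated})
        return pd.DataFrame(rows)


def integrated_dynamics(matrix: TransitionMatrix, T: float) -> float:
    """Integrated land-use dynamic degree, % per year (always >= 0)."""
    if T <= 0:
        raise ValueError("period length T must be positive")
    total = matrix.start_areas().sum()
    if total == 0:
        raise ValueError("zero total area")
    outflow = matrix.start_areas().values - np.diag(matrix.entries.values)
    return float(outflow.sum() / (2.0 * total) / T * 100.0)


def single_class_dynamics(matrix: TransitionMatrix, class_code: int,
                          T: float) -> float | None:
    """Signed single land-use dynamic degree of one class, % per year.

    Negative means shrinkage.  Returns ``None`` (with a warning) when the
    class has zero start area, where the rate is undefined.
    """
    if T <= 0:
        raise ValueError("period length T must be positive")
    start = float(matrix.start_areas().get(class_code, 0.0))
    end = float(matrix.end_areas().get(class_code, 0.0))
    if start == 0:
        warnings.warn(
            f"class {class_code} has zero start area; dynamics undefined",
            stacklevel=2,
        )
        return None
    return (end - start) / start / T * 100.0


def dynamics_report(matrix: TransitionMatrix, T: float) -> DynamicsReport:
    per_class = {
        int(c): single_class_dynamics(matrix, int(c), T)
        for c in matrix.classes
    }
    return DynamicsReport(per_class=per_class,
                          integrated=integrated_dynamics(matrix, T), T=T)


def chord_table(matrix: TransitionMatrix) -> pd.DataFrame:
    """Long-form off-diagonal transfers (from, to, area_ha), area-descending.

    This is the data behind a chord/transfer diagram; drawing is left to
    the caller.
    """
    rows = []
    for i in matrix.classes:
        for j in matrix.classes:
            if i != j and matrix.entries.loc[i, j] > 0:
                rows.append({
                    "from": CLASS_NAMES.get(i, str(i)),
                    "to": CLASS_NAMES.get(j, str(j)),
                    "area_ha": float(matrix.entries.loc[i, j]),
                })
    out = pd.DataFrame(rows, columns=["from", "to", "area_ha"])
    return out.sort_values("area_ha", ascending=False,
                           kind="mergesort").reset_index(drop=True)
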