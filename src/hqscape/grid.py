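"""Raster grid container and plain-text raster I/O.

All analysis stages operate on rasters that share a single equal-area
projected grid: a 2-D array of values, a square cell size in metres, an
explicit nodata code and a boolean analysis mask (the reserve boundary).
Rasters are stored on disk as ESRI ASCII grids (``.asc``) with a JSON
sidecar carrying the cell size, nodata value and free-form labels, so a
whole run round-trips through plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Internal land-cover codebook. External codings (e.g. CLCD) are handled
#: by remapping into these codes before analysis.
CLASS_CODES = {
    "forest": 1,
    "cropland": 2,
    "shrub": 3,
    "grassland": 4,
    "water": 5,
    "impervious": 6,
    "wasteland": 7,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}
ALL_CLASSES = tuple(sorted(CLASS_NAMES))

M2_PER_HECTARE = 10_000.0


class GridAlignmentError(ValueError):
    """Raised when two rasters do not share shape, cell size or mask."""


@dataclass
class Raster:
    """A single-band raster on a projected equal-area grid.

    Parameters
    ----------
    values
        2-D array; integer class codes for land use, floats for covariates.
    cell_size
        Side length of a square cell, metres.
    nodata
        Value marking cells without data.
    mask
        Boolean analysis region; defaults to all cells with data.
    label
        Free-form identifier (e.g. a year, a covariate name).
    """

    values: np.ndarray
    cell_size: float
    nodata: float = -9999
    mask: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            self.mask = self.values != self.nodata
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must equal values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares."""
        return self.cell_size**2 / M2_PER_HECTARE

    def masked(self) -> np.ndarray:
        """1-D array of values over the analysis mask."""
        return self.values[self.mask]

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
        )

    def require_same_grid(self, other: "Raster") -> None:
        if not self.same_grid(other):
            raise GridAlignmentError(
                f"grid mismatch: {self.shape}@{self.cell_size} m vs "
                f"{other.shape}@{other.cell_size} m"
            )


@dataclass
class LandUseRaster(Raster):
    """Categorical land-cover raster over the 7-class codebook."""

    codebook: dict = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.int64)
        known = set(self.codebook.values())
        present = set(np.unique(self.values[self.mask]).tolist())
        unknown = present - known
        if unknown:
            raise ValueError(f"unknown class codes in masked area: {sorted(unknown)}")

    def class_areas_ha(self) -> dict[int, float]:
        """Masked area per class, hectares."""
        codes, counts = np.unique(self.values[self.mask], return_counts=True)
        return {int(c): float(n) * self.cell_area_ha for c, n in zip(codes, counts)}

    @staticmethod
    def from_codes(values, cell_size, remap: dict | None = None, **kw) -> "LandUseRaster":
        """Build a land-use raster, optionally remapping an external coding.

        ``remap`` maps external integer codes to the internal codebook.
        """
        values = np.asarray(values)
        if remap:
            out = np.full_like(values, kw.get("nodata", -9999))
            for src, dst in remap.items():
                out[values == src] = dst
            values = out
        return LandUseRaster(values=values, cell_size=cell_size, **kw)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain text; JSON sidecar for metadata)
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, raster: Raster, fmt: str = "%.10g",
                     sidecar: dict | None = None) -> None:
    """Write a raster as an ESRI ASCII grid plus a ``.json`` sidecar."""
    path = Path(path)
    nrows, ncols = raster.shape
    vals = np.where(raster.mask, raster.values, raster.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0\n")
        fh.write("yllcorner 0\n")
        fh.write(f"cellsize {raster.cell_size:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:.10g}\n")
        np.savetxt(fh, vals, fmt=fmt)
    meta = {
        "cell_size_m": raster.cell_size,
        "nodata": raster.nodata,
        "label": raster.label,
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_ascii_grid(path: str | Path, landuse: bool = False) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", -9999)
    label = ""
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        label = json.loads(side.read_text()).get("label", "")
    cls = LandUseRaster if landuse else Raster
    if landuse:
        data = data.astype(np.int64)
        nodata = int(nodata)
    return cls(values=data, cell_size=header["cellsize"], nodata=nodata, label=label)
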