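"""Grids, rasters and occurrence records.

Everything downstream (thresholding, omission rates, environmental-space
indices) works on a regular longitude/latitude grid.  This module defines the
grid geometry, continuous suitability rasters and thresholded binary maps,
reads and writes the ESRI ASCII grid text format, and handles occurrence
tables: parsing, mapping coordinates to cells, and grid-based spatial
thinning (at most one record per cell, the standard guard against
pseudoreplication in presence-only data).

Conventions
-----------
* Cell intervals are half-open ``[edge, edge + cell_size)`` in both axes, so
  a point exactly on a cell's lower-left corner belongs to that cell.
* Cell indices are 0-based with row 0 the northernmost row, matching raster
  reading order; ``origin_lon``/``origin_lat`` are the lower-left outer
  corner of the grid (ESRI convention).
* The spatial-thinning grid is anchored at (-180, -90) so that 2.5-arcminute
  cells coincide with the tiling of global bioclimatic data sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Population labels with a defined role in the calibration/evaluation split.
KNOWN_POPULATIONS = ("north", "central", "south", "other")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class AlignmentError(ValueError):
    """Raised when two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular lon/lat grid with square cells.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; row 0 is the northernmost row.
    cell_size
        Cell edge length in decimal degrees, identical in lon and lat.
    origin_lon, origin_lat
        Lower-left outer corner of the grid, decimal degrees.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_lon: float
    origin_lat: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned_with(self, other: "GridGeometry") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.cell_size, other.cell_size, rtol=0, atol=1e-12)
            and np.isclose(self.origin_lon, other.origin_lon, rtol=0, atol=1e-9)
            and np.isclose(self.origin_lat, other.origin_lat, rtol=0, atol=1e-9)
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Map a point to its (row, col) cell, or None when off the grid."""
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row_from_bottom = int(np.floor((lat - self.origin_lat) / self.cell_size))
        row = self.n_rows - 1 - row_from_bottom
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Longitude/latitude of the center of cell (row, col)."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat + (self.n_rows - row - 0.5) * self.cell_size
        return (lon, lat)


def check_aligned(*geoms: GridGeometry) -> None:
    first = geoms[0]
    for g in geoms[1:]:
        if not first.aligned_with(g):
            raise AlignmentError(f"grids are not aligned: {first} vs {g}")


@dataclass
class Raster:
    """A single-band raster: per-cell float values plus a nodata mask.

    ``values`` is an (n_rows, n_cols) float array; masked (nodata) cells hold
    NaN.  Continuous suitability outputs and integer ensemble counts are both
    carried by this class; :class:`BinaryMap` wraps the thresholded form.
    """

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match "
                f"geometry {self.geometry.shape}"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


# A continuous model output; alias kept for API clarity.
SuitabilityRaster = Raster


@dataclass
class BinaryMap:
    """A thresholded suitability raster with threshold provenance.

    ``suitable`` is boolean on non-nodata cells; the threshold value and the
    omission tolerance that produced it are always recorded, because a binary
    map is meaningless without knowing how it was cut.
    """

    geometry: GridGeometry
    suitable: np.ndarray
    nodata_mask: np.ndarray
    threshold_value: float
    omission_tolerance: float

    def __post_init__(self) -> None:
        self.suitable = np.asarray(self.suitable, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.suitable.shape != self.geometry.shape:
            raise ValueError("suitable array shape does not match geometry")
        if not 0 <= self.omission_tolerance <= 1:
            raise ValueError("omission_tolerance must lie in [0, 1]")
        # suitability is undefined on nodata cells
        self.suitable = self.suitable & ~self.nodata_mask

    def to_raster(self) -> Raster:
        vals = self.suitable.astype(float)
        vals[self.nodata_mask] = np.nan
        return Raster(self.geometry, vals)


@dataclass(frozen=True)
class OccurrenceRecord:
    longitude: float
    latitude: float
    population: str = "other"


@dataclass
class OccurrenceSet:
    """Georeferenced presence records with population labels."""

    records: list[OccurrenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_arrays(
        cls,
        lons: Sequence[float],
        lats: Sequence[float],
        populations: Sequence[str] | None = None,
    ) -> "OccurrenceSet":
        if populations is None:
            populations = ["other"] * len(lons)
        return cls(
            [
                OccurrenceRecord(float(lo), float(la), str(p))
                for lo, la, p in zip(lons, lats, populations, strict=True)
            ]
        )

    def subset(self, population: str | Iterable[str]) -> "OccurrenceSet":
        wanted = {population} if isinstance(population, str) else set(population)
        return OccurrenceSet([r for r in self.records if r.population in wanted])

    @property
    def lons(self) -> np.ndarray:
        return np.array([r.longitude for r in self.records], dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return np.array([r.latitude for r in self.records], dtype=float)

    @property
    def populations(self) -> list[str]:
        return [r.population for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "longitude": self.lons,
                "latitude": self.lats,
                "population": self.populations,
            }
        )


def read_occurrences(
    path: str | Path,
    lon_column: str = "longitude",
    lat_column: str = "latitude",
    population_column: str = "population",
) -> tuple[OccurrenceSet, list[int]]:
    """Read an occurrence CSV.

    Returns the parseable records in file order together with the 0-based row
    indices (data rows, header excluded) that were rejected.  A row is
    rejected when a coordinate does not parse or lies outside
    [-180, 180] x [-90, 90]; missing mandatory columns raise
    :class:`FormatError`.  A missing population column labels every record
    ``"other"``; extra columns are ignored.
    """
    df = pd.read_csv(path)
    for col in (lon_column, lat_column):
        if col not in df.columns:
            raise FormatError(f"mandatory column {col!r} missing from {path}")
    has_pop = population_column in df.columns

    records: list[OccurrenceRecord] = []
    rejected: list[int] = []
    lons = pd.to_numeric(df[lon_column], errors="coerce")
    lats = pd.to_numeric(df[lat_column], errors="coerce")
    for i in range(len(df)):
        lon, lat = lons.iloc[i], lats.iloc[i]
        ok = (
            np.isfinite(lon)
            and np.isfinite(lat)
            and -180 <= lon <= 180
            and -90 <= lat <= 90
        )
        if not ok:
            rejected.append(i)
            continue
        pop = str(df[population_column].iloc[i]) if has_pop else "other"
        records.append(OccurrenceRecord(float(lon), float(lat), pop))
    if rejected:
        logger.warning("%d occurrence rows rejected (rows %s)", len(rejected), rejected)
    return OccurrenceSet(records), rejected


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.to_frame().to_csv(path, index=False)


@dataclass
class CellAssignment:
    """Result of mapping occurrences onto a grid.

    ``cells[i]`` is the (row, col) of record i, or None when the record falls
    off the grid; ``usable`` flags records on valid non-nodata cells.
    Off-grid and nodata records are flagged, never silently dropped: dropped
    points change every downstream metric, so callers must see them.
    """

    cells: list[tuple[int, int] | None]
    usable: np.ndarray  # boolean per record
    off_grid: list[int]  # record indices outside the extent
    on_nodata: list[int]  # record indices on masked cells

    @property
    def usable_cells(self) -> list[tuple[int, int]]:
        return [c for c, u in zip(self.cells, self.usable) if u]

    def unique_usable_cells(self) -> list[tuple[int, int]]:
        seen: dict[tuple[int, int], None] = {}
        for c in self.usable_cells:
            seen.setdefault(c)
        return list(seen)


def assign_cells(
    occ: OccurrenceSet,
    geom: GridGeometry,
    nodata_mask: np.ndarray | None = None,
) -> CellAssignment:
    """Map each occurrence to its grid cell, flagging unusable records."""
    cells: list[tuple[int, int] | None] = []
    off_grid: list[int] = []
    on_nodata: list[int] = []
    usable = np.zeros(len(occ), dtype=bool)
    for i, rec in enumerate(occ):
        cell = geom.cell_of(rec.longitude, rec.latitude)
        cells.append(cell)
        if cell is None:
            off_grid.append(i)
        elif nodata_mask is not None and nodata_mask[cell]:
            on_nodata.append(i)
        else:
            usable[i] = True
    if off_grid or on_nodata:
        logger.warning(
            "flagged occurrences: %d off-grid, %d on nodata cells",
            len(off_grid),
            len(on_nodata),
        )
    return CellAssignment(cells, usable, off_grid, on_nodata)


#: Anchor of the spatial-thinning grid (matches global bioclim tiling).
THINNING_ANCHOR = (-180.0, -90.0)

#: 2.5 arcminutes in decimal degrees, the standard bioclim-tile resolution.
CELL_2P5_ARCMIN = 2.5 / 60.0


def thin_to_grid(occ: OccurrenceSet, cell_size: float = CELL_2P5_ARCMIN) -> OccurrenceSet:
    """Spatially thin occurrences to at most one record per grid cell.

    The thinning grid is anchored at (-180, -90); within each occupied cell
    the FIRST record in input order is kept, making the operation
    deterministic and idempotent.  Population labels are preserved.
    """
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    anchor_lon, anchor_lat = THINNING_ANCHOR
    seen: set[tuple[int, int]] = set()
    kept: list[OccurrenceRecord] = []
    for rec in occ:
        key = (
            int(np.floor((rec.longitude - anchor_lon) / cell_size)),
            int(np.floor((rec.latitude - anchor_lat) / cell_size)),
        )
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return OccurrenceSet(kept)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_ASCII_NODATA = -9999.0


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc).

    Supports ``xllcorner``/``yllcorner`` (and the cell-center variants,
    shifted back by half a cell).  Rejects grids with separate dx/dy: the
    evaluation machinery assumes square cells.
    """
    path = Path(path)
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value", "dx", "dy",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    if "dx" in header or "dy" in header:
        raise FormatError(f"{path}: non-uniform cell sizes (dx/dy) are unsupported")
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing required header field {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cs = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cs / 2
    else:
        raise FormatError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cs / 2
    else:
        raise FormatError(f"{path}: missing yllcorner/yllcenter")

    values = np.loadtxt(path, skiprows=n_header, ndmin=2)
    if values.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: data block shape {values.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    if "nodata_value" in header:
        values = np.where(values == header["nodata_value"], np.nan, values)
    geom = GridGeometry(nrows, ncols, cs, xll, yll)
    return Raster(geom, values)


def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = _ASCII_NODATA) -> None:
    """Write an ESRI ASCII grid with full float64 precision (%.17g).

    Finite values survive a write/read round trip bit-for-bit.
    """
    g = raster.geometry
    values = np.where(np.isfinite(raster.values), raster.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin_lon:.12g}\n")
        fh.write(f"yllcorner {g.origin_lat:.12g}\n")
        fh.write(f"cellsize {g.cell_size:.17g}\n")
        fh.write(f"NODATA_value {nodata:.17g}\n")
        np.savetxt(fh, values, fmt="%.17g")


def read_raster(path: str | Path) -> Raster:
    """Read a suitability raster (ESRI ASCII grid)."""
    return read_ascii_grid(path)


def write_raster(raster: Raster, path: str | Path) -> None:
    write_ascii_grid(raster, path)


def read_binary(
    path: str | Path,
    threshold_value: float = float("nan"),
    omission_tolerance: float = 0.0,
) -> BinaryMap:
    """Read a 0/1 integer raster as a binary map.

    The text format cannot carry threshold provenance, so callers may supply
    it; it defaults to unknown (NaN threshold, tolerance 0).
    """
    r = read_ascii_grid(path)
    finite = np.isfinite(r.values)
    vals = np.where(finite, r.values, 0.0)
    if not np.all(np.isin(vals[finite], (0.0, 1.0))):
        raise FormatError(f"{path}: binary map contains values other than 0/1")
    return BinaryMap(
        geometry=r.geometry,
        suitable=vals == 1.0,
        nodata_mask=~finite,
        threshold_value=threshold_value,
        omission_tolerance=omission_tolerance,
    )


def write_binary(bin_map: BinaryMap, path: str | Path) -> None:
    write_ascii_grid(bin_map.to_raster(), path)


__all__ = [
    "GridGeometry",
    "Raster",
    "SuitabilityRaster",
    "BinaryMap",
    "OccurrenceRecord",
    "OccurrenceSet",
    "CellAssignment",
    "FormatError",
    "AlignmentError",
    "check_aligned",
    "read_occurrences",
    "write_occurrences",
    "assign_cells",
    "thin_to_grid",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_raster",
    "write_raster",
    "read_binary",
    "write_binary",
    "CELL_2P5_ARCMIN",
]
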