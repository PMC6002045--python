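"""Gridded climate layers: data model, I/O, stack alignment, cell areas.

All grids live on a plain geographic latitude/longitude lattice (degrees,
WGS84 assumed, square cells). Cells are addressed row-major from the
upper-left corner; a point maps to the cell containing it under half-open
intervals ``[edge, edge + cell_size)``. There is deliberately no resampling
or reprojection: layers entering one stack must already share their
georeference, and a mismatch is an error rather than an implicit resample.

Two on-disk formats are supported: ESRI ASCII grid (text) and single-band
GeoTIFF with the standard georeference tags (ModelPixelScale, ModelTiepoint,
GDAL_NODATA), read and written through :mod:`tifffile`.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

EARTH_RADIUS_KM = 6371.0

#: default nodata sentinel written to files
DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridFormatError(ValueError):
    """A raster file does not satisfy the supported-grid contract."""


class AlignmentError(ValueError):
    """Grids with incompatible georeference were combined."""


@dataclass
class ClimateGrid:
    """One named raster layer.

    Parameters
    ----------
    name : str
        Variable label, e.g. ``"bio1"``.
    values : ndarray
        2-D float array. Entries under the mask are ignored.
    mask : ndarray of bool
        True where the cell carries no data. Same shape as ``values``.
    origin : (float, float)
        (lon, lat) of the grid's upper-left *corner*, degrees.
    cell_size : float
        Degrees per cell, square cells.
    units : str
        Free-text units (``"°C"``, ``"mm"``, ``"index"``).
    """

    name: str
    values: np.ndarray
    mask: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise GridFormatError(f"values must be 2-D, got shape {self.values.shape}")
        if self.mask.shape != self.values.shape:
            raise GridFormatError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if not self.cell_size > 0:
            raise GridFormatError(f"cell_size must be > 0, got {self.cell_size}")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise GridFormatError(f"grid {self.name!r} has non-finite unmasked values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def lat_center(self, row: int | np.ndarray) -> float | np.ndarray:
        """Latitude of the centre of the cells in ``row`` (rows count down)."""
        return self.origin[1] - (np.asarray(row) + 0.5) * self.cell_size

    def lon_center(self, col: int | np.ndarray) -> float | np.ndarray:
        return self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of all cell centres, each of grid shape."""
        rows, cols = np.indices(self.shape)
        return np.asarray(self.lon_center(cols)), np.asarray(self.lat_center(rows))

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; half-open intervals."""
        col = int(math.floor((lon - self.origin[0]) / self.cell_size))
        row = int(math.floor((self.origin[1] - lat) / self.cell_size))
        if not (0 <= row < self.shape[0] and 0 <= col < self.shape[1]):
            raise ValueError(f"point ({lon}, {lat}) falls outside the grid")
        return row, col

    def same_georeference(self, other: "ClimateGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def with_values(self, values: np.ndarray, name: str | None = None,
                    units: str | None = None) -> "ClimateGrid":
        """New grid on the same lattice with different cell values."""
        return replace(
            self,
            name=self.name if name is None else name,
            values=np.asarray(values, dtype=float),
            mask=self.mask.copy(),
            units=self.units if units is None else units,
        )


@dataclass
class GridStack:
    """Aligned named layers for one time slice."""

    layers: dict[str, ClimateGrid]
    slice_label: str = "current"

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def mask(self) -> np.ndarray:
        return next(iter(self.layers.values())).mask

    @property
    def template(self) -> ClimateGrid:
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> ClimateGrid:
        return self.layers[name]

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> dict[str, np.ndarray]:
        """Per-variable vectors of layer values at the given cells."""
        return {name: g.values[rows, cols] for name, g in self.layers.items()}

    def unmasked_values(self) -> dict[str, np.ndarray]:
        keep = ~self.mask
        return {name: g.values[keep] for name, g in self.layers.items()}

    def values_at_points(self, points: np.ndarray) -> dict[str, np.ndarray]:
        """Per-variable vectors at the cells containing (lon, lat) points.

        Points on masked cells or outside the grid raise ValueError.
        """
        template = self.template
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        rows = np.empty(len(pts), dtype=int)
        cols = np.empty(len(pts), dtype=int)
        for i, (lon, lat) in enumerate(pts):
            rows[i], cols[i] = template.cell_of(lon, lat)
        if self.mask[rows, cols].any():
            bad = int(self.mask[rows, cols].sum())
            raise ValueError(f"{bad} point(s) fall on masked cells")
        return self.values_at_cells(rows, cols)


def align_stack(grids: list[ClimateGrid], slice_label: str = "current") -> GridStack:
    """Assemble aligned grids into a stack whose shared mask is the union.

    Mismatched shape, origin, or cell size raises :class:`AlignmentError`;
    nothing is ever resampled.
    """
    if not grids:
        raise ValueError("align_stack requires at least one grid")
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_georeference(g):
            raise AlignmentError(
                f"grid {g.name!r} (shape {g.shape}, origin {g.origin}, "
                f"cell_size {g.cell_size}) does not align with {ref.name!r} "
                f"(shape {ref.shape}, origin {ref.origin}, cell_size {ref.cell_size})"
            )
    shared = np.zeros(ref.shape, dtype=bool)
    for g in grids:
        shared |= g.mask
    layers = {}
    for g in grids:
        layers[g.name] = replace(g, mask=shared.copy())
    return GridStack(layers=layers, slice_label=slice_label)


def cell_area_km2(grid: ClimateGrid, row_index: int) -> float:
    """Spherical-Earth area of one cell in the given row, km².

    area = (cell_size · π/180 · R)² · cos(latitude of row centre), R = 6371 km.
    Constant within a row; a 2.5-arc-minute cell on the equator is ≈ 21.47 km².
    """
    if not (0 <= row_index < grid.shape[0]):
        raise IndexError(f"row {row_index} out of range for {grid.shape[0]} rows")
    lat = float(grid.lat_center(row_index))
    side = grid.cell_size * math.pi / 180.0 * EARTH_RADIUS_KM
    return side * side * max(math.cos(math.radians(lat)), 0.0)


def row_areas_km2(grid: ClimateGrid) -> np.ndarray:
    """cell_area_km2 for every row, as a vector."""
    return np.array([cell_area_km2(grid, r) for r in range(grid.shape[0])])


# ---------------------------------------------------------------------------
# I/O


def read_grid(path: str, format: str | None = None, name: str | None = None,
              units: str = "") -> ClimateGrid:
    """Read a raster layer from ESRI ASCII (.asc) or GeoTIFF (.tif/.tiff).

    ``format`` is ``"ascii"`` or ``"geotiff"``; inferred from the extension
    when omitted. The layer name defaults to the file stem.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".asc": "ascii", ".txt": "ascii", ".tif": "geotiff",
                  ".tiff": "geotiff"}.get(ext)
        if format is None:
            raise GridFormatError(f"cannot infer format from extension of {path!r}")
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    if format == "ascii":
        return _read_ascii(path, name, units)
    if format == "geotiff":
        return _read_geotiff(path, name, units)
    raise GridFormatError(f"unknown format {format!r} (expected 'ascii' or 'geotiff')")


def write_grid(grid: ClimateGrid, path: str, format: str | None = None,
               nodata: float = DEFAULT_NODATA) -> None:
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "ascii" if ext in (".asc", ".txt") else "geotiff"
    if format == "ascii":
        _write_ascii(grid, path, nodata)
    elif format == "geotiff":
        _write_geotiff(grid, path, nodata)
    else:
        raise GridFormatError(f"unknown format {format!r}")


def _read_ascii(path: str, name: str, units: str) -> ClimateGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                   "yllcenter", "cellsize", "dx", "dy", "nodata_value"}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in header_keys and len(parts) == 2:
                header[parts[0].lower()] = float(parts[1])
            else:
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise GridFormatError(f"{path}: non-numeric data line: {line!r}") from exc
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header and not (key == "cellsize" and "dx" in header):
            raise GridFormatError(f"{path}: missing required header field {key!r}")
    if "cellsize" in header:
        cell = header["cellsize"]
    else:
        if not math.isclose(header["dx"], header["dy"]):
            raise GridFormatError(f"{path}: non-square cells dx={header['dx']} dy={header['dy']}")
        cell = header["dx"]
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.array([v for row in rows for v in row], dtype=float)
    if values.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} values, found {values.size}")
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    mask = np.zeros_like(values, dtype=bool) if nodata is None else values == nodata
    if "xllcorner" in header:
        xll = header["xllcorner"]
    else:
        xll = header["xllcenter"] - cell / 2.0
    if "yllcorner" in header:
        yll = header["yllcorner"]
    else:
        yll = header["yllcenter"] - cell / 2.0
    origin = (xll, yll + nrows * cell)
    vals = values.copy()
    vals[mask] = 0.0
    return ClimateGrid(name=name, values=vals, mask=mask, origin=origin,
                       cell_size=cell, units=units)


def _write_ascii(grid: ClimateGrid, path: str, nodata: float) -> None:
    nrows, ncols = grid.shape
    yll = grid.origin[1] - nrows * grid.cell_size
    out = grid.values.copy()
    out[grid.mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def _read_geotiff(path: str, name: str, units: str) -> ClimateGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise GridFormatError(f"{path}: expected single-band raster, got shape {values.shape}")
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise GridFormatError(f"{path}: missing georeference tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise GridFormatError(f"{path}: non-square cells sx={sx} sy={sy}")
        tp = tags[_TAG_MODEL_TIEPOINT].value
        # tie point maps raster (i, j) to model (x, y); we require (0, 0)
        origin = (tp[3] - tp[0] * sx, tp[4] + tp[1] * sy)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    mask = np.zeros_like(values, dtype=bool)
    if nodata is not None:
        mask = values == nodata
    mask |= ~np.isfinite(values)
    vals = values.copy()
    vals[mask] = 0.0
    return ClimateGrid(name=name, values=vals, mask=mask, origin=origin,
                       cell_size=float(sx), units=units)


def _write_geotiff(grid: ClimateGrid, path: str, nodata: float) -> None:
    out = grid.values.copy()
    out[grid.mask] = nodata
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{nodata:.10g}"),
    ]
    tifffile.imwrite(path, out, extratags=extratags)
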