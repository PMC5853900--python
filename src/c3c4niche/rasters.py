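"""Regular latitude/longitude raster grids and their file formats.

Registration convention, used everywhere in the package: the grid origin is
the north-west corner; row 0 is the northernmost row; a cell with west edge
``w`` and south edge ``s`` owns the half-open rectangle
``[w, w + size) x (s, s + size]`` (west and north edges included, east and
south excluded).  One bit-exact ownership rule keeps point extraction, the
land-mask test and the synthetic sampler mutually consistent.

Formats: ESRI ASCII grid (plain text) and single- or multi-band GeoTIFF.
GeoTIFF georeferencing is carried by the ModelPixelScale / ModelTiepoint /
GDAL_NODATA tags, written and read through :mod:`tifffile`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat/lon grid anchored at its north-west corner."""

    west: float
    north: float
    cell_size: float
    nrows: int
    ncols: int
    nodata: float = -9999.0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid must have positive dimensions")
        if not (-180.0 <= self.west and self.east <= 180.0):
            raise ValueError("longitude extent outside [-180, 180]")
        if not (self.south >= -90.0 and self.north <= 90.0):
            raise ValueError("latitude extent outside [-90, 90]")

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cell_size

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.cell_size

    def index_of(self, lat: float, lon: float) -> tuple[int, int] | None:
        """(row, col) of the cell owning the point, or None if off-extent."""
        if not (math.isfinite(lat) and math.isfinite(lon)):
            return None
        row = math.floor((self.north - lat) / self.cell_size)
        col = math.floor((lon - self.west) / self.cell_size)
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return int(row), int(col)
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lat = self.north - (row + 0.5) * self.cell_size
        lon = self.west + (col + 0.5) * self.cell_size
        return lat, lon

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) arrays of shape (nrows, ncols)."""
        lats = self.north - (np.arange(self.nrows) + 0.5) * self.cell_size
        lons = self.west + (np.arange(self.ncols) + 0.5) * self.cell_size
        return np.meshgrid(lats, lons, indexing="ij")


@dataclass
class EnvGrid:
    """One environmental variable on a grid; nodata cells carry the sentinel."""

    spec: GridSpec
    variable: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError(
                f"grid shape {self.values.shape} does not match spec "
                f"({self.spec.nrows}, {self.spec.ncols})"
            )

    def value_at(self, lat: float, lon: float) -> float:
        """Cell value at a point; NaN for off-extent or nodata."""
        idx = self.spec.index_of(lat, lon)
        if idx is None:
            return math.nan
        v = self.values[idx]
        if v == self.spec.nodata or not math.isfinite(v):
            return math.nan
        return float(v)

    def masked(self) -> np.ndarray:
        """Values with the nodata sentinel replaced by NaN."""
        out = self.values.copy()
        out[out == self.spec.nodata] = np.nan
        return out


@dataclass
class LandMask:
    """Boolean land/sea grid; True = land."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError("mask shape does not match spec")

    def is_land(self, lat: float, lon: float) -> bool:
        idx = self.spec.index_of(lat, lon)
        return bool(self.values[idx]) if idx is not None else False


MONTHS = 12


@dataclass
class MonthlyStack:
    """Twelve monthly layers (January first) of one variable on a shared grid."""

    spec: GridSpec
    variable: str
    layers: np.ndarray  # (12, nrows, ncols)

    def __post_init__(self):
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.shape != (MONTHS, self.spec.nrows, self.spec.ncols):
            raise ValueError("monthly stack must hold exactly 12 aligned layers")

    def month(self, m: int) -> EnvGrid:
        """EnvGrid for month ``m`` (0-based, 0 = January)."""
        return EnvGrid(self.spec, f"{self.variable}_m{m + 1:02d}", self.layers[m])


def check_same_spec(*specs: GridSpec) -> GridSpec:
    first = specs[0]
    for s in specs[1:]:
        if s != first:
            raise ValueError("raster layers are not registered on the same grid")
    return first


# ---------------------------------------------------------------------------
# ESRI ASCII grid

def write_ascii_grid(grid: EnvGrid, path) -> None:
    spec = grid.spec
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {spec.west!r}\n"
        f"yllcorner {spec.south!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"nodata_value {spec.nodata!r}\n"
    )
    vals = np.where(np.isfinite(grid.values), grid.values, spec.nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path, variable: str | None = None) -> EnvGrid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header field {key}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    spec = GridSpec(
        west=header["xllcorner"],
        north=header["yllcorner"] + nrows * header["cellsize"],
        cell_size=header["cellsize"],
        nrows=nrows,
        ncols=ncols,
        nodata=header.get("nodata_value", -9999.0),
    )
    return EnvGrid(spec, variable or path.stem, values)


# ---------------------------------------------------------------------------
# GeoTIFF (georeferencing tags handled directly)

def _geo_extratags(spec: GridSpec):
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.west, spec.north, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(spec.nodata)),
    ]


def write_geotiff(grid: EnvGrid | MonthlyStack, path) -> None:
    """Write a single-band (EnvGrid) or 12-band (MonthlyStack) GeoTIFF."""
    spec = grid.spec
    if isinstance(grid, MonthlyStack):
        data = grid.layers
    else:
        data = grid.values
    data = np.where(np.isfinite(data), data, spec.nodata).astype("float64")
    tifffile.imwrite(path, data, extratags=_geo_extratags(spec))


def _spec_from_tif(tif: tifffile.TiffFile, shape) -> GridSpec:
    tags = tif.pages[0].tags
    try:
        sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
    except KeyError as e:
        raise ValueError("GeoTIFF lacks ModelPixelScale/ModelTiepoint tags") from e
    if abs(sx - sy) > 1e-12:
        raise ValueError("only square-cell GeoTIFFs are supported")
    nodata = -9999.0
    if _TAG_GDAL_NODATA in tags:
        nodata = float(tags[_TAG_GDAL_NODATA].value)
    nrows, ncols = shape[-2], shape[-1]
    return GridSpec(
        west=float(tie[3]), north=float(tie[4]), cell_size=float(sx),
        nrows=nrows, ncols=ncols, nodata=nodata,
    )


def read_geotiff(path, variable: str | None = None):
    """Read a GeoTIFF; one band -> EnvGrid, twelve bands -> MonthlyStack."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        spec = _spec_from_tif(tif, data.shape)
    name = variable or path.stem
    if data.ndim == 2:
        return EnvGrid(spec, name, data)
    if data.ndim == 3 and data.shape[0] == MONTHS:
        return MonthlyStack(spec, name, data)
    raise ValueError(f"unsupported GeoTIFF band layout: shape {data.shape}")


def read_raster(path, variable: str | None = None):
    """Dispatch on extension: .tif/.tiff -> GeoTIFF, .asc/.grd -> ASCII grid."""
    suffix = Path(path).suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return read_geotiff(path, variable)
    if suffix in {".asc", ".grd", ".txt"}:
        return read_ascii_grid(path, variable)
    raise ValueError(f"unrecognized raster format: {path}")


def stack_from_files(paths: Sequence, variable: str) -> MonthlyStack:
    """Build a MonthlyStack from 12 single-band files in January-first order."""
    if len(paths) != MONTHS:
        raise ValueError("a monthly stack needs exactly 12 files")
    grids = [read_raster(p) for p in paths]
    spec = check_same_spec(*[g.spec for g in grids])
    return MonthlyStack(spec, variable, np.stack([g.values for g in grids]))
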