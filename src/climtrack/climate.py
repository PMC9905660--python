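"""Climate rasters, breeding-range polygons, and the species temperature index.

The species temperature index (STI) is a one-number climate envelope: the
long-term mean June temperature over a species' breeding range.  It is
computed here as a zonal statistic — the (optionally cos-latitude-weighted)
mean of the climate-grid cells whose *centers* fall inside the range
polygon.

Rasters are regular north-up lon/lat grids, matching the native WorldClim
layout; no reprojection is performed.  Two on-disk formats are supported:
single-band GeoTIFF (georeferencing read from the ModelPixelScale /
ModelTiepoint tags) and ESRI ASCII grid (plain text).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .errors import (
    EmptyOverlapError,
    FormatError,
    SchemaError,
    UnsupportedFormatError,
    ValidationError,
)

# GeoTIFF tag ids used for georeferencing.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_TAG_GEO_KEYS = 34735


@dataclass(frozen=True)
class GridGeoreference:
    """North-up affine georeference: grid (row, col) -> (lon, lat) degrees.

    ``west``/``north`` are the outer edges of the top-left cell; ``dx`` and
    ``dy`` are positive cell sizes (rows advance southward).
    """

    west: float
    north: float
    dx: float
    dy: float

    def __post_init__(self):
        if not (self.dx > 0 and self.dy > 0):
            raise ValidationError("cell sizes must be positive")

    def lon_centers(self, ncols: int) -> np.ndarray:
        return self.west + (np.arange(ncols) + 0.5) * self.dx

    def lat_centers(self, nrows: int) -> np.ndarray:
        return self.north - (np.arange(nrows) + 0.5) * self.dy

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.west + (col + 0.5) * self.dx, self.north - (row + 0.5) * self.dy)


@dataclass
class ClimateRaster:
    """A single-band temperature grid (degrees C) on a lon/lat graticule."""

    values: np.ndarray
    geo: GridGeoreference
    nodata: float | None = None
    crs_id: str = "EPSG:4326"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValidationError("raster values must be a non-empty 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """True where the cell holds usable data (finite and not nodata)."""
        mask = np.isfinite(self.values)
        if self.nodata is not None:
            mask &= self.values != self.nodata
        return mask

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell-center coordinates, each shaped like ``values``."""
        nrows, ncols = self.values.shape
        lon = np.broadcast_to(self.geo.lon_centers(ncols), (nrows, ncols))
        lat = np.broadcast_to(self.geo.lat_centers(nrows)[:, None], (nrows, ncols))
        return lon, lat


@dataclass(frozen=True)
class RangePolygon:
    """A species' breeding range as a (multi)polygon in lon/lat degrees."""

    species: str
    geometry: BaseGeometry
    source_tag: str = ""

    def __post_init__(self):
        if self.geometry.is_empty:
            raise ValidationError(f"range geometry for {self.species!r} is empty")
        minx, _, maxx, _ = self.geometry.bounds
        if maxx - minx > 180.0:
            raise ValidationError(
                f"range for {self.species!r} spans more than 180 deg of longitude; "
                "antimeridian-crossing ranges must be pre-split at +/-180"
            )


@dataclass(frozen=True)
class SpeciesTemperatureIndex:
    """Zonal-mean climate statistic for one species."""

    species: str
    sti_degc: float
    n_cells: int
    weighted: bool


# ---------------------------------------------------------------------------
# Raster I/O


def read_climate_raster(path: str | Path) -> ClimateRaster:
    """Read a single-band GeoTIFF (.tif/.tiff) or ESRI ASCII grid (.asc)."""
    path = Path(path)
    if path.suffix.lower() in {".asc", ".txt"}:
        return _read_ascii_grid(path)
    return _read_geotiff(path)


def _read_geotiff(path: Path) -> ClimateRaster:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            if len(tif.pages) > 1 or page.samplesperpixel > 1:
                raise UnsupportedFormatError(f"{path} is not a single-band raster")
            values = page.asarray()
            tags = {
                code: page.tags[code].value
                for code in (_TAG_MODEL_PIXEL_SCALE, _TAG_MODEL_TIEPOINT, _TAG_GDAL_NODATA, _TAG_GEO_KEYS)
                if code in page.tags
            }
    except FileNotFoundError:
        raise
    except tifffile.TiffFileError as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    except UnsupportedFormatError:
        raise
    except Exception as exc:  # truncated/corrupt payloads surface variously
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if values.ndim != 2:
        raise UnsupportedFormatError(f"{path} has {values.ndim} dimensions; expected 2")

    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise FormatError(f"{path} lacks GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
    tp = tags[_TAG_MODEL_TIEPOINT]
    # tiepoint: raster (i, j, k) -> model (x, y, z); anchor at the top-left corner
    i, j, _, x, y, _ = tp[:6]
    west = x - i * sx
    north = y + j * sy

    nodata = None
    if _TAG_GDAL_NODATA in tags:
        nodata = float(tags[_TAG_GDAL_NODATA])

    crs_id = "EPSG:4326"
    if _TAG_GEO_KEYS not in tags:
        warnings.warn(f"{path} has no CRS metadata; assuming geographic lon/lat", stacklevel=2)
    return ClimateRaster(values=values, geo=GridGeoreference(west, north, sx, sy), nodata=nodata, crs_id=crs_id)


def write_climate_raster(raster: ClimateRaster, path: str | Path) -> Path:
    """Write GeoTIFF (.tif/.tiff) or ESRI ASCII grid (.asc), by extension."""
    path = Path(path)
    if path.suffix.lower() in {".asc", ".txt"}:
        return _write_ascii_grid(raster, path)
    geo = raster.geo
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (geo.dx, geo.dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geo.west, geo.north, 0.0)),
        # minimal GeoTIFF key directory declaring geographic WGS84
        (_TAG_GEO_KEYS, "H", 16, (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 2, 2048, 0, 1, 4326)),
    ]
    if raster.nodata is not None:
        nd = repr(raster.nodata)
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd), nd))
    tifffile.imwrite(path, raster.values.astype(np.float64), extratags=extratags)
    return path


def _read_ascii_grid(path: Path) -> ClimateRaster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    try:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"could not parse ASCII grid {path}: {exc}") from exc
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= header.keys():
        raise FormatError(f"{path} is missing ASCII-grid header fields {required - header.keys()}")
    values = np.array(rows, dtype=float)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise FormatError(f"{path}: data shape {values.shape} does not match header ({nrows}, {ncols})")
    cell = header["cellsize"]
    geo = GridGeoreference(west=header["xllcorner"], north=header["yllcorner"] + nrows * cell, dx=cell, dy=cell)
    return ClimateRaster(values=values, geo=geo, nodata=header.get("nodata_value"))


def _write_ascii_grid(raster: ClimateRaster, path: Path) -> Path:
    if not math.isclose(raster.geo.dx, raster.geo.dy):
        raise UnsupportedFormatError("ASCII grids require square cells")
    nrows, ncols = raster.shape
    nodata = raster.nodata if raster.nodata is not None else -9999.0
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.geo.west!r}\n")
        fh.write(f"yllcorner {raster.geo.north - nrows * raster.geo.dy!r}\n")
        fh.write(f"cellsize {raster.geo.dx!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        out = np.where(np.isfinite(raster.values), raster.values, nodata)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# Vector I/O


def read_range_polygons(path: str | Path, species_key: str = "species") -> list[RangePolygon]:
    """Read per-species breeding-range polygons from a GeoJSON FeatureCollection.

    Each feature needs a ``species`` property (configurable key); invalid
    rings are repaired with :func:`shapely.validation.make_valid`.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"could not parse GeoJSON {path}: {exc}") from exc
    features = doc.get("features")
    if doc.get("type") != "FeatureCollection" or features is None:
        raise FormatError(f"{path} is not a GeoJSON FeatureCollection")
    out = []
    for k, feat in enumerate(features):
        props = feat.get("properties") or {}
        if species_key not in props:
            raise SchemaError(f"feature {k} in {path} lacks the {species_key!r} property")
        geom = geom_shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
            if geom.is_empty or not geom.is_valid:
                raise ValidationError(f"geometry for {props[species_key]!r} could not be repaired")
        out.append(RangePolygon(species=str(props[species_key]), geometry=geom, source_tag=str(path)))
    return out


def write_range_polygons(ranges: list[RangePolygon], path: str | Path) -> Path:
    """Write range polygons as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"species": r.species, "source": r.source_tag},
            "geometry": geom_mapping(r.geometry),
        }
        for r in ranges
    ]
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


# ---------------------------------------------------------------------------
# Zonal statistics


def cell_inclusion_mask(raster: ClimateRaster, polygon: RangePolygon) -> np.ndarray:
    """Boolean grid of cells whose center lies in (or on) the range polygon.

    Cells carrying the nodata sentinel are never included.  Raises
    :class:`EmptyOverlapError` when no cell qualifies.
    """
    lon, lat = raster.center_grids()
    inside = shapely.intersects_xy(polygon.geometry, lon.ravel(), lat.ravel()).reshape(raster.shape)
    mask = inside & raster.valid_mask()
    if not mask.any():
        raise EmptyOverlapError(polygon.species)
    return mask


def compute_sti(
    raster: ClimateRaster, polygon: RangePolygon, area_weighted: bool = True
) -> SpeciesTemperatureIndex:
    """Mean June temperature over a species' breeding range.

    ``area_weighted=True`` weights each included cell by cos(latitude of its
    center), compensating for the poleward shrinkage of graticule cells;
    unweighted mode is the plain arithmetic mean.
    """
    mask = cell_inclusion_mask(raster, polygon)
    values = raster.values[mask]
    if area_weighted:
        _, lat = raster.center_grids()
        weights = np.cos(np.radians(lat[mask]))
        sti = float(np.sum(weights * values) / np.sum(weights))
    else:
        sti = float(np.mean(values))
    return SpeciesTemperatureIndex(
        species=polygon.species, sti_degc=sti, n_cells=int(mask.sum()), weighted=area_weighted
    )
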