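"""Georeferenced raster and sample-table I/O.

Rasters are single-band, north-up, geographic (WGS84 lon/lat) GeoTIFFs.
Georeferencing is carried by the standard GeoTIFF tags (ModelPixelScale +
ModelTiepoint, GDAL_NODATA for the missing-value sentinel) written and
read through :mod:`tifffile`.  Reprojection and resampling are out of
scope: grids must already be mutually aligned, and any CRS other than
geographic WGS84 is rejected.

Pixel convention: a pixel's footprint is half-open, [left, right) in
longitude and (bottom, top] in latitude, so a point on a shared edge
belongs to exactly one pixel.  Missing pixels are NaN in memory and the
NoData sentinel (default -9999) on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

DEFAULT_NODATA = -9999.0
WGS84 = "EPSG:4326"

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKey directory: geographic model, pixel-is-area, EPSG:4326
_GEO_KEYS_WGS84 = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


class AlignmentError(ValueError):
    """Raster grids do not share transform/shape/CRS."""


class ExtentError(ValueError):
    """A bounding box or point falls outside the raster extent."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeferencing: map = origin + pixel * scale."""

    west: float   # longitude of the left edge of column 0
    north: float  # latitude of the top edge of row 0
    px: float     # pixel width  (degrees, > 0)
    py: float     # pixel height (degrees, > 0; rows go southward)

    def __post_init__(self):
        if self.px <= 0 or self.py <= 0:
            raise ValueError("pixel size must be positive")

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.west + (col + 0.5) * self.px,
            self.north - (row + 0.5) * self.py,
        )

    def index(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the pixel whose half-open footprint contains the point."""
        col = math.floor((lon - self.west) / self.px)
        row = math.floor((self.north - lat) / self.py)
        return row, col

    def shift(self, row0: int, col0: int) -> "GridTransform":
        return replace(
            self,
            west=self.west + col0 * self.px,
            north=self.north - row0 * self.py,
        )


@dataclass(frozen=True)
class BoundingBox:
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("degenerate bounding box")


#: Clip extent used for the subcontinental prediction maps.
INDIA_BBOX = BoundingBox(lon_min=68.1, lon_max=97.4, lat_min=6.74, lat_max=35.7)


@dataclass
class RasterGrid:
    """One band of georeferenced values; NaN marks NoData in memory."""

    values: np.ndarray
    transform: GridTransform
    crs: str = WGS84
    band_name: str = ""
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.crs != WGS84:
            raise ValueError(f"only geographic WGS84 is supported, got {self.crs!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> BoundingBox:
        nrow, ncol = self.shape
        t = self.transform
        return BoundingBox(
            lon_min=t.west,
            lon_max=t.west + ncol * t.px,
            lat_min=t.north - nrow * t.py,
            lat_max=t.north,
        )

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs == other.crs
        )


def write_raster(grid: RasterGrid, path) -> Path:
    """Write a single-band float32 GeoTIFF with geo-tags and NoData."""
    path = Path(path)
    data = grid.values.astype(np.float32).copy()
    data[~np.isfinite(data)] = np.float32(grid.nodata)
    t = grid.transform
    nodata_ascii = (repr(float(grid.nodata)) + "\x00").encode("ascii")
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.px, t.py, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.west, t.north, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS_WGS84), _GEO_KEYS_WGS84),
        (_TAG_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii),
    ]
    tifffile.imwrite(path, data, extratags=extratags)
    return path


def read_raster(path) -> RasterGrid:
    """Read one single-band GeoTIFF; NoData becomes NaN."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path.name}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        if tuple(tie[:3]) != (0.0, 0.0, 0.0):
            raise ValueError(f"{path.name}: tiepoint not anchored at pixel (0,0)")
        west, north = tie[3], tie[4]
        if _TAG_GEO_KEYS in tags:
            keys = tuple(tags[_TAG_GEO_KEYS].value)
            kv = dict(zip(keys[4::4], keys[7::4]))
            epsg = kv.get(2048)
            if epsg is not None and epsg != 4326:
                raise ValueError(f"{path.name}: unsupported CRS EPSG:{epsg}")
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).split("\x00")[0])
    if data.ndim != 2:
        raise ValueError(f"{path.name}: expected a single band, got shape {data.shape}")
    values = data.astype(np.float32)
    values[values == np.float32(nodata)] = np.nan
    return RasterGrid(
        values=values,
        transform=GridTransform(west=west, north=north, px=sx, py=sy),
        band_name=path.stem,
        nodata=nodata,
    )


def read_raster_stack(paths) -> list[RasterGrid]:
    """Read several rasters and verify mutual alignment."""
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("empty raster stack")
    grids = [read_raster(p) for p in paths]
    ref = grids[0]
    for p, g in zip(paths[1:], grids[1:]):
        if not g.aligned_with(ref):
            raise AlignmentError(
                f"{p.name} is not aligned with {paths[0].name}: "
                f"shape {g.shape} vs {ref.shape}, transform {g.transform} vs {ref.transform}"
            )
    return grids


def clip_to_bbox(grid: RasterGrid, box: BoundingBox) -> RasterGrid:
    """Crop to the smallest pixel-aligned window containing the box.

    Window edges snap outward to pixel edges; values are never resampled.
    """
    t = grid.transform
    nrow, ncol = grid.shape
    # tolerance so a box edge that coincides with a pixel edge (up to fp
    # noise) snaps to that edge instead of pulling in an extra pixel row
    eps = 1e-9
    col0 = math.floor((box.lon_min - t.west) / t.px + eps)
    col1 = math.ceil((box.lon_max - t.west) / t.px - eps)
    row0 = math.floor((t.north - box.lat_max) / t.py + eps)
    row1 = math.ceil((t.north - box.lat_min) / t.py - eps)
    col0, col1 = max(col0, 0), min(col1, ncol)
    row0, row1 = max(row0, 0), min(row1, nrow)
    if col0 >= col1 or row0 >= row1:
        raise ExtentError("bounding box does not intersect the raster extent")
    return RasterGrid(
        values=grid.values[row0:row1, col0:col1].copy(),
        transform=t.shift(row0, col0),
        crs=grid.crs,
        band_name=grid.band_name,
        nodata=grid.nodata,
    )


def extract_at_points(grid: RasterGrid, points) -> np.ndarray:
    """Value of the pixel containing each (lon, lat) point; no interpolation.

    A point on a NoData pixel yields NaN; a point outside the extent is an
    error.
    """
    nrow, ncol = grid.shape
    out = np.empty(len(points), dtype=float)
    for i, (lon, lat) in enumerate(points):
        row, col = grid.transform.index(lon, lat)
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ExtentError(
                f"point ({lon}, {lat}) falls outside the raster extent"
            )
        out[i] = grid.values[row, col]
    return out


REQUIRED_SAMPLE_COLUMNS = ("sample_id", "latitude", "longitude")
ACTIVITY_COLUMNS = ("pla2", "protease", "laao")


def read_sample_table(path, *, strict_extent: bool = False) -> pd.DataFrame:
    """Read and validate a sample CSV.

    Required columns: ``sample_id, latitude, longitude`` plus at least one
    activity column (``pla2``/``protease``/``laao`` or any other numeric
    assay column).  Duplicate coordinates are allowed (pooled or nearby
    samples); sample ids must be unique and activities nonnegative.  With
    ``strict_extent`` coordinates must fall inside the India clip box.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table is missing columns {missing}")
    problems = []
    for col in ("latitude", "longitude"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        if bad:
            problems.append(f"non-numeric {col} in rows {bad}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        problems.append(f"duplicate sample ids {dupes}")
    activity_cols = [c for c in df.columns if c in ACTIVITY_COLUMNS]
    for col in activity_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals < 0].tolist()
        if bad:
            problems.append(f"negative {col} activity in rows {bad}")
    if strict_extent:
        box = INDIA_BBOX
        out = df.index[
            (df["longitude"] < box.lon_min)
            | (df["longitude"] > box.lon_max)
            | (df["latitude"] < box.lat_min)
            | (df["latitude"] > box.lat_max)
        ].tolist()
        if out:
            problems.append(f"coordinates outside the study extent in rows {out}")
    if problems:
        raise ValueError("invalid sample table: " + "; ".join(problems))
    return df


def unique_locations(df: pd.DataFrame) -> int:
    """Count distinct (longitude, latitude) sampling points."""
    return len(df[["longitude", "latitude"]].drop_duplicates())
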