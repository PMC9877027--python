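"""Georeferenced raster lattices and block resampling.

All layers in the pipeline are 2D lattices in WGS84 longitude/latitude with an
upper-left-corner geotransform; values are cell means referenced to cell
centers. ``RasterGrid`` is the common in-memory currency. GeoTIFF I/O is
implemented on top of :mod:`tifffile` using the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the GDAL nodata
convention, so the files round-trip through GDAL/QGIS.

Two resampling kernels are provided:

``resample_categorical_nearest``
    coarsens a categorical layer by taking, in each coarse block, the fine
    cell nearest the block center (ties broken toward the smallest
    (row, col) in scan order);
``aggregate_mean``
    coarsens a continuous layer by the arithmetic mean of the valid fine
    cells in each block (nodata cells are excluded; an all-nodata block
    stays nodata).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import AlignmentError, DimensionError

__all__ = [
    "RasterGrid",
    "require_same_grid",
    "resample_categorical_nearest",
    "aggregate_mean",
    "read_geotiff",
    "write_geotiff",
]

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKeyDirectory: geographic model, pixel-is-area, EPSG:4326.
_WGS84_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


@dataclass(frozen=True)
class RasterGrid:
    """A georeferenced 2D value lattice with nodata semantics.

    Parameters
    ----------
    values
        2D array; integer arrays carry categorical codes, float arrays carry
        continuous quantities (MgC ha-1, proportions, %).
    origin_x, origin_y
        Longitude / latitude of the upper-left corner of the upper-left pixel
        (degrees).
    pixel_width, pixel_height
        Positive pixel sizes in degrees; rows advance southwards.
    nodata
        Sentinel marking invalid cells, or ``None``. NaN cells in float
        rasters are always treated as invalid as well.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    pixel_width: float
    pixel_height: float
    nodata: float | int | None = None
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise DimensionError(f"raster values must be 2D, got shape {v.shape}")
        if not (self.pixel_width > 0 and self.pixel_height > 0):
            raise DimensionError("pixel sizes must be positive")
        object.__setattr__(self, "values", v)

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=tol)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=tol)
            and math.isclose(self.pixel_width, other.pixel_width, rel_tol=tol)
            and math.isclose(self.pixel_height, other.pixel_height, rel_tol=tol)
        )

    def pixel_at(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Row/col of the pixel containing a point, or None if outside."""
        col = int(math.floor((lon - self.origin_x) / self.pixel_width))
        row = int(math.floor((self.origin_y - lat) / self.pixel_height))
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    # -- values -----------------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        v = self.values
        if np.issubdtype(v.dtype, np.floating):
            mask = ~np.isnan(v)
            if self.nodata is not None and not (
                isinstance(self.nodata, float) and math.isnan(self.nodata)
            ):
                mask &= v != self.nodata
            return mask
        if self.nodata is None:
            return np.ones(v.shape, dtype=bool)
        return v != self.nodata

    def masked(self) -> np.ndarray:
        """Float copy of the values with invalid cells set to NaN."""
        out = self.values.astype(float, copy=True)
        out[~self.valid_mask()] = np.nan
        return out

    def with_values(
        self, values: np.ndarray, nodata: float | int | None | str = "keep"
    ) -> "RasterGrid":
        """New grid on the same georeference with different values."""
        nd = self.nodata if nodata == "keep" else nodata
        return replace(self, values=np.asarray(values), nodata=nd)


def require_same_grid(*grids: RasterGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.same_grid(g):
            raise AlignmentError(
                f"rasters do not share a grid: {first.shape} @ "
                f"({first.origin_x}, {first.origin_y}, {first.pixel_width}) vs "
                f"{g.shape} @ ({g.origin_x}, {g.origin_y}, {g.pixel_width})"
            )


def _check_factor(grid: RasterGrid, factor: int) -> None:
    if int(factor) != factor or factor < 1:
        raise DimensionError(f"aggregation factor must be a positive integer, got {factor}")
    if grid.nrows % factor or grid.ncols % factor:
        raise DimensionError(
            f"raster shape {grid.shape} is not divisible by factor {factor}"
        )


def resample_categorical_nearest(fine: RasterGrid, factor: int) -> RasterGrid:
    """Coarsen a categorical raster by nearest-neighbour block sampling.

    Each coarse cell takes the value of the fine cell nearest the coarse-cell
    center. For even factors the center is equidistant from four cells and the
    tie is broken toward the smallest (row, col) in scan order, i.e. the cell
    at offset ``(factor - 1) // 2`` in both axes. Nodata propagates whenever
    the selected fine cell is nodata.
    """
    _check_factor(fine, factor)
    factor = int(factor)
    if factor == 1:
        return fine
    off = (factor - 1) // 2
    values = fine.values[off::factor, off::factor].copy()
    return RasterGrid(
        values,
        fine.origin_x,
        fine.origin_y,
        fine.pixel_width * factor,
        fine.pixel_height * factor,
        nodata=fine.nodata,
        crs=fine.crs,
    )


def aggregate_mean(fine: RasterGrid, factor: int) -> RasterGrid:
    """Coarsen a continuous raster by block means over valid cells.

    Each coarse cell is the arithmetic mean of the non-nodata fine cells in
    its ``factor x factor`` block; a block with no valid cell becomes nodata.
    """
    _check_factor(fine, factor)
    factor = int(factor)
    vm = fine.masked()
    rows = fine.nrows // factor
    cols = fine.ncols // factor
    blocks = vm.reshape(rows, factor, cols, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(blocks, axis=(1, 3))
    nodata: float | None
    if fine.nodata is not None and not (
        isinstance(fine.nodata, float) and math.isnan(fine.nodata)
    ):
        nodata = float(fine.nodata)
        means = np.where(np.isnan(means), nodata, means)
    else:
        nodata = None  # NaN marks empty blocks
    return RasterGrid(
        means,
        fine.origin_x,
        fine.origin_y,
        fine.pixel_width * factor,
        fine.pixel_height * factor,
        nodata=nodata,
        crs=fine.crs,
    )


# -- GeoTIFF I/O ----------------------------------------------------------

def _format_nodata(nodata: float | int) -> str:
    if isinstance(nodata, (int, np.integer)):
        return str(int(nodata))
    return repr(float(nodata))


def write_geotiff(grid: RasterGrid, path: str | Path) -> None:
    """Write a RasterGrid as a single-band GeoTIFF."""
    extratags = [
        (
            _TAG_MODEL_PIXEL_SCALE,
            "d",
            3,
            (float(grid.pixel_width), float(grid.pixel_height), 0.0),
        ),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0),
        ),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS),
    ]
    if grid.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, _format_nodata(grid.nodata)))
    tifffile.imwrite(str(path), grid.values, extratags=extratags)


def read_geotiff(path: str | Path) -> RasterGrid:
    """Read a single-band GeoTIFF written with the conventions above."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        values = page.asarray()
        tags = page.tags
        scale_tag = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie_tag = tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise AlignmentError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        ox, oy = float(tie_tag.value[3]), float(tie_tag.value[4])
        nodata: float | int | None = None
        nod_tag = tags.get(_TAG_GDAL_NODATA)
        if nod_tag is not None:
            text = str(nod_tag.value).strip("\x00 ")
            if np.issubdtype(values.dtype, np.integer):
                nodata = int(float(text))
            else:
                nodata = float(text)
        crs = "EPSG:4326"
        geo_tag = tags.get(_TAG_GEO_KEY_DIRECTORY)
        if geo_tag is not None:
            keys = list(geo_tag.value)
            for i in range(4, len(keys), 4):
                if keys[i] == 2048:
                    crs = f"EPSG:{keys[i + 3]}"
    return RasterGrid(values, ox, oy, sx, sy, nodata=nodata, crs=crs)
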