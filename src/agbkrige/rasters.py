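"""Grid containers and GeoTIFF input/output.

Rasters are plain numpy arrays paired with an affine georeference
(:class:`GridTransform`). Missing data is represented internally as NaN;
on disk the GDAL_NODATA tag records the marker so other GIS software can
read the files. Multi-band stacks are written as multi-page GeoTIFFs with
the ModelPixelScale and ModelTiepoint tags and a JSON ImageDescription
carrying band names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

#: Fixed predictor band order used everywhere in the package.
BAND_ORDER: tuple[str, ...] = (
    "blue", "green", "red", "nir", "swir1", "swir2",
    "ndvi", "msavi", "evi", "cc", "dem", "canopy_height",
)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference of a north-up grid.

    ``x0, y0`` is the outer corner of the top-left cell; ``dx, dy`` are the
    (positive) cell sizes in map units. Row indices increase southward.
    A point maps to the cell whose half-open extent
    ``[x, x+dx) x (y-dy, y]`` contains it.
    """

    x0: float
    y0: float
    dx: float = 30.0
    dy: float = 30.0

    def cell_center(self, row, col):
        """Map-space coordinates of cell centers (vectorised)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.dx
        y = self.y0 - (row + 0.5) * self.dy
        return x, y

    def point_to_cell(self, x, y):
        """Row/column of the cell containing each point (no interpolation)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - y) / self.dy).astype(int)
        return row, col


@dataclass
class Raster:
    """A single 2-D grid with georeference; NaN marks nodata."""

    values: np.ndarray
    transform: GridTransform
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Raster values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.transform, self.name)


@dataclass
class CovariateStack:
    """The 12 aligned predictor grids plus a land-cover class grid.

    ``bands`` maps band name to 2-D array; all grids share ``transform``
    and shape. Land cover is an integer class grid (NLCD-style codes).
    """

    bands: dict[str, np.ndarray]
    landcover: np.ndarray
    transform: GridTransform

    def __post_init__(self):
        missing = [b for b in BAND_ORDER if b not in self.bands]
        if missing:
            raise ValueError(f"stack is missing bands: {missing}")
        shape = self.landcover.shape
        for name, grid in self.bands.items():
            if grid.shape != shape:
                raise ValueError(
                    f"band {name!r} shape {grid.shape} != land cover shape {shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.landcover.shape

    def band(self, name: str) -> Raster:
        return Raster(self.bands[name], self.transform, name)

    def to_array(self, order: Sequence[str] = BAND_ORDER) -> np.ndarray:
        """Bands stacked to a (n_bands, rows, cols) array in ``order``."""
        return np.stack([np.asarray(self.bands[b], dtype=float) for b in order])

    def copy(self) -> "CovariateStack":
        return CovariateStack(
            {k: v.copy() for k, v in self.bands.items()},
            self.landcover.copy(),
            self.transform,
        )


def write_raster(path, values, transform: GridTransform,
                 band_names: Sequence[str] | None = None,
                 nodata=np.nan) -> None:
    """Write a 2-D grid or (bands, rows, cols) stack as a GeoTIFF.

    Values, nodata cells, the georeference and band names survive a
    write/read round trip losslessly.
    """
    arr = np.asarray(values)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if band_names is None:
        band_names = [f"band_{i + 1}" for i in range(arr.shape[0])]
    if len(band_names) != arr.shape[0]:
        raise ValueError("band_names length does not match band count")
    desc = json.dumps({
        "band_names": list(band_names),
        "nodata": None if (isinstance(nodata, float) and np.isnan(nodata)) else nodata,
    })
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (transform.dx, transform.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0,
         "nan" if (isinstance(nodata, float) and np.isnan(nodata)) else str(nodata)),
    ]
    tifffile.imwrite(
        str(path), arr,
        photometric="minisblack",
        description=desc,
        extratags=extratags,
        metadata=None,
    )


def read_raster(path):
    """Read a GeoTIFF written by :func:`write_raster`.

    Returns ``(data, transform, band_names)`` where data has shape
    (bands, rows, cols). Files without georeference tags get a unit-grid
    transform anchored at the origin.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        tags = page.tags
        if _TAG_PIXEL_SCALE in tags and _TAG_TIEPOINT in tags:
            sx, sy, _ = tags[_TAG_PIXEL_SCALE].value[:3]
            tp = tags[_TAG_TIEPOINT].value
            transform = GridTransform(x0=float(tp[3]), y0=float(tp[4]),
                                      dx=float(sx), dy=float(sy))
        else:
            transform = GridTransform(0.0, float(data.shape[-2]), 1.0, 1.0)
        band_names = None
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                band_names = meta.get("band_names")
            except (json.JSONDecodeError, TypeError):
                pass
    if data.ndim == 2:
        data = data[None, :, :]
    if band_names is None:
        band_names = [f"band_{i + 1}" for i in range(data.shape[0])]
    return data, transform, list(band_names)


def write_stack(path, stack: CovariateStack) -> None:
    """Write the 12 predictor bands (fixed order) as one multi-band GeoTIFF."""
    write_raster(path, stack.to_array().astype(np.float64),
                 stack.transform, band_names=BAND_ORDER)


def write_landcover(path, stack: CovariateStack) -> None:
    arr = stack.landcover.astype(np.int32)[None, :, :]
    desc = json.dumps({"band_names": ["landcover"], "nodata": -1})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (stack.transform.dx, stack.transform.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, stack.transform.x0, stack.transform.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "-1"),
    ]
    tifffile.imwrite(str(path), arr, photometric="minisblack",
                     description=desc, extratags=extratags, metadata=None)


def read_stack(band_path, landcover_path) -> CovariateStack:
    """Assemble a CovariateStack from a multi-band GeoTIFF plus a land-cover grid."""
    data, transform, names = read_raster(band_path)
    bands = {name: data[i] for i, name in enumerate(names)}
    lc, lc_transform, _ = read_raster(landcover_path)
    if lc_transform != transform:
        raise ValueError("land-cover georeference does not match band stack")
    return CovariateStack(bands, lc[0].astype(int), transform)
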