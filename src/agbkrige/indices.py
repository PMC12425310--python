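"""Vegetation indices from surface-reflectance bands.

NDVI = (NIR - red) / (NIR + red)
MSAVI = (2 NIR + 1 - sqrt((2 NIR + 1)^2 - 8 (NIR - red))) / 2
EVI = 2.5 (NIR - red) / (NIR + 6 red - 7.5 blue + 1)

Inputs are reflectance grids on [0, 1]; integer-scaled rasters (x10,000,
as delivered by some providers) are detected by value range and rescaled
with a log message. Division by zero or a negative MSAVI discriminant
yields nodata (NaN), never infinities, so downstream extraction skips
such cells deterministically.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

_EVI_DENOM_EPS = 1e-9
_SCALED_THRESHOLD = 1.5  # reflectance > this means integer-scaled input
_INT_SCALE = 10000.0


def _as_reflectance(band: np.ndarray, name: str) -> np.ndarray:
    band = np.asarray(band, dtype=float)
    finite = band[np.isfinite(band)]
    if finite.size and finite.max() > _SCALED_THRESHOLD:
        logger.info("band %s looks integer-scaled (max %.1f); dividing by %g",
                    name, finite.max(), _INT_SCALE)
        band = band / _INT_SCALE
    return band


def _check_shapes(*bands: np.ndarray) -> None:
    shapes = {np.asarray(b).shape for b in bands}
    if len(shapes) != 1:
        raise ValueError(f"band grids are not co-registered: shapes {shapes}")


def ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index; in [-1, 1] where defined."""
    _check_shapes(nir, red)
    nir = _as_reflectance(nir, "nir")
    red = _as_reflectance(red, "red")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (nir - red) / denom, np.nan)
    out[~np.isfinite(out)] = np.nan
    return out


def msavi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Modified soil-adjusted vegetation index."""
    _check_shapes(nir, red)
    nir = _as_reflectance(nir, "nir")
    red = _as_reflectance(red, "red")
    disc = (2.0 * nir + 1.0) ** 2 - 8.0 * (nir - red)
    with np.errstate(invalid="ignore"):
        out = np.where(disc >= 0,
                       (2.0 * nir + 1.0 - np.sqrt(np.maximum(disc, 0.0))) / 2.0,
                       np.nan)
    out[~np.isfinite(out)] = np.nan
    return out


def evi(nir: np.ndarray, red: np.ndarray, blue: np.ndarray) -> np.ndarray:
    """Enhanced vegetation index (coefficients 2.5, 6, 7.5, +1)."""
    _check_shapes(nir, red, blue)
    nir = _as_reflectance(nir, "nir")
    red = _as_reflectance(red, "red")
    blue = _as_reflectance(blue, "blue")
    denom = nir + 6.0 * red - 7.5 * blue + 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(denom) > _EVI_DENOM_EPS,
                       2.5 * (nir - red) / denom, np.nan)
    out[~np.isfinite(out)] = np.nan
    return out
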