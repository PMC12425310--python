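"""Forest masking, predictor extraction at plots, and train/test split."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .rasters import BAND_ORDER, CovariateStack

logger = logging.getLogger(__name__)

#: NLCD codes of the classes retained as forest: deciduous, evergreen and
#: mixed forest, shrub/scrub, woody wetlands.
DEFAULT_FOREST_CLASSES = frozenset({41, 42, 43, 52, 90})


def apply_forest_mask(stack: CovariateStack,
                      forest_classes=DEFAULT_FOREST_CLASSES) -> CovariateStack:
    """Set predictor cells outside the forest classes to nodata.

    Masking only withholds cells; retained values are untouched. The
    land-cover grid itself is kept so the mask is reproducible.
    """
    forest_classes = set(forest_classes)
    if not forest_classes:
        raise ValueError("forest class set must not be empty")
    forest = np.isin(stack.landcover, sorted(forest_classes))
    logger.info("forest mask: %d of %d cells retained",
                int(forest.sum()), forest.size)
    out = stack.copy()
    for name in out.bands:
        out.bands[name] = np.where(forest, out.bands[name], np.nan)
    return out


def extract_at_plots(stack: CovariateStack, plot_table: pd.DataFrame) -> pd.DataFrame:
    """Join the 12 predictor values to each plot by containing cell.

    A plot takes the value of the single cell whose half-open extent
    contains its coordinate (no interpolation). Plots outside the grid
    extent, or in cells where any predictor is nodata, are dropped; the
    counts are logged and stored in ``result.attrs``.
    """
    required = {"plot_id", "x", "y", "agb_mg_ha"}
    missing = required - set(plot_table.columns)
    if missing:
        raise ValueError(f"plot table is missing columns: {sorted(missing)}")
    rows_n, cols_n = stack.shape
    r, c = stack.transform.point_to_cell(plot_table["x"].to_numpy(),
                                         plot_table["y"].to_numpy())
    inside = (r >= 0) & (r < rows_n) & (c >= 0) & (c < cols_n)
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning("extraction: dropped %d plots outside the grid extent",
                       n_outside)
    table = plot_table.loc[inside].reset_index(drop=True).copy()
    r, c = r[inside], c[inside]
    for name in BAND_ORDER:
        table[name] = stack.bands[name][r, c]
    predictor_ok = np.isfinite(table[list(BAND_ORDER)].to_numpy()).all(axis=1)
    n_nodata = int((~predictor_ok).sum())
    if n_nodata:
        logger.info("extraction: dropped %d plots in nodata cells", n_nodata)
    table = table.loc[predictor_ok].reset_index(drop=True)
    table.attrs["n_outside"] = n_outside
    table.attrs["n_nodata"] = n_nodata
    return table


def split_train_test(table: pd.DataFrame, train_fraction: float,
                     seed) -> pd.DataFrame:
    """Uniform random train/test split (no stratification), seeded.

    Adds a ``role`` column with round(train_fraction * n) rows marked
    "train" and the remainder "test".
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"degenerate split: {n_train} train / {n - n_train} test of {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    role = np.empty(n, dtype=object)
    role[perm[:n_train]] = "train"
    role[perm[n_train:]] = "test"
    out = table.copy()
    out["role"] = role
    logger.info("split: %d train / %d test", n_train, n - n_train)
    return out
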