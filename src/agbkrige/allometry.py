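"""Tree-level allometry and plot expansion to per-hectare biomass.

Individual-tree aboveground biomass (kg) follows the log-log allometric
form ``AGB = exp(b0 + b1 * ln(dbh))`` with species-group constants for the
four groups used in southern US inventories: cedar (CE), hard hardwood
(HH), pine, and soft hardwood (SH). The model applies to trees of 2.5 cm
DBH and larger.

Plot expansion converts each measured tree to trees per acre:

* fixed-radius plots (FRP): ``1 / plot_area_acre`` for every tree;
* variable-radius (prism) plots (VRP): ``BAF / (0.005454 * DBH_in^2)``,
  the US forestry basal-area expansion, with DBH in inches.

DBH is stored in centimetres throughout the package; the VRP formula
converts to inches internally (/ 2.54) because 0.005454 is the ft^2-per-
inch^2 basal-area constant. Per-acre biomass (kg/acre) is converted to
Mg/ha with 2.4710538 acre/ha and 1000 kg/Mg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES_GROUPS = ("CE", "HH", "Pine", "SH")

#: species group -> (b0, b1) of AGB_kg = exp(b0 + b1 ln DBH_cm)
DEFAULT_ALLOMETRY: dict[str, tuple[float, float]] = {
    "CE": (-2.0336, 2.2592),
    "HH": (-2.0127, 2.4342),
    "Pine": (-2.5356, 2.4349),
    "SH": (-1.9123, 2.3651),
}

MIN_DBH_CM = 2.5
ACRES_PER_HECTARE = 2.4710538
KG_PER_MG = 1000.0
#: ft^2 of basal area per (DBH in inches)^2
BASAL_AREA_CONST = 0.005454
CM_PER_INCH = 2.54


class AllometryError(ValueError):
    """Invalid tree or plot input for the allometric model."""


@dataclass(frozen=True)
class TreeRecord:
    species_group: str
    dbh_cm: float

    def __post_init__(self):
        if self.species_group not in SPECIES_GROUPS:
            raise AllometryError(
                f"unknown species group {self.species_group!r}; "
                f"expected one of {SPECIES_GROUPS}"
            )
        if self.dbh_cm < MIN_DBH_CM:
            raise AllometryError(
                f"DBH {self.dbh_cm} cm is below the {MIN_DBH_CM} cm floor "
                "of the allometric model"
            )


@dataclass
class PlotRecord:
    """One inventory plot: location, design, and its tree list."""

    plot_id: str
    x: float
    y: float
    plot_type: str  # "FRP" | "VRP"
    area_fraction_acre: float | None = None
    baf: float | None = None
    trees: list[TreeRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.plot_type == "FRP":
            if self.area_fraction_acre is None or self.baf is not None:
                raise AllometryError(
                    f"plot {self.plot_id}: FRP requires area_fraction_acre only"
                )
            if self.area_fraction_acre <= 0:
                raise AllometryError(f"plot {self.plot_id}: plot area must be > 0")
        elif self.plot_type == "VRP":
            if self.baf is None or self.area_fraction_acre is not None:
                raise AllometryError(f"plot {self.plot_id}: VRP requires baf only")
            if self.baf <= 0:
                raise AllometryError(f"plot {self.plot_id}: BAF must be > 0")
        else:
            raise AllometryError(
                f"plot {self.plot_id}: plot_type must be 'FRP' or 'VRP', "
                f"got {self.plot_type!r}"
            )

    @property
    def expansion_parameter(self) -> float:
        return self.area_fraction_acre if self.plot_type == "FRP" else self.baf


def make_allometry_table(overrides: dict | None = None) -> dict[str, tuple[float, float]]:
    """Default species constants, optionally overridden (overrides are logged)."""
    table = dict(DEFAULT_ALLOMETRY)
    if overrides:
        for group, coefs in overrides.items():
            if group not in SPECIES_GROUPS:
                raise AllometryError(f"unknown species group {group!r} in override")
            logger.info("allometry override for %s: %s -> %s",
                        group, table[group], tuple(coefs))
            table[group] = (float(coefs[0]), float(coefs[1]))
    return table


def tree_agb_kg(species_group: str, dbh_cm: float,
                table: dict[str, tuple[float, float]] | None = None) -> float:
    """Aboveground biomass (kg) of one tree: exp(b0 + b1 ln DBH_cm)."""
    table = table if table is not None else DEFAULT_ALLOMETRY
    if species_group not in table:
        raise AllometryError(f"unknown species group {species_group!r}")
    if dbh_cm < MIN_DBH_CM:
        raise AllometryError(
            f"DBH {dbh_cm} cm below the {MIN_DBH_CM} cm model floor"
        )
    b0, b1 = table[species_group]
    return float(np.exp(b0 + b1 * np.log(dbh_cm)))


def expansion_factor(plot: PlotRecord, tree: TreeRecord) -> float:
    """Trees per acre represented by one measured tree."""
    if plot.plot_type == "FRP":
        return 1.0 / plot.area_fraction_acre
    dbh_in = tree.dbh_cm / CM_PER_INCH
    if dbh_in <= 0:
        raise AllometryError("VRP expansion undefined for non-positive DBH")
    return plot.baf / (BASAL_AREA_CONST * dbh_in ** 2)


def plot_agb_mg_ha(plot: PlotRecord,
                   table: dict[str, tuple[float, float]] | None = None) -> float:
    """Plot aboveground biomass in Mg/ha.

    Sums tree AGB (kg) times the per-tree expansion factor to kg/acre,
    then converts with 2.4710538 acre/ha / 1000 kg/Mg. An empty tree list
    gives 0.
    """
    kg_per_acre = sum(
        tree_agb_kg(t.species_group, t.dbh_cm, table) * expansion_factor(plot, t)
        for t in plot.trees
    )
    return kg_per_acre * ACRES_PER_HECTARE / KG_PER_MG


def compute_plot_table(plots: list[PlotRecord],
                       table: dict[str, tuple[float, float]] | None = None
                       ) -> pd.DataFrame:
    """Per-plot AGB table: one row (plot_id, x, y, agb_mg_ha) per plot."""
    ids = [p.plot_id for p in plots]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AllometryError(f"duplicate plot ids: {dupes}")
    rows = [
        {"plot_id": p.plot_id, "x": p.x, "y": p.y,
         "agb_mg_ha": plot_agb_mg_ha(p, table)}
        for p in plots
    ]
    out = pd.DataFrame(rows, columns=["plot_id", "x", "y", "agb_mg_ha"])
    if len(out):
        logger.info("plot AGB: n=%d min=%.2f mean=%.2f max=%.2f Mg/ha",
                    len(out), out.agb_mg_ha.min(), out.agb_mg_ha.mean(),
                    out.agb_mg_ha.max())
    return out


TREE_CSV_COLUMNS = ["plot_id", "x", "y", "species_group", "dbh_cm",
                    "plot_type", "expansion_parameter"]


def plots_from_tree_table(trees: pd.DataFrame) -> list[PlotRecord]:
    """Group a flat tree table (schema ``TREE_CSV_COLUMNS``) into PlotRecords.

    Rows with an empty ``species_group`` denote treeless plots. DBH below
    the 2.5 cm floor is rejected with the offending plots listed.
    """
    missing = [c for c in TREE_CSV_COLUMNS if c not in trees.columns]
    if missing:
        raise AllometryError(f"tree table is missing columns: {missing}")
    bad = trees.loc[trees.species_group.notna()
                    & (trees.dbh_cm < MIN_DBH_CM), "plot_id"].unique()
    if len(bad):
        raise AllometryError(
            f"DBH below the {MIN_DBH_CM} cm floor in plots: {sorted(bad)}"
        )
    plots = []
    for plot_id, grp in trees.groupby("plot_id", sort=False):
        first = grp.iloc[0]
        kind = str(first.plot_type)
        kwargs = ({"area_fraction_acre": float(first.expansion_parameter)}
                  if kind == "FRP" else {"baf": float(first.expansion_parameter)})
        tree_rows = grp[grp.species_group.notna()]
        plots.append(PlotRecord(
            plot_id=str(plot_id), x=float(first.x), y=float(first.y),
            plot_type=kind,
            trees=[TreeRecord(str(r.species_group), float(r.dbh_cm))
                   for r in tree_rows.itertuples()],
            **kwargs,
        ))
    return plots


def tree_table_from_plots(plots: list[PlotRecord]) -> pd.DataFrame:
    """Flatten PlotRecords to the tree CSV schema (inverse of the reader)."""
    rows = []
    for p in plots:
        if not p.trees:
            rows.append({"plot_id": p.plot_id, "x": p.x, "y": p.y,
                         "species_group": np.nan, "dbh_cm": np.nan,
                         "plot_type": p.plot_type,
                         "expansion_parameter": p.expansion_parameter})
        for t in p.trees:
            rows.append({"plot_id": p.plot_id, "x": p.x, "y": p.y,
                         "species_group": t.species_group, "dbh_cm": t.dbh_cm,
                         "plot_type": p.plot_type,
                         "expansion_parameter": p.expansion_parameter})
    return pd.DataFrame(rows, columns=TREE_CSV_COLUMNS)
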