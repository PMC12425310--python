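"""Synthetic study area: covariates, truth AGB surface, plots, tree lists.

The generator emulates the statistical structure the mapping pipeline
assumes: spatially smooth covariate grids, a latent AGB surface that is a
linear function of the covariates plus a spatially autocorrelated residual
with known nugget/partial sill/range plus white noise, plot samples of
that surface at forest cell centers, and per-plot tree lists whose
allometric recomputation returns the plot's AGB. Everything is
deterministic under the configured seed.

Gaussian random fields come from either an exact dense Cholesky
factorization of the covariance (small grids) or FFT circulant embedding
(fast; exact whenever the embedded covariance is positive semidefinite,
with negative eigenvalues clamped and logged otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.fft import fft2, ifft2, next_fast_len
from scipy.optimize import brentq
from scipy.spatial.distance import pdist, squareform

from . import indices as vi
from .allometry import (MIN_DBH_CM, PlotRecord, TreeRecord, plot_agb_mg_ha,
                        tree_agb_kg, expansion_factor, AllometryError)
from .geostat import VariogramModel
from .rasters import BAND_ORDER, CovariateStack, GridTransform, Raster

logger = logging.getLogger(__name__)

#: grids up to this many cells use exact dense Cholesky by default
EXACT_FACTORIZATION_LIMIT = 4096

FOREST_CLASS = 42      # evergreen forest (NLCD code)
NONFOREST_CLASS = 21   # developed, open space (NLCD code)

#: reflectance / value ranges the smooth covariate fields are rescaled to
_BAND_RANGES = {
    "blue": (0.02, 0.08),
    "green": (0.03, 0.12),
    "red": (0.02, 0.15),
    "nir": (0.15, 0.45),
    "swir1": (0.08, 0.30),
    "swir2": (0.04, 0.25),
    "cc": (0.0, 100.0),
    "dem": (100.0, 500.0),
    "canopy_height": (2.0, 28.0),
}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic landscape.

    Defaults describe a 100x100-cell, 30 m landscape with 300 plots whose
    AGB level is anchored near the 72 Mg/ha regional mean, a residual
    field with an exponential variogram (partial sill 400 (Mg/ha)^2,
    range 300 m = 10 cells) and white noise of sd 10 Mg/ha, i.e. the
    residual sill is four times the noise variance — a strongly
    autocorrelated regime in which residual kriging has signal to recover.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    cell_size: float = 30.0
    intercept: float = 0.0
    linear_coefficients: dict[str, float] = field(
        default_factory=lambda: {"canopy_height": 3.0, "cc": 0.3, "ndvi": 30.0})
    residual_variogram: VariogramModel = field(
        default_factory=lambda: VariogramModel("exponential", 0.0, 400.0, 300.0))
    noise_sd: float = 10.0
    n_plots: int = 300
    nonforest_fraction: float = 0.1
    species_mix: dict[str, float] = field(
        default_factory=lambda: {"CE": 0.10, "HH": 0.20, "Pine": 0.55, "SH": 0.15})
    covariate_range_cells: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if abs(sum(self.species_mix.values()) - 1.0) > 1e-9:
            raise ValueError("species mix proportions must sum to 1")
        if any(p < 0 for p in self.species_mix.values()):
            raise ValueError("species mix proportions must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 <= self.nonforest_fraction < 1:
            raise ValueError("nonforest_fraction must be in [0, 1)")
        if self.n_plots > self.grid_rows * self.grid_cols:
            raise ValueError("more plots requested than grid cells")
        unknown = set(self.linear_coefficients) - set(BAND_ORDER)
        if unknown:
            raise ValueError(f"coefficients for unknown covariates: {sorted(unknown)}")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(0.0, self.grid_rows * self.cell_size,
                             self.cell_size, self.cell_size)


def _simulate_cholesky(rows, cols, vgm, rng, cell_size, n_fields):
    xy = np.column_stack([g.ravel() * cell_size for g in
                          np.meshgrid(np.arange(rows), np.arange(cols),
                                      indexing="ij")])
    cov = vgm.partial_sill - vgm._structured(squareform(pdist(xy)))
    cov[np.diag_indices_from(cov)] += vgm.nugget + 1e-10 * max(vgm.sill, 1.0)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance matrix is not positive definite; "
            f"degenerate variogram parameters ({vgm})") from exc
    z = rng.standard_normal((rows * cols, n_fields))
    return (chol @ z).T.reshape(n_fields, rows, cols)


def _simulate_circulant(rows, cols, vgm, rng, cell_size, n_fields):
    m = next_fast_len(2 * rows)
    n = next_fast_len(2 * cols)
    ii = np.minimum(np.arange(m), m - np.arange(m))
    jj = np.minimum(np.arange(n), n - np.arange(n))
    h = cell_size * np.hypot(ii[:, None], jj[None, :])
    cov = vgm.partial_sill - vgm._structured(h)
    lam = fft2(cov).real
    neg = lam < 0
    if neg.any():
        frac = neg.mean()
        if frac > 0.05:
            logger.warning("circulant embedding clamped %.1f%% negative "
                           "eigenvalues; field covariance is approximate",
                           100 * frac)
        lam = np.maximum(lam, 0.0)
    root = np.sqrt(lam / (m * n))
    fields = np.empty((n_fields, rows, cols))
    for k in range(n_fields):
        z = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
        f = fft2(root * z)
        fields[k] = f.real[:rows, :cols]
    if vgm.nugget > 0:
        fields += rng.normal(0.0, np.sqrt(vgm.nugget),
                             size=(n_fields, rows, cols))
    return fields


def simulate_gaussian_field(rows: int, cols: int, vgm: VariogramModel,
                            seed, cell_size: float = 1.0,
                            method: str = "auto", n_fields: int = 1) -> np.ndarray:
    """Zero-mean Gaussian random field(s) with covariance sill - gamma(h).

    ``seed`` may be an int or a numpy Generator. ``method`` is "cholesky"
    (exact, dense; grids up to ~10k cells), "circulant" (FFT embedding),
    or "auto" (cholesky up to 4,096 cells, circulant beyond). Returns a
    (rows, cols) array, or (n_fields, rows, cols) when ``n_fields`` > 1 —
    extra fields are i.i.d. draws from one factorization.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if vgm.partial_sill == 0.0:
        # pure nugget: i.i.d. values with variance = nugget
        fields = rng.normal(0.0, np.sqrt(vgm.nugget),
                            size=(n_fields, rows, cols))
    elif method == "cholesky" or (method == "auto"
                                  and rows * cols <= EXACT_FACTORIZATION_LIMIT):
        if rows * cols > 10_000:
            raise ValueError("cholesky method limited to grids of <= 10,000 cells; "
                             "use method='circulant'")
        fields = _simulate_cholesky(rows, cols, vgm, rng, cell_size, n_fields)
    elif method in ("circulant", "auto"):
        fields = _simulate_circulant(rows, cols, vgm, rng, cell_size, n_fields)
    else:
        raise ValueError(f"unknown method {method!r}")
    return fields[0] if n_fields == 1 else fields


def _smooth_unit_field(rows, cols, range_cells, rng):
    """Smooth field min-max rescaled to [0, 1]."""
    vgm = VariogramModel("exponential", 0.0, 1.0, float(range_cells))
    f = simulate_gaussian_field(rows, cols, vgm, rng,
                                method="circulant")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full_like(f, 0.5)
    return (f - lo) / (hi - lo)


def make_covariate_stack(config: SimulationConfig) -> CovariateStack:
    """Synthetic predictor stack: 6 smooth spectral bands scaled to
    plausible reflectance, canopy cover, elevation and canopy height, the
    three vegetation indices recomputed from the synthetic bands, and a
    land-cover grid with exactly ``nonforest_fraction`` non-forest cells.
    """
    rows, cols = config.grid_rows, config.grid_cols
    ss = np.random.SeedSequence([config.seed, 101])
    children = ss.spawn(len(_BAND_RANGES) + 1)
    bands: dict[str, np.ndarray] = {}
    for (name, (lo, hi)), child in zip(_BAND_RANGES.items(), children):
        rng = np.random.default_rng(child)
        bands[name] = lo + (hi - lo) * _smooth_unit_field(
            rows, cols, config.covariate_range_cells, rng)
    bands["ndvi"] = vi.ndvi(bands["nir"], bands["red"])
    bands["msavi"] = vi.msavi(bands["nir"], bands["red"])
    bands["evi"] = vi.evi(bands["nir"], bands["red"], bands["blue"])

    lc_rng = np.random.default_rng(children[-1])
    lc_field = _smooth_unit_field(rows, cols, config.covariate_range_cells, lc_rng)
    landcover = np.full((rows, cols), FOREST_CLASS, dtype=int)
    n_nonforest = int(round(config.nonforest_fraction * rows * cols))
    if n_nonforest:
        # threshold by exact rank so the non-forest fraction is exact
        order = np.argsort(lc_field.ravel(), kind="stable")[::-1]
        landcover.ravel()[order[:n_nonforest]] = NONFOREST_CLASS
    return CovariateStack(bands, landcover, config.transform)


def make_agb_surface(stack: CovariateStack, config: SimulationConfig) -> Raster:
    """Truth AGB surface: linear trend + autocorrelated residual + noise.

    truth = intercept + sum(coef * covariate) + GRF residual + white
    noise, clamped at 0 (clamped fraction logged).
    """
    rows, cols = stack.shape
    trend = np.full((rows, cols), float(config.intercept))
    for name, coef in config.linear_coefficients.items():
        trend = trend + coef * stack.bands[name]
    ss = np.random.SeedSequence([config.seed, 202])
    resid_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    vgm = config.residual_variogram
    if vgm.sill > 0:
        resid = simulate_gaussian_field(rows, cols, vgm, resid_rng,
                                        cell_size=config.cell_size,
                                        method="circulant")
    else:
        resid = np.zeros((rows, cols))
    noise = (noise_rng.normal(0.0, config.noise_sd, size=(rows, cols))
             if config.noise_sd > 0 else 0.0)
    truth = trend + resid + noise
    clamped = truth < 0
    if clamped.any():
        logger.info("truth surface: clamped %.2f%% of cells to 0",
                    100 * clamped.mean())
    return Raster(np.where(clamped, 0.0, truth), stack.transform, "agb_truth")


def sample_plots(truth: Raster, n_plots: int, seed,
                 forest_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Sample plot locations uniformly without replacement at forest cell
    centers; returns (plot_id, x, y, agb_mg_ha)."""
    rows, cols = truth.shape
    if forest_mask is None:
        forest_mask = np.ones((rows, cols), dtype=bool)
    candidates = np.flatnonzero(np.asarray(forest_mask, dtype=bool).ravel())
    if n_plots > len(candidates):
        raise ValueError(
            f"requested {n_plots} plots but only {len(candidates)} forest cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = np.sort(rng.choice(candidates, size=n_plots, replace=False))
    rr, cc = np.unravel_index(chosen, (rows, cols))
    x, y = truth.transform.cell_center(rr, cc)
    return pd.DataFrame({
        "plot_id": [f"P{i + 1:05d}" for i in range(n_plots)],
        "x": x, "y": y,
        "agb_mg_ha": truth.values[rr, cc],
    })


def make_tree_list(target_agb_mg_ha: float, plot: PlotRecord,
                   species_mix: dict[str, float], seed,
                   dbh_median_cm: float = 20.0,
                   dbh_log_sd: float = 0.35) -> PlotRecord:
    """Construct a tree list whose recomputed plot AGB hits the target.

    Scheme: draw species from the mix and DBH from a lognormal (median
    ``dbh_median_cm``, log-sd ``dbh_log_sd``); choose the tree count from
    the mean per-tree contribution; then solve for a multiplicative DBH
    scale (DBH floored at 2.5 cm) by root finding so that the plot AGB of
    the result matches the target to well within 1%. A zero target gives
    an empty tree list; targets below the single-smallest-tree minimum
    are reported as unreachable.
    """
    if target_agb_mg_ha < 0:
        raise ValueError("target AGB must be >= 0")
    result = replace(plot, trees=[])
    if target_agb_mg_ha == 0:
        return result
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = sorted(species_mix)
    probs = np.array([species_mix[g] for g in groups])

    def contribution(group, dbh):
        t = TreeRecord(group, dbh)
        return (tree_agb_kg(group, dbh) * expansion_factor(result, t)
                * 2.4710538 / 1000.0)

    floor_min = min(contribution(g, MIN_DBH_CM)
                    for g in groups if species_mix[g] > 0)
    if target_agb_mg_ha < floor_min * (1 - 1e-9):
        raise AllometryError(
            f"target {target_agb_mg_ha:.4f} Mg/ha unreachable: one tree at the "
            f"{MIN_DBH_CM} cm DBH floor already contributes {floor_min:.4f} Mg/ha")

    trial_species = rng.choice(groups, size=50, p=probs)
    trial_dbh = np.exp(rng.normal(np.log(dbh_median_cm), dbh_log_sd, size=50))
    trial_dbh = np.maximum(trial_dbh, MIN_DBH_CM)
    mean_contrib = np.mean([contribution(s, d)
                            for s, d in zip(trial_species, trial_dbh)])
    n = max(1, int(round(target_agb_mg_ha / mean_contrib)))

    cheapest = min((g for g in groups if species_mix[g] > 0),
                   key=lambda g: contribution(g, MIN_DBH_CM))
    for _ in range(30):
        species = rng.choice(groups, size=n, p=probs)
        dbh0 = np.exp(rng.normal(np.log(dbh_median_cm), dbh_log_sd, size=n))

        def agb_at_scale(s):
            dbh = np.maximum(s * dbh0, MIN_DBH_CM)
            return sum(contribution(sp, d) for sp, d in zip(species, dbh))

        f_floor = agb_at_scale(0.0)  # every tree at the DBH floor
        if f_floor > target_agb_mg_ha * (1 + 1e-12):
            if n > 1:
                n = max(1, n - max(1, n // 4))
                continue
            # a single tree of the drawn species overshoots even at the
            # floor; the cheapest group fits (target >= floor_min)
            species = np.array([cheapest])
            f_floor = agb_at_scale(0.0)
        if abs(f_floor - target_agb_mg_ha) <= max(1e-12,
                                                  1e-9 * target_agb_mg_ha):
            scale = 0.0
        else:
            hi = 1.0
            while agb_at_scale(hi) < target_agb_mg_ha:
                hi *= 2.0
                if hi > 1e6:  # pragma: no cover
                    raise AllometryError("tree-list scale search diverged")
            scale = brentq(lambda s: agb_at_scale(s) - target_agb_mg_ha,
                           0.0, hi, xtol=1e-12, rtol=8.9e-16)
        dbh = np.maximum(scale * dbh0, MIN_DBH_CM)
        result.trees = [TreeRecord(sp, float(d)) for sp, d in zip(species, dbh)]
        achieved = plot_agb_mg_ha(result)
        if abs(achieved - target_agb_mg_ha) <= 0.01 * max(target_agb_mg_ha, 1e-9):
            return result
    raise AllometryError(  # pragma: no cover
        f"could not match target {target_agb_mg_ha} Mg/ha within 1%")


def make_plot_records(plots: pd.DataFrame, config: SimulationConfig,
                      frp_fraction: float = 0.46,
                      area_fraction_acre: float = 1 / 25,
                      baf: float = 10.0) -> list[PlotRecord]:
    """Tree lists for every sampled plot, mixing FRP and VRP designs.

    Plot designs mirror the regional inventory: ``frp_fraction`` of plots
    are fixed-radius (default 1/25 acre), the rest variable-radius prism
    plots (default BAF 10). VRP plots cannot represent AGB below one
    2.5 cm tree's contribution (~3.4 Mg/ha at BAF 10), so plots with
    smaller targets fall back to the FRP design.
    """
    ss = np.random.SeedSequence([config.seed, 303])
    records = []
    for (row, child) in zip(plots.itertuples(), ss.spawn(len(plots))):
        rng = np.random.default_rng(child)
        use_frp = rng.random() < frp_fraction
        if not use_frp:
            probe = PlotRecord(plot_id="probe", x=0, y=0, plot_type="VRP", baf=baf)
            vrp_min = min(
                tree_agb_kg(g, MIN_DBH_CM)
                * expansion_factor(probe, TreeRecord(g, MIN_DBH_CM))
                * 2.4710538 / 1000.0
                for g, p in config.species_mix.items() if p > 0)
            if row.agb_mg_ha < vrp_min:
                use_frp = True
        if use_frp:
            shell = PlotRecord(plot_id=row.plot_id, x=row.x, y=row.y,
                               plot_type="FRP",
                               area_fraction_acre=area_fraction_acre)
        else:
            shell = PlotRecord(plot_id=row.plot_id, x=row.x, y=row.y,
                               plot_type="VRP", baf=baf)
        records.append(make_tree_list(float(row.agb_mg_ha), shell,
                                      config.species_mix, rng))
    return records


def simulate_dataset(config: SimulationConfig):
    """Full synthetic study area.

    Returns ``(stack, truth, plots, plot_records)``: the covariate stack,
    the truth AGB raster, the sampled plot table, and tree lists whose
    allometric recomputation matches the sampled AGB within 1%.
    """
    stack = make_covariate_stack(config)
    truth = make_agb_surface(stack, config)
    plot_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    plots = sample_plots(truth, config.n_plots, plot_rng,
                         forest_mask=(stack.landcover == FOREST_CLASS))
    records = make_plot_records(plots, config)
    return stack, truth, plots, records
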