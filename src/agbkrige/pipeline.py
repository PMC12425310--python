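"""End-to-end orchestration: simulate/ingest -> plot AGB -> mask ->
extract -> split -> fit RF and SVM -> residual kriging -> regression
kriging -> evaluation report.

All randomness flows from one root seed, split deterministically per
stage with :class:`numpy.random.SeedSequence`, so a run is reproducible
byte-for-byte from its config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, training
from .geostat import (VariogramModel, compute_residuals, empirical_variogram,
                      fit_variogram, ordinary_krige, regression_krige)
from .metrics import evaluate, relative_improvement, surface_summary
from .models import fit_rf, fit_svm, predict_surface, variable_importance
from .rasters import CovariateStack, Raster, read_stack, write_landcover, write_raster, write_stack
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

MODEL_LABELS = ("rf", "svm", "rfrk", "svmrk")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    In simulate mode (default) the synthetic generator provides the
    landscape; otherwise ``stack_path``/``landcover_path``/``plots_path``
    (or ``trees_path``) point at existing inputs.
    """

    seed: int = 0
    out_dir: str | Path | None = None
    simulation: SimulationConfig | None = None
    stack_path: str | Path | None = None
    landcover_path: str | Path | None = None
    plots_path: str | Path | None = None
    trees_path: str | Path | None = None
    train_fraction: float = 0.8
    forest_classes: frozenset = training.DEFAULT_FOREST_CLASSES
    variogram_family: str = "spherical"
    variogram_bins: int = 15
    rf_params: dict = field(default_factory=dict)
    svm_params: dict = field(default_factory=dict)
    importance_repeats: int = 0   # 0 disables the (slow) importance stage

    def __post_init__(self):
        if self.simulation is None and self.stack_path is None:
            self.simulation = SimulationConfig(seed=self.seed)


def _stage_counts(**kwargs) -> dict:
    return {k: int(v) for k, v in kwargs.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the run report (JSON-serializable).

    When ``config.out_dir`` is set, writes: the covariate stack and land
    cover (simulate mode), plots/trees/training-table CSVs, the four AGB
    GeoTIFFs, kriged-residual and kriging-variance GeoTIFFs per learner,
    variogram reports, and ``report.json``.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("split", "rf", "svm", "importance"), ss.spawn(4))}
    int_seed = lambda name: int(seeds[name].generate_state(1)[0] % (2 ** 31))

    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "models": {}}

    # --- inputs: simulate or ingest -------------------------------------
    if config.simulation is not None:
        stack, truth, plots, records = simulate_dataset(config.simulation)
        plot_table = allometry.compute_plot_table(records)
        report["stages"]["simulate"] = _stage_counts(
            cells=stack.landcover.size, plots=len(plots))
        if out:
            write_stack(out / "stack.tif", stack)
            write_landcover(out / "landcover.tif", stack)
            write_raster(out / "agb_truth.tif", truth.values, truth.transform,
                         band_names=["agb_truth"])
            plots.to_csv(out / "plots.csv", index=False)
            allometry.tree_table_from_plots(records).to_csv(
                out / "trees.csv", index=False)
    else:
        stack = read_stack(config.stack_path, config.landcover_path)
        if config.trees_path is not None:
            trees = pd.read_csv(config.trees_path, float_precision="round_trip")
            plot_table = allometry.compute_plot_table(
                allometry.plots_from_tree_table(trees))
        elif config.plots_path is not None:
            plot_table = pd.read_csv(config.plots_path, float_precision="round_trip")
        else:
            raise ValueError("need plots_path or trees_path in ingest mode")

    # --- mask, extract, split -------------------------------------------
    masked = training.apply_forest_mask(stack, config.forest_classes)
    table = training.extract_at_plots(masked, plot_table)
    report["stages"]["extract"] = _stage_counts(
        plots_in=len(plot_table), rows_out=len(table),
        dropped_outside=table.attrs.get("n_outside", 0),
        dropped_nodata=table.attrs.get("n_nodata", 0))
    table = training.split_train_test(table, config.train_fraction,
                                      np.random.default_rng(seeds["split"]))
    train = table[table.role == "train"]
    test = table[table.role == "test"]
    report["stages"]["split"] = _stage_counts(train=len(train), test=len(test))
    if out:
        table.to_csv(out / "table.csv", index=False)

    # --- learners, residual kriging, composition, evaluation ------------
    forest_mask = np.isin(stack.landcover, sorted(config.forest_classes))
    observed = test["agb_mg_ha"].to_numpy(dtype=float)
    rmse_by_label: dict[str, float] = {}
    report["variograms"] = {}

    for kind, fitter, params in (("rf", fit_rf, config.rf_params),
                                 ("svm", fit_svm, config.svm_params)):
        model = fitter(train, seed=int_seed(kind), **params)
        base_surface = predict_surface(model, masked)
        base_eval = evaluate(np.maximum(model.predict(test), 0.0),
                             observed, label=kind)
        rmse_by_label[kind] = base_eval.rmse
        report["models"][kind] = {
            "evaluation": base_eval.to_dict(),
            "surface_summary": surface_summary(base_surface).to_dict(),
            "hyperparameters": model.hyperparameters,
        }

        residuals = compute_residuals(model, train)
        emp = empirical_variogram(residuals, n_bins=config.variogram_bins)
        vgm = fit_variogram(emp, family=config.variogram_family)
        report["variograms"][kind] = {
            "family": vgm.family, "nugget": vgm.nugget,
            "partial_sill": vgm.partial_sill, "range": vgm.range_,
            "weighted_sse": vgm.fit_diagnostics.get("weighted_sse"),
        }
        kriged = ordinary_krige(residuals, vgm, stack.transform, stack.shape,
                                mask=forest_mask)
        composed = regression_krige(base_surface, kriged)
        rk_label = f"{kind}rk"
        # evaluate the composed surface at the held-out plot cells
        r, c = stack.transform.point_to_cell(test["x"].to_numpy(),
                                             test["y"].to_numpy())
        rk_pred = composed.values[r, c]
        rk_eval = evaluate(rk_pred, observed, label=rk_label)
        frac, pct = relative_improvement(base_eval.rmse, rk_eval.rmse)
        rk_eval.ri_fraction, rk_eval.ri_percent = frac, round(pct, 2)
        rk_eval.ri_baseline = kind
        rmse_by_label[rk_label] = rk_eval.rmse
        report["models"][rk_label] = {
            "evaluation": rk_eval.to_dict(),
            "surface_summary": surface_summary(composed).to_dict(),
        }
        if config.importance_repeats:
            imp = variable_importance(model, test,
                                      n_repeats=config.importance_repeats,
                                      seed=int_seed("importance"))
            report["models"][kind]["importance"] = imp.to_dict(orient="records")
        if out:
            write_raster(out / f"agb_{kind}.tif", base_surface.values,
                         stack.transform, band_names=[f"agb_{kind}"])
            write_raster(out / f"agb_{rk_label}.tif", composed.values,
                         stack.transform, band_names=[f"agb_{rk_label}"])
            write_raster(out / f"residual_{kind}.tif",
                         np.stack([kriged.prediction.values,
                                   kriged.variance.values]),
                         stack.transform,
                         band_names=["kriged_residual", "kriging_variance"])
            pd.DataFrame({"lag": emp.lags, "gamma": emp.gamma,
                          "pairs": emp.counts}).to_csv(
                out / f"variogram_{kind}.csv", index=False)

    report["ri"] = {
        "rf_to_rfrk_pct": round(relative_improvement(
            rmse_by_label["rf"], rmse_by_label["rfrk"])[1], 2),
        "svm_to_svmrk_pct": round(relative_improvement(
            rmse_by_label["svm"], rmse_by_label["svmrk"])[1], 2),
    }
    report["config"] = {
        "train_fraction": config.train_fraction,
        "variogram_family": config.variogram_family,
        "forest_classes": sorted(config.forest_classes),
        "simulate": config.simulation is not None,
    }
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
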