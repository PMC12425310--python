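"""Base learners for the AGB trend: random forest and radial-kernel SVR.

Both learners are commodity components (scikit-learn); this module pins
the interface — a :class:`RegressionModel` wrapping a fitted estimator
with its predictor order and preprocessing — plus surface prediction and
a single permutation-importance procedure applied identically to both
model kinds (the relative increase in MSE when one predictor's values are
shuffled, the %IncMSE idea).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .rasters import BAND_ORDER, CovariateStack, Raster

logger = logging.getLogger(__name__)

MIN_TRAINING_ROWS = 20


@dataclass
class RegressionModel:
    """A fitted learner plus the metadata needed to apply it elsewhere."""

    kind: str                      # "rf" | "svm"
    estimator: object              # fitted sklearn estimator / pipeline
    predictors: list[str]
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.predictors].to_numpy(dtype=float)
        return np.asarray(self.estimator.predict(x), dtype=float)


def _validate_training(table: pd.DataFrame, predictors) -> tuple[np.ndarray, np.ndarray]:
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise ValueError(f"training table is missing predictors: {missing}")
    x = table[list(predictors)].to_numpy(dtype=float)
    y = table["agb_mg_ha"].to_numpy(dtype=float)
    if len(table) < MIN_TRAINING_ROWS:
        raise ValueError(f"need at least {MIN_TRAINING_ROWS} training rows, "
                         f"got {len(table)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("training predictors contain missing values")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to fit")
    return x, y


def fit_rf(table: pd.DataFrame, predictors=BAND_ORDER, n_estimators: int = 500,
           max_features: float = 1 / 3, seed: int = 0) -> RegressionModel:
    """Bagged regression-tree ensemble (500 trees, p/3 features per split,
    unlimited depth). The out-of-bag R^2 is recorded in the
    hyperparameters record."""
    predictors = list(predictors)
    x, y = _validate_training(table, predictors)
    est = RandomForestRegressor(
        n_estimators=n_estimators, max_features=max_features,
        oob_score=True, random_state=seed, n_jobs=1)
    est.fit(x, y)
    logger.info("rf: %d trees, OOB R^2 = %.3f", n_estimators, est.oob_score_)
    return RegressionModel(
        kind="rf", estimator=est, predictors=predictors,
        hyperparameters={"n_estimators": n_estimators,
                         "max_features": max_features,
                         "oob_r2": float(est.oob_score_)},
        seed=seed)


def fit_svm(table: pd.DataFrame, predictors=BAND_ORDER,
            costs=(0.25, 1.0, 4.0, 16.0), gamma_factors=(0.25, 1.0, 4.0),
            cv_folds: int = 5, seed: int = 0) -> RegressionModel:
    """Radial-kernel support-vector regression on standardized predictors.

    Cost and kernel width are chosen by k-fold cross-validated grid
    search: costs as given, gamma = factor / n_predictors around the
    standard 1/p heuristic for standardized inputs. Constant predictor
    columns are dropped with a warning. Selected hyperparameters are
    logged and recorded.
    """
    predictors = list(predictors)
    x, y = _validate_training(table, predictors)
    keep = np.ptp(x, axis=0) > 0
    if not keep.all():
        dropped = [p for p, k in zip(predictors, keep) if not k]
        logger.warning("svm: dropping constant predictors %s", dropped)
        predictors = [p for p, k in zip(predictors, keep) if k]
        x = x[:, keep]
    gammas = [f / x.shape[1] for f in gamma_factors]
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    grid = GridSearchCV(
        pipe,
        {"svr__C": list(costs), "svr__gamma": gammas},
        cv=KFold(n_splits=cv_folds, shuffle=True, random_state=seed),
        scoring="neg_mean_squared_error", n_jobs=1)
    grid.fit(x, y)
    chosen = {k.replace("svr__", ""): v for k, v in grid.best_params_.items()}
    logger.info("svm: selected %s (cv RMSE %.2f)", chosen,
                float(np.sqrt(-grid.best_score_)))
    return RegressionModel(
        kind="svm", estimator=grid.best_estimator_, predictors=predictors,
        hyperparameters={**chosen, "cv_folds": cv_folds,
                         "cv_rmse": float(np.sqrt(-grid.best_score_))},
        seed=seed)


def predict_surface(model: RegressionModel, stack: CovariateStack) -> Raster:
    """Cellwise model prediction over non-nodata cells of the stack.

    Negative predictions are clamped to 0 (logged); cells with any nodata
    predictor stay nodata.
    """
    missing = [p for p in model.predictors if p not in stack.bands]
    if missing:
        raise ValueError(f"stack is missing bands required by the model: {missing}")
    arr = np.stack([stack.bands[p] for p in model.predictors])
    flat = arr.reshape(len(model.predictors), -1).T
    live = np.isfinite(flat).all(axis=1)
    out = np.full(flat.shape[0], np.nan)
    if live.any():
        preds = np.asarray(model.estimator.predict(flat[live]), dtype=float)
        n_neg = int((preds < 0).sum())
        if n_neg:
            logger.info("predict_surface(%s): clamped %d negative cells to 0",
                        model.kind, n_neg)
        out[live] = np.maximum(preds, 0.0)
    return Raster(out.reshape(stack.shape), stack.transform,
                  name=f"agb_{model.kind}")


def variable_importance(model: RegressionModel, table: pd.DataFrame,
                        n_repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Permutation importance: mean % increase in MSE when one predictor
    is shuffled, identical procedure for both model kinds.

    Scored on the rows supplied (typically held-out rows). Returns one
    row per predictor with columns (predictor, importance_pct_inc_mse,
    se, rank); rank 1 is most important.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    x = table[model.predictors].to_numpy(dtype=float)
    y = table["agb_mg_ha"].to_numpy(dtype=float)
    base_mse = float(np.mean((model.estimator.predict(x) - y) ** 2))
    if base_mse == 0:
        base_mse = 1e-12
    name_order = sorted(model.predictors)
    rows = []
    for j, name in enumerate(model.predictors):
        # seed per predictor name so scores ignore column order
        rng = np.random.default_rng([seed, name_order.index(name)])
        increases = np.empty(n_repeats)
        for rep in range(n_repeats):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            mse = float(np.mean((model.estimator.predict(xp) - y) ** 2))
            increases[rep] = 100.0 * (mse - base_mse) / base_mse
        rows.append({"predictor": name,
                     "importance_pct_inc_mse": float(increases.mean()),
                     "se": float(increases.std(ddof=1) / np.sqrt(n_repeats))
                     if n_repeats > 1 else 0.0})
    out = pd.DataFrame(rows)
    out["rank"] = (out["importance_pct_inc_mse"]
                   .rank(ascending=False, method="first").astype(int))
    return out.sort_values("rank").reset_index(drop=True)
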