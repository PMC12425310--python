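"""Semivariograms, ordinary kriging of residuals, and regression kriging.

Regression kriging decomposes a spatial field into a regression trend and
a spatially autocorrelated residual: the trend is predicted by a fitted
regression model, the residuals at the training locations are interpolated
by ordinary kriging (OK), and the final surface is their cellwise sum.

The variogram ``gamma(h)`` uses the effective-range convention common in
GIS software:

* spherical:   gamma = n + s * (1.5 h/r - 0.5 (h/r)^3) for h <= r, else n + s
* exponential: gamma = n + s * (1 - exp(-3 h / r))
* gaussian:    gamma = n + s * (1 - exp(-3 h^2 / r^2))

with nugget ``n``, partial sill ``s`` and range ``r``; gamma(0) = 0 by
convention, the nugget being the h -> 0+ limit. Empirical semivariance is
the Matheron classical estimator; fitting is weighted least squares with
``N(h) / h^2`` weights.

OK solves, per prediction location, the augmented system with the
unbiasedness constraint (weights sum to 1, Lagrange multiplier internal);
with a zero nugget it interpolates the data exactly. Kriging is global for
up to 2,000 points and switches to a nearest-k neighborhood beyond that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .rasters import GridTransform, Raster

logger = logging.getLogger(__name__)

VARIOGRAM_FAMILIES = ("spherical", "exponential", "gaussian")

#: above this many residual points, grid kriging uses a local neighborhood
GLOBAL_KRIGING_LIMIT = 2000
DEFAULT_NEIGHBORHOOD_K = 64


@dataclass
class VariogramModel:
    """Parametric semivariogram: family, nugget, partial sill, range."""

    family: str
    nugget: float
    partial_sill: float
    range_: float
    fit_diagnostics: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.family not in VARIOGRAM_FAMILIES:
            raise ValueError(
                f"unknown variogram family {self.family!r}; "
                f"expected one of {VARIOGRAM_FAMILIES}"
            )
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        """Total sill = nugget + partial sill."""
        return self.nugget + self.partial_sill

    def _structured(self, h: np.ndarray) -> np.ndarray:
        """Partial-sill component of gamma (no nugget), vectorised over h."""
        h = np.asarray(h, dtype=float)
        r = self.range_
        if self.family == "spherical":
            hr = np.minimum(h / r, 1.0)
            g = 1.5 * hr - 0.5 * hr ** 3
        elif self.family == "exponential":
            g = 1.0 - np.exp(-3.0 * h / r)
        else:  # gaussian
            g = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        return self.partial_sill * g

    def gamma(self, h) -> np.ndarray:
        """Semivariance at lag h; gamma(0) = 0, nugget appears for h > 0."""
        h = np.asarray(h, dtype=float)
        out = self._structured(h)
        out = out + np.where(h > 0, self.nugget, 0.0)
        return out

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h) (nugget only at h=0)."""
        h = np.asarray(h, dtype=float)
        return self.sill - self.gamma(h)


@dataclass
class EmpiricalVariogram:
    """Matheron semivariance estimates per lag bin."""

    lags: np.ndarray        # bin centers (distance units)
    gamma: np.ndarray       # semivariance per bin
    counts: np.ndarray      # pair counts per bin
    max_lag: float

    def __post_init__(self):
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag bins must be strictly increasing")
        if np.any(self.counts < 1):
            raise ValueError("retained bins must have at least one pair")
        if np.any(self.gamma < 0):
            raise ValueError("semivariance must be non-negative")


@dataclass
class KrigedField:
    """OK predictions and kriging variances on a grid."""

    prediction: Raster
    variance: Raster


def compute_residuals(model, table: pd.DataFrame) -> pd.DataFrame:
    """Training residuals r_i = observed - predicted with coordinates.

    ``model`` is a fitted RegressionModel (see :mod:`agbkrige.models`);
    ``table`` must carry x, y, agb_mg_ha and the model's predictors.
    """
    for col in ("x", "y"):
        if col not in table.columns:
            raise ValueError(f"training table is missing coordinates column {col!r}")
    predicted = model.predict(table)
    out = pd.DataFrame({
        "x": table["x"].to_numpy(dtype=float),
        "y": table["y"].to_numpy(dtype=float),
        "residual": table["agb_mg_ha"].to_numpy(dtype=float) - predicted,
    })
    if not np.all(np.isfinite(out.residual)):
        raise ValueError("non-finite residuals")
    return out


def empirical_variogram(points: pd.DataFrame, n_bins: int = 15,
                        max_lag: float | None = None,
                        value_col: str = "residual",
                        min_points: int = 30) -> EmpiricalVariogram:
    """Classical (Matheron) semivariogram of scattered values.

    gamma_hat(h) = (1 / 2N(h)) * sum over pairs in the bin of (r_i - r_j)^2.
    Default max lag is half the maximum pairwise distance; bins with no
    pairs are dropped. Fewer than ``min_points`` points (default 30, the
    conventional floor for a usable variogram) is an error; lower the
    floor explicitly for didactic tiny configurations.
    """
    if len(points) < min_points:
        raise ValueError(
            f"need at least {min_points} points for an empirical variogram")
    xy = points[["x", "y"]].to_numpy(dtype=float)
    vals = points[value_col].to_numpy(dtype=float)
    d = pdist(xy)
    if np.all(d == 0):
        raise ValueError("all points are coincident")
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
    if max_lag <= 0:
        raise ValueError("max_lag must be > 0")
    sq_diff = pdist(vals[:, None], metric="sqeuclidean")
    keep = (d > 0) & (d <= max_lag)
    d, sq_diff = d[keep], sq_diff[keep]
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    # right-closed bins (0, h1], (h1, h2], ... so exact lattice lags land
    # in the bin they name
    which = np.clip(np.digitize(d, edges, right=True) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sq_diff, minlength=n_bins)
    dist_sums = np.bincount(which, weights=d, minlength=n_bins)
    nonempty = counts > 0
    gamma = sums[nonempty] / (2.0 * counts[nonempty])
    lags = dist_sums[nonempty] / counts[nonempty]  # mean pair distance per bin
    return EmpiricalVariogram(lags=lags, gamma=gamma,
                              counts=counts[nonempty], max_lag=float(max_lag))


def fit_variogram(emp: EmpiricalVariogram, family: str = "spherical") -> VariogramModel:
    """Weighted least-squares fit of a variogram model to empirical bins.

    Weights are N(h)/h^2 (short lags, well-populated bins dominate);
    parameters are bounded to nugget >= 0, partial sill >= 0 and range in
    (0, 2 * max_lag]. Several starting points are tried; the best weighted
    SSE wins. Fit diagnostics are attached to the returned model.
    """
    if family not in VARIOGRAM_FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")
    if len(emp.lags) < 4:
        raise ValueError("need at least 4 variogram bins to fit 3 parameters")
    h, g, n = emp.lags, emp.gamma, emp.counts
    w = np.sqrt(n / h ** 2)
    var_level = float(g[-max(1, len(g) // 3):].mean())
    var_level = max(var_level, 1e-12)

    def resid(theta):
        nugget, psill, rng = theta
        m = VariogramModel(family, max(nugget, 0.0), max(psill, 0.0),
                           max(rng, 1e-12))
        return w * (m.gamma(h) - g)

    bounds = ([0.0, 0.0, 1e-9 * emp.max_lag],
              [2.0 * var_level + 1e-9, 2.0 * var_level + 1e-9, 2.0 * emp.max_lag])
    starts = [
        (0.0, var_level, emp.max_lag / 2),
        (0.0, var_level, emp.max_lag / 4),
        (var_level / 2, var_level / 2, emp.max_lag / 2),
        (var_level, 1e-9, emp.max_lag / 2),
    ]
    best = None
    attempted = []
    for x0 in starts:
        attempted.append(x0)
        try:
            sol = optimize.least_squares(resid, x0, bounds=bounds, method="trf")
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(
            f"variogram fit did not converge; starting values tried: {attempted}"
        )
    nugget, psill, rng = best.x
    model = VariogramModel(family, float(max(nugget, 0.0)),
                           float(max(psill, 0.0)), float(max(rng, 1e-12)))
    model.fit_diagnostics = {
        "weighted_sse": float(2.0 * best.cost),
        "n_bins": int(len(h)),
        "max_lag": emp.max_lag,
    }
    return model


def _deduplicate(xy: np.ndarray, values: np.ndarray):
    """Average values at exactly coincident coordinates (OK needs distinct points)."""
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "v": values})
    grouped = df.groupby(["x", "y"], sort=False, as_index=False).mean()
    if len(grouped) < len(df):
        logger.info("kriging: averaged %d duplicate locations",
                    len(df) - len(grouped))
    return grouped[["x", "y"]].to_numpy(), grouped["v"].to_numpy()


def _ok_factorize(xy: np.ndarray, vgm: VariogramModel):
    """LU-factorized augmented OK matrix [[Gamma, 1], [1^T, 0]]."""
    n = len(xy)
    gamma = vgm.gamma(squareform(pdist(xy)))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    try:
        return linalg.lu_factor(a)
    except linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"singular kriging matrix: {exc}") from exc


def krige_points(points: pd.DataFrame, vgm: VariogramModel,
                 targets_xy: np.ndarray, value_col: str = "residual",
                 return_weights: bool = False):
    """Global ordinary kriging at arbitrary target locations.

    Returns ``(predictions, variances)`` — and the (n_targets, n_data)
    weight matrix when ``return_weights`` — solving the full augmented
    system once per call. Duplicate data coordinates are averaged first.
    """
    xy = points[["x", "y"]].to_numpy(dtype=float)
    vals = points[value_col].to_numpy(dtype=float)
    xy, vals = _deduplicate(xy, vals)
    n = len(xy)
    if n == 0:
        raise ValueError("no data points to krige from")
    targets_xy = np.atleast_2d(np.asarray(targets_xy, dtype=float))
    if n == 1:
        preds = np.full(len(targets_xy), vals[0])
        h = np.hypot(targets_xy[:, 0] - xy[0, 0], targets_xy[:, 1] - xy[0, 1])
        variances = 2.0 * vgm.gamma(h)
        weights = np.ones((len(targets_xy), 1))
        return (preds, variances, weights) if return_weights else (preds, variances)
    lu = _ok_factorize(xy, vgm)
    d = np.hypot(targets_xy[:, 0, None] - xy[None, :, 0],
                 targets_xy[:, 1, None] - xy[None, :, 1])
    b = np.empty((n + 1, len(targets_xy)))
    b[:n, :] = vgm.gamma(d).T
    b[n, :] = 1.0
    sol = linalg.lu_solve(lu, b)
    weights = sol[:n, :].T
    mu = sol[n, :]
    preds = weights @ vals
    variances = np.maximum(np.einsum("ij,ji->i", weights, b[:n, :]) + mu, 0.0)
    if return_weights:
        return preds, variances, weights
    return preds, variances


def _krige_local(xy, vals, vgm, targets_xy, k):
    """Nearest-k neighborhood OK, one small augmented solve per target."""
    tree = cKDTree(xy)
    k = min(k, len(xy))
    dist, idx = tree.query(targets_xy, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    preds = np.empty(len(targets_xy))
    variances = np.empty(len(targets_xy))
    for i in range(len(targets_xy)):
        sub = idx[i]
        sub_xy = xy[sub]
        a = np.empty((k + 1, k + 1))
        a[:k, :k] = vgm.gamma(squareform(pdist(sub_xy))) if k > 1 else 0.0
        a[:k, k] = 1.0
        a[k, :k] = 1.0
        a[k, k] = 0.0
        b = np.empty(k + 1)
        b[:k] = vgm.gamma(dist[i])
        b[k] = 1.0
        sol = np.linalg.solve(a, b)
        preds[i] = sol[:k] @ vals[sub]
        variances[i] = max(float(sol[:k] @ b[:k] + sol[k]), 0.0)
    return preds, variances


def ordinary_krige(points: pd.DataFrame, vgm: VariogramModel,
                   transform: GridTransform, shape: tuple[int, int],
                   mask: np.ndarray | None = None,
                   neighborhood: int | None = None,
                   value_col: str = "residual") -> KrigedField:
    """Ordinary kriging of scattered residuals onto a grid.

    Predicts at cell centers of a ``shape`` grid with georeference
    ``transform``; cells where ``mask`` is False become nodata. Uses one
    global system for up to 2,000 points, otherwise a nearest-k
    neighborhood (default k=64, override with ``neighborhood``).
    """
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = transform.cell_center(rr.ravel(), cc.ravel())
    targets = np.column_stack([x, y])
    if mask is not None:
        live = np.asarray(mask, dtype=bool).ravel()
    else:
        live = np.ones(rows * cols, dtype=bool)
    pred_grid = np.full(rows * cols, np.nan)
    var_grid = np.full(rows * cols, np.nan)
    if live.any():
        xy = points[["x", "y"]].to_numpy(dtype=float)
        vals = points[value_col].to_numpy(dtype=float)
        xy, vals = _deduplicate(xy, vals)
        use_local = neighborhood is not None or len(xy) > GLOBAL_KRIGING_LIMIT
        if use_local and len(xy) > 1:
            k = neighborhood or DEFAULT_NEIGHBORHOOD_K
            logger.info("kriging: local neighborhood k=%d over %d points",
                        k, len(xy))
            preds, variances = _krige_local(xy, vals, vgm, targets[live], k)
        else:
            dedup = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], value_col: vals})
            preds, variances = krige_points(dedup, vgm, targets[live],
                                            value_col=value_col)
        pred_grid[live] = preds
        var_grid[live] = variances
    return KrigedField(
        prediction=Raster(pred_grid.reshape(rows, cols), transform, "kriged_residual"),
        variance=Raster(var_grid.reshape(rows, cols), transform, "kriging_variance"),
    )


def regression_krige(base: Raster, kriged: KrigedField | Raster) -> Raster:
    """Regression-kriging surface: base prediction + kriged residual.

    Cellwise sum; nodata in either input propagates; negative sums are
    clamped to 0 (biomass is nonnegative) with a logged count.
    """
    resid = kriged.prediction if isinstance(kriged, KrigedField) else kriged
    if base.transform != resid.transform or base.shape != resid.shape:
        raise ValueError("regression kriging: georeference mismatch "
                         "between base surface and kriged residuals")
    total = base.values + resid.values
    negative = np.isfinite(total) & (total < 0)
    if negative.any():
        logger.info("regression kriging: clamped %d negative cells to 0",
                    int(negative.sum()))
    total = np.where(negative, 0.0, total)
    return Raster(total, base.transform, name=f"{base.name}_rk" if base.name else "rk")
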