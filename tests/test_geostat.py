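"""Semivariograms, ordinary kriging, and regression-kriging composition."""

import numpy as np
import pandas as pd
import pytest

from agbkrige.geostat import (EmpiricalVariogram, VariogramModel,
                              compute_residuals, empirical_variogram,
                              fit_variogram, krige_points, ordinary_krige,
                              regression_krige)
from agbkrige.models import RegressionModel
from agbkrige.rasters import GridTransform, Raster
from agbkrige.synthetic import simulate_gaussian_field

FAMILIES = ("spherical", "exponential", "gaussian")


def dense_ok_oracle(data_xy, values, vgm, target_xy):
    """Independent brute-force OK: assemble and solve the augmented
    system with plain numpy, one target at a time."""
    n = len(data_xy)
    a = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            h = np.hypot(*(data_xy[i] - data_xy[j]))
            a[i, j] = vgm.gamma(h)
        a[i, n] = a[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        b[i] = vgm.gamma(np.hypot(*(target_xy - data_xy[i])))
    b[n] = 1.0
    sol = np.linalg.solve(a, b)
    return float(sol[:n] @ values), float(sol[:n] @ b[:n] + sol[n])


class TestVariogramModel:
    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="family"):
            VariogramModel("cubic", 0.0, 1.0, 10.0)
        with pytest.raises(ValueError):
            VariogramModel("spherical", -0.1, 1.0, 10.0)
        with pytest.raises(ValueError):
            VariogramModel("spherical", 0.0, 1.0, 0.0)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_gamma_conventions(self, family):
        v = VariogramModel(family, 0.3, 1.2, 25.0)
        assert v.gamma(0.0) == 0.0
        # nugget is the h -> 0+ limit
        assert v.gamma(1e-9) == pytest.approx(0.3, abs=1e-6)
        # effective range: ~95% of the partial sill is reached at h = range
        assert v.gamma(25.0) >= 0.3 + 0.95 * 1.2 - 1e-9
        assert np.allclose(v.covariance([0.0, 10.0, 50.0]),
                           v.sill - v.gamma([0.0, 10.0, 50.0]))


class TestEmpiricalVariogram:
    def test_three_collinear_points_brute_force(self):
        """Values (0, 1, 0) at spacing d: gamma(d) = 0.5, gamma(2d) = 0."""
        pts = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": 0.0,
                            "residual": [0.0, 1.0, 0.0]})
        emp = empirical_variogram(pts, n_bins=2, max_lag=2.0, min_points=3)
        assert emp.gamma == pytest.approx([0.5, 0.0])
        assert emp.counts.tolist() == [2, 1]

    def test_white_noise_is_flat_at_the_variance(self, rng):
        n = 400
        pts = pd.DataFrame({"x": rng.uniform(0, 100, n),
                            "y": rng.uniform(0, 100, n),
                            "residual": rng.normal(0, 2.0, n)})
        emp = empirical_variogram(pts)
        assert emp.gamma == pytest.approx(np.full_like(emp.gamma, 4.0),
                                          rel=0.35)

    def test_tracks_generating_variogram(self):
        truth = VariogramModel("exponential", 0.0, 1.0, 15.0)
        field = simulate_gaussian_field(50, 50, truth, seed=3,
                                        method="circulant")
        rr, cc = np.meshgrid(np.arange(50), np.arange(50), indexing="ij")
        rng = np.random.default_rng(4)
        idx = rng.choice(2500, 600, replace=False)
        pts = pd.DataFrame({"x": cc.ravel()[idx].astype(float),
                            "y": rr.ravel()[idx].astype(float),
                            "residual": field.ravel()[idx]})
        emp = empirical_variogram(pts, max_lag=20.0)
        expected = truth.gamma(emp.lags)
        assert np.all(np.abs(emp.gamma - expected) < 0.35 * truth.sill)

    def test_guards(self, rng):
        few = pd.DataFrame({"x": [0.0, 1.0], "y": 0.0, "residual": [0.0, 1.0]})
        with pytest.raises(ValueError, match="at least 30"):
            empirical_variogram(few)
        coincident = pd.DataFrame({"x": 1.0, "y": 2.0,
                                   "residual": rng.normal(size=40)})
        with pytest.raises(ValueError, match="coincident"):
            empirical_variogram(coincident)


class TestFitVariogram:
    def test_flat_empirical_gives_pure_nugget(self):
        emp = EmpiricalVariogram(lags=np.linspace(5, 50, 10),
                                 gamma=np.full(10, 3.0),
                                 counts=np.full(10, 200), max_lag=50.0)
        fit = fit_variogram(emp, family="spherical")
        assert fit.nugget == pytest.approx(3.0, abs=0.05)
        assert fit.partial_sill == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_recovers_noiseless_curve(self, family):
        truth = VariogramModel(family, 0.4, 2.0, 22.0)
        lags = np.linspace(2, 60, 15)
        emp = EmpiricalVariogram(lags=lags, gamma=truth.gamma(lags),
                                 counts=np.full(15, 500), max_lag=60.0)
        fit = fit_variogram(emp, family=family)
        assert fit.nugget == pytest.approx(0.4, abs=1e-4)
        assert fit.partial_sill == pytest.approx(2.0, abs=1e-4)
        assert fit.range_ == pytest.approx(22.0, rel=1e-3)
        assert fit.fit_diagnostics["weighted_sse"] < 1e-6

    def test_too_few_bins_rejected(self):
        emp = EmpiricalVariogram(lags=np.array([1.0, 2.0, 3.0]),
                                 gamma=np.ones(3), counts=np.ones(3),
                                 max_lag=3.0)
        with pytest.raises(ValueError, match="4"):
            fit_variogram(emp)


class TestOrdinaryKriging:
    @pytest.fixture
    def points(self, rng):
        return pd.DataFrame({"x": rng.uniform(0, 20, 5),
                             "y": rng.uniform(0, 20, 5),
                             "residual": rng.normal(0, 2, 5)})

    @pytest.mark.parametrize("family", FAMILIES)
    @pytest.mark.parametrize("n_data", [2, 3, 5])
    def test_matches_dense_solve_oracle(self, family, n_data, points, rng):
        vgm = VariogramModel(family, 0.2, 1.5, 12.0)
        data = points.iloc[:n_data]
        targets = rng.uniform(-5, 25, (8, 2))
        preds, variances = krige_points(data, vgm, targets)
        xy = data[["x", "y"]].to_numpy()
        vals = data["residual"].to_numpy()
        for t, p, v in zip(targets, preds, variances):
            p0, v0 = dense_ok_oracle(xy, vals, vgm, t)
            assert p == pytest.approx(p0, abs=1e-8)
            assert v == pytest.approx(v0, abs=1e-8)

    def test_single_point_returns_datum(self):
        one = pd.DataFrame({"x": [3.0], "y": [4.0], "residual": [7.5]})
        vgm = VariogramModel("exponential", 0.1, 1.0, 5.0)
        preds, _, weights = krige_points(one, vgm, [[0.0, 0.0], [9.0, 9.0]],
                                         return_weights=True)
        assert np.allclose(preds, 7.5)
        assert np.allclose(weights, 1.0)

    def test_midpoint_weights_by_symmetry(self):
        two = pd.DataFrame({"x": [0.0, 10.0], "y": [0.0, 0.0],
                            "residual": [2.0, 4.0]})
        vgm = VariogramModel("spherical", 0.3, 1.0, 8.0)
        preds, _, weights = krige_points(two, vgm, [[5.0, 0.0]],
                                         return_weights=True)
        assert weights[0] == pytest.approx([0.5, 0.5], abs=1e-10)
        assert preds[0] == pytest.approx(3.0)

    def test_pure_nugget_gives_equal_weights(self, points):
        vgm = VariogramModel("spherical", 2.0, 0.0, 5.0)
        preds, _, weights = krige_points(points, vgm, [[10.0, 10.0]],
                                         return_weights=True)
        assert np.allclose(weights, 0.2)
        assert preds[0] == pytest.approx(points.residual.mean())

    def test_exact_interpolation_with_zero_nugget(self, points):
        vgm = VariogramModel("exponential", 0.0, 2.0, 10.0)
        preds, variances = krige_points(points, vgm,
                                        points[["x", "y"]].to_numpy())
        assert np.abs(preds - points.residual.to_numpy()).max() < 1e-6
        assert variances.max() <= 1e-8

    def test_variance_far_from_data_approaches_sill(self, points):
        vgm = VariogramModel("spherical", 0.5, 1.5, 10.0)
        _, variances = krige_points(points, vgm, [[1e4, 1e4]])
        assert variances[0] == pytest.approx(vgm.sill, rel=0.25)

    def test_weights_sum_to_one_on_grid(self, scattered_residuals):
        vgm = VariogramModel("spherical", 0.2, 1.0, 15.0)
        targets = np.column_stack([np.tile(np.arange(0, 50, 5.0), 10),
                                   np.repeat(np.arange(0, 50, 5.0), 10)])
        _, _, weights = krige_points(scattered_residuals, vgm, targets,
                                     return_weights=True)
        assert np.abs(weights.sum(axis=1) - 1.0).max() < 1e-8

    def test_duplicates_averaged_before_solving(self):
        pts = pd.DataFrame({"x": [0.0, 0.0, 8.0], "y": [0.0, 0.0, 0.0],
                            "residual": [1.0, 3.0, 5.0]})
        vgm = VariogramModel("exponential", 0.0, 1.0, 6.0)
        preds, _ = krige_points(pts, vgm, [[0.0, 0.0]])
        assert preds[0] == pytest.approx(2.0, abs=1e-6)

    def test_grid_kriging_matches_point_kriging(self, scattered_residuals):
        vgm = VariogramModel("exponential", 0.1, 1.0, 12.0)
        transform = GridTransform(0.0, 10.0, 1.0, 1.0)
        field = ordinary_krige(scattered_residuals, vgm, transform, (10, 10))
        rr, cc = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        x, y = transform.cell_center(rr.ravel(), cc.ravel())
        preds, variances = krige_points(scattered_residuals, vgm,
                                        np.column_stack([x, y]))
        assert np.allclose(field.prediction.values.ravel(), preds)
        assert np.allclose(field.variance.values.ravel(), variances)
        assert np.nanmin(field.variance.values) >= 0

    def test_local_neighborhood_with_full_k_matches_global(
            self, scattered_residuals):
        vgm = VariogramModel("spherical", 0.1, 1.0, 20.0)
        transform = GridTransform(0.0, 8.0, 2.0, 2.0)
        global_field = ordinary_krige(scattered_residuals, vgm, transform,
                                      (4, 4))
        local_field = ordinary_krige(scattered_residuals, vgm, transform,
                                     (4, 4),
                                     neighborhood=len(scattered_residuals))
        assert np.allclose(global_field.prediction.values,
                           local_field.prediction.values, atol=1e-8)

    def test_mask_cells_stay_nodata(self, scattered_residuals):
        vgm = VariogramModel("spherical", 0.1, 1.0, 20.0)
        transform = GridTransform(0.0, 6.0, 2.0, 2.0)
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, :] = True
        field = ordinary_krige(scattered_residuals, vgm, transform, (3, 3),
                               mask=mask)
        assert np.isfinite(field.prediction.values[0]).all()
        assert np.isnan(field.prediction.values[1:]).all()


class TestRegressionKrige:
    @pytest.fixture
    def transform(self):
        return GridTransform(0.0, 90.0, 30.0, 30.0)

    def test_zero_residuals_identity(self, transform, rng):
        base = Raster(rng.uniform(10, 100, (3, 3)), transform, "agb")
        out = regression_krige(base, Raster(np.zeros((3, 3)), transform))
        assert np.array_equal(out.values, base.values)

    def test_cellwise_sum_clamp_and_nodata(self, transform):
        base = Raster(np.array([[80.0, 2.0], [np.nan, 50.0]]), transform)
        resid = Raster(np.array([[-3.0, -10.0], [1.0, np.nan]]), transform)
        out = regression_krige(base, resid)
        assert out.values[0, 0] == pytest.approx(77.0)
        assert out.values[0, 1] == 0.0          # negative sum clamped
        assert np.isnan(out.values[1, 0]) and np.isnan(out.values[1, 1])

    def test_georeference_mismatch_rejected(self, transform):
        base = Raster(np.zeros((3, 3)), transform)
        other = Raster(np.zeros((3, 3)), GridTransform(1.0, 90.0, 30.0, 30.0))
        with pytest.raises(ValueError, match="mismatch"):
            regression_krige(base, other)


class _StubModel(RegressionModel):
    """Predicts a fixed callable of the table; enough for residual tests."""

    def __init__(self, fn, predictors=("dem",)):
        super().__init__(kind="rf", estimator=None, predictors=list(predictors))
        self._fn = fn

    def predict(self, table):
        return self._fn(table)


class TestComputeResiduals:
    def test_perfect_fit_gives_zero_residuals(self, rng):
        table = pd.DataFrame({"x": rng.uniform(0, 9, 20),
                              "y": rng.uniform(0, 9, 20),
                              "dem": rng.normal(size=20)})
        table["agb_mg_ha"] = 50 + 2 * table.dem
        model = _StubModel(lambda t: (50 + 2 * t.dem).to_numpy())
        res = compute_residuals(model, table)
        assert np.allclose(res.residual, 0.0)
        assert np.array_equal(res.x, table.x) and np.array_equal(res.y, table.y)

    def test_constant_model_gives_centered_responses(self, rng):
        table = pd.DataFrame({"x": rng.uniform(0, 9, 30),
                              "y": rng.uniform(0, 9, 30),
                              "agb_mg_ha": rng.uniform(20, 120, 30)})
        mean = table.agb_mg_ha.mean()
        model = _StubModel(lambda t: np.full(len(t), mean))
        res = compute_residuals(model, table)
        assert np.allclose(res.residual,
                           table.agb_mg_ha.to_numpy() - mean)

    def test_missing_coordinates_rejected(self):
        model = _StubModel(lambda t: np.zeros(len(t)))
        with pytest.raises(ValueError, match="coordinates"):
            compute_residuals(model, pd.DataFrame({"agb_mg_ha": [1.0, 2.0]}))
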