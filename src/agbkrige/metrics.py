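"""Accuracy metrics and the relative-improvement (RI) index.

For estimates x_i against held-out observations y_i:

* R^2   = 1 - sum (x_i - y_i)^2 / sum (y_i - ybar)^2
* RMSE  = sqrt(mean (x_i - y_i)^2)
* MAE   = mean |x_i - y_i|
* bias  = mean (x_i - y_i)

All means use the population (divide-by-n) convention. The RI index
compares a regression-kriging model with its base learner:
RI = (RMSE_base - RMSE_rk) / RMSE_base, reported as a percentage to two
decimals; negative values mean kriging hurt.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .rasters import Raster


@dataclass
class EvaluationReport:
    label: str
    n_test: int
    r_squared: float
    rmse: float
    mae: float
    bias: float
    ri_fraction: float | None = None
    ri_percent: float | None = None
    ri_baseline: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SurfaceSummary:
    min: float
    max: float
    mean: float
    sd: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(predicted, observed, label: str = "") -> EvaluationReport:
    """Accuracy of estimates against observations (see module docstring).

    R^2 is reported as NaN when the observations are all identical.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs to evaluate")
    err = x - y
    ss_res = float(np.sum(err ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return EvaluationReport(
        label=label, n_test=n,
        r_squared=r2,
        rmse=float(np.sqrt(np.mean(err ** 2))),
        mae=float(np.mean(np.abs(err))),
        bias=float(np.mean(err)),
    )


def relative_improvement(rmse_base: float, rmse_rk: float) -> tuple[float, float]:
    """RI of a kriged model over its base: (fraction, percent).

    Percent is the fraction x 100, unrounded; format with two decimals
    for reporting. Negative when the kriged model is worse.
    """
    if rmse_base <= 0:
        raise ValueError("baseline RMSE must be > 0")
    frac = (rmse_base - rmse_rk) / rmse_base
    return float(frac), float(100.0 * frac)


def format_ri_percent(rmse_base: float, rmse_rk: float) -> str:
    """RI as the two-decimal percentage string used in reports."""
    _, pct = relative_improvement(rmse_base, rmse_rk)
    return f"{pct:.2f}%"


def surface_summary(surface: Raster | np.ndarray) -> SurfaceSummary:
    """Min/max/mean/sd (population) over non-nodata cells of a surface."""
    values = surface.values if isinstance(surface, Raster) else np.asarray(surface)
    live = values[np.isfinite(values)]
    if live.size == 0:
        raise ValueError("surface has no non-nodata cells")
    return SurfaceSummary(
        min=float(live.min()), max=float(live.max()),
        mean=float(live.mean()), sd=float(live.std()),
    )
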