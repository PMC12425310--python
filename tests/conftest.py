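import numpy as np
import pandas as pd
import pytest

from agbkrige import (SimulationConfig, VariogramModel, extract_at_plots,
                      apply_forest_mask, simulate_dataset, split_train_test)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale landscape: 40x40 cells, 120 plots, same structure as the
    default study conditions."""
    return SimulationConfig(grid_rows=40, grid_cols=40, n_plots=120, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    stack, truth, plots, records = small_dataset
    masked = apply_forest_mask(stack)
    table = extract_at_plots(masked, plots)
    return split_train_test(table, 0.8, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def scattered_residuals(rng):
    """60 scattered points with a smooth-ish value surface."""
    x = rng.uniform(0, 50, 60)
    y = rng.uniform(0, 50, 60)
    vals = np.sin(x / 12.0) + 0.5 * np.cos(y / 9.0) + rng.normal(0, 0.1, 60)
    return pd.DataFrame({"x": x, "y": y, "residual": vals})
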