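"""Shared fixtures: small synthetic worlds and fitted models."""

from __future__ import annotations

import numpy as np
import pytest

from maxsdm.grids import EnvLayer, EnvStack, GridSpec
from maxsdm.occurrences import thin_to_grid
from maxsdm.synth import (
    TrueModel,
    generate_env_stack,
    sample_occurrences,
    true_suitability,
)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(n_rows=24, n_cols=32, x_min=100.0, y_min=22.0, cell_size=0.25)


@pytest.fixture(scope="session")
def small_stack(small_grid) -> EnvStack:
    """4-variable 24x32 world, mild correlation, fixed seed."""
    specs = {
        "bio2": {"mean": 8.0, "sd": 2.0, "smoothness": 3.0},
        "bio9": {"mean": 12.0, "sd": 6.0, "smoothness": 3.0},
        "Ele": {"mean": 800.0, "sd": 500.0, "smoothness": 2.0},
        "UVB4": {"mean": 2800.0, "sd": 400.0, "smoothness": 3.0},
    }
    corr = np.eye(4)
    corr[1, 2] = corr[2, 1] = -0.5
    return generate_env_stack(
        n_rows=small_grid.n_rows, n_cols=small_grid.n_cols,
        cell_size=small_grid.cell_size,
        origin=(small_grid.x_min, small_grid.y_min),
        var_specs=specs, target_corr=corr, seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_stack):
    model = TrueModel(
        intercept=-4.0,
        linear_coeffs={"bio2": -4.0, "Ele": -3.5},
        quadratic_coeffs={"bio9": -3.5},
    )
    return true_suitability(model, small_stack)


@pytest.fixture(scope="session")
def small_occurrences(small_stack, small_truth):
    occ = sample_occurrences(small_truth, 60, seed=11, noise=0.05, species="test_sp")
    return thin_to_grid(occ, small_stack.grid, small_stack.joint_mask)


def toy_layer(values, name="v", x_min=0.0, y_min=0.0, cell_size=1.0, nodata=-9999.0):
    """Small helper: EnvLayer from a 2-D list, nodata-aware."""
    values = np.asarray(values, dtype=float)
    grid = GridSpec(
        n_rows=values.shape[0], n_cols=values.shape[1],
        x_min=x_min, y_min=y_min, cell_size=cell_size, nodata=nodata,
    )
    mask = values != nodata
    return EnvLayer(name=name, grid=grid, values=np.where(mask, values, 0.0), mask=mask)
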