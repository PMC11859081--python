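"""Synthetic world generators: correlation targeting, ground-truth
response, occurrence sampling, scenario deltas, PA masks."""

import numpy as np
import pytest
from scipy import stats

from maxsdm.grids import GridSpec
from maxsdm.synth import (
    PAMask,
    ScenarioDelta,
    TrueModel,
    generate_env_stack,
    generate_pa_mask,
    make_future_stack,
    sample_occurrences,
    true_suitability,
)

TWO_VARS = {
    "v1": {"mean": 0.0, "sd": 1.0, "smoothness": 2.0},
    "v2": {"mean": 10.0, "sd": 3.0, "smoothness": 2.0},
}


def sample_r(stack):
    X = stack.valid_values()
    return float(np.corrcoef(X, rowvar=False)[0, 1])


class TestGenerateEnvStack:
    def test_independent_target_gives_near_zero_sample_r(self):
        stack = generate_env_stack(
            n_rows=64, n_cols=64, var_specs=TWO_VARS, target_corr=np.eye(2), seed=1
        )
        assert abs(sample_r(stack)) < 0.15

    def test_strong_target_correlation_recovered(self):
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        stack = generate_env_stack(
            n_rows=64, n_cols=64, var_specs=TWO_VARS, target_corr=corr, seed=1
        )
        assert sample_r(stack) == pytest.approx(0.9, abs=0.1)

    def test_deterministic_given_seed(self):
        a = generate_env_stack(n_rows=16, n_cols=16, seed=5)
        b = generate_env_stack(n_rows=16, n_cols=16, seed=5)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.values, lb.values)

    def test_marginal_mean_sd_respected(self):
        stack = generate_env_stack(
            n_rows=64, n_cols=64, var_specs=TWO_VARS, target_corr=np.eye(2), seed=3
        )
        v2 = stack["v2"].values
        assert v2.mean() == pytest.approx(10.0, abs=0.5)
        assert v2.std() == pytest.approx(3.0, rel=0.15)

    def test_non_psd_target_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues -1, 3
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_env_stack(n_rows=8, n_cols=8, var_specs=TWO_VARS, target_corr=bad)


class TestTrueSuitability:
    def test_null_model_is_uniform_cloglog_constant(self, small_stack):
        model = TrueModel(intercept=0.0, linear_coeffs={"bio2": 0.0},
                          quadratic_coeffs={})
        with pytest.raises(ValueError):
            model.active_vars  # no nonzero coefficient
        # intercept-only surface evaluates the link at eta = 0
        truth = true_suitability(
            TrueModel(intercept=0.0, linear_coeffs={"bio2": 1e-300},
                      quadratic_coeffs={}),
            small_stack,
        )
        assert truth.valid() == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_large_negative_intercept_drives_suitability_to_zero(self, small_stack):
        truth = true_suitability(
            TrueModel(intercept=-30.0, linear_coeffs={"bio2": 1e-6},
                      quadratic_coeffs={}),
            small_stack,
        )
        assert truth.valid().max() < 1e-10

    def test_monotone_in_linear_predictor(self, small_stack):
        lo = true_suitability(
            TrueModel(intercept=-1.0, linear_coeffs={"bio2": -1.0},
                      quadratic_coeffs={}), small_stack)
        hi = true_suitability(
            TrueModel(intercept=0.0, linear_coeffs={"bio2": -1.0},
                      quadratic_coeffs={}), small_stack)
        assert np.all(hi.valid() >= lo.valid())

    def test_invariant_to_variable_location_scale(self):
        """Standardization makes truth independent of var_specs mean/sd."""
        model = TrueModel(intercept=-1.0, linear_coeffs={"v1": -2.0},
                          quadratic_coeffs={"v2": -1.0})
        a = generate_env_stack(n_rows=32, n_cols=32, var_specs=TWO_VARS,
                               target_corr=np.eye(2), seed=9)
        rescaled = {
            "v1": {**TWO_VARS["v1"], "mean": 100.0, "sd": 7.0},
            "v2": {**TWO_VARS["v2"], "mean": -5.0, "sd": 0.2},
        }
        b = generate_env_stack(n_rows=32, n_cols=32, var_specs=rescaled,
                               target_corr=np.eye(2), seed=9)
        np.testing.assert_allclose(
            true_suitability(model, a).values, true_suitability(model, b).values,
            atol=1e-10,
        )

    def test_missing_variable_raises(self, small_stack):
        model = TrueModel(intercept=0.0, linear_coeffs={"nope": 1.0},
                          quadratic_coeffs={})
        with pytest.raises(KeyError):
            true_suitability(model, small_stack)


class TestSampleOccurrences:
    def test_samples_concentrate_where_truth_is_high(self, small_stack, small_truth):
        grid_mean = small_truth.valid().mean()
        wins = 0
        for seed in range(20):
            occ = sample_occurrences(small_truth, 41, seed=seed, noise=0.0)
            vals = [
                small_truth.values[small_stack.grid.cell_of(lon, lat)]
                for lon, lat in occ.records
            ]
            wins += np.mean(vals) > grid_mean
        assert wins == 20

    def test_full_noise_is_uniform_over_cells(self, small_truth):
        occ = sample_occurrences(small_truth, 300, seed=4, noise=1.0, replace=True)
        grid = small_truth.grid
        idx = [
            r * grid.n_cols + c
            for r, c in (grid.cell_of(lon, lat) for lon, lat in occ.records)
        ]
        n_cells = int(small_truth.mask.sum())
        res = stats.kstest(np.asarray(idx) / n_cells, "uniform")
        assert res.pvalue > 0.01

    def test_all_points_inside_valid_mask(self, small_stack, small_truth):
        occ = sample_occurrences(small_truth, 50, seed=2)
        for lon, lat in occ.records:
            cell = small_stack.grid.cell_of(lon, lat)
            assert cell is not None and small_truth.mask[cell]

    def test_without_replacement_capacity_error(self, small_truth):
        n_valid = int(small_truth.mask.sum())
        with pytest.raises(ValueError, match="without replacement"):
            sample_occurrences(small_truth, n_valid + 1, seed=0, replace=False)

    def test_deterministic_given_seed(self, small_truth):
        a = sample_occurrences(small_truth, 20, seed=6)
        b = sample_occurrences(small_truth, 20, seed=6)
        assert a.records == b.records


class TestFutureStack:
    def test_identity_delta_copies_stack(self, small_stack):
        future = make_future_stack(
            small_stack, ScenarioDelta(label="null", shift={"bio9": 0.0},
                                       scale={"bio9": 1.0})
        )
        for la, lb in zip(small_stack.layers, future.layers):
            np.testing.assert_array_equal(la.values, lb.values)

    def test_shift_moves_mean_exactly(self, small_stack):
        future = make_future_stack(
            small_stack, ScenarioDelta(label="w", shift={"bio9": 2.0})
        )
        assert future["bio9"].values.mean() == pytest.approx(
            small_stack["bio9"].values.mean() + 2.0, rel=1e-12
        )

    def test_scale_shrinks_sd(self, small_stack):
        future = make_future_stack(
            small_stack, ScenarioDelta(label="d", scale={"UVB4": 0.9})
        )
        assert future["UVB4"].values.std() == pytest.approx(
            0.9 * small_stack["UVB4"].values.std(), rel=1e-12
        )

    def test_unknown_layer_rejected(self, small_stack):
        with pytest.raises(KeyError):
            make_future_stack(small_stack, ScenarioDelta(label="x", shift={"zzz": 1.0}))

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            ScenarioDelta(label="x", scale={"bio9": 0.0})


class TestPAMask:
    def test_zero_coverage_is_empty(self, small_grid):
        assert generate_pa_mask(small_grid, 0.0, seed=0).member.sum() == 0

    def test_coverage_within_20_percent_of_target(self):
        grid = GridSpec(n_rows=64, n_cols=64, x_min=0.0, y_min=0.0, cell_size=0.25)
        for seed in range(5):
            mask = generate_pa_mask(grid, 0.03, seed=seed)
            assert 0.024 <= mask.coverage <= 0.036

    def test_deterministic_given_seed(self, small_grid):
        a = generate_pa_mask(small_grid, 0.05, seed=3)
        b = generate_pa_mask(small_grid, 0.05, seed=3)
        np.testing.assert_array_equal(a.member, b.member)

    def test_impossible_target_rejected(self, small_grid):
        with pytest.raises(ValueError):
            generate_pa_mask(small_grid, 1.5, seed=0)

    def test_mask_shape_checked(self, small_grid):
        with pytest.raises(ValueError):
            PAMask(grid=small_grid, member=np.zeros((2, 2), dtype=bool))
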