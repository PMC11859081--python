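"""MaxEnt engine: objective/oracle agreement, normalization, gain
monotonicity, interpretation outputs, AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from maxsdm.features import build_features
from maxsdm.grids import assemble_stack
from maxsdm.maxent import (
    MaxentModel,
    auc,
    compute_betas,
    fit_maxent,
    fit_occurrence_model,
    jackknife_importance,
    penalized_gain,
    percent_contribution,
    predict,
    replicate_auc,
    response_curve,
)
from maxsdm.occurrences import thin_to_grid
from maxsdm.synth import (
    TrueModel,
    generate_env_stack,
    make_future_stack,
    sample_occurrences,
    true_suitability,
)
from maxsdm.synth import ScenarioDelta


def tiny_problem(n_bg=20, n_pres=6, v=1, fc="LQ", seed=0):
    rng = np.random.default_rng(seed)
    bg_X = rng.uniform(0, 10, size=(n_bg, v))
    bg_F, exp = build_features(bg_X, [f"v{i}" for i in range(v)], fc)
    pres_idx = rng.choice(n_bg, n_pres, replace=False)
    return bg_F[pres_idx], bg_F, exp


def manual_model(bg_X, fc, lambdas, var_names=None):
    var_names = var_names or [f"v{i}" for i in range(bg_X.shape[1])]
    bg_F, exp = build_features(bg_X, var_names, fc)
    lambdas = np.asarray(lambdas, dtype=float)
    eta = bg_F @ lambdas
    ln_z = float(logsumexp(eta))
    p = np.exp(eta - ln_z)
    return MaxentModel(
        expansion=exp, lambdas=lambdas, fc=fc, rm=1.0, ln_z=ln_z,
        entropy=float(-(p @ (eta - ln_z))), n_presence=2,
        n_background=bg_X.shape[0], gain=0.0,
    )


class TestFitOracles:
    def test_no_signal_constant_features_stay_at_zero(self):
        """A feature identical on presences and background carries no
        gradient, so its coefficient stays 0 and raw is uniform."""
        pres_F, bg_F, exp = tiny_problem(v=1, fc="L")
        const = np.full_like(bg_F, 0.5)
        model = fit_maxent(np.full((6, 1), 0.5), const, exp, rm=1.0)
        assert np.all(model.lambdas == 0.0)
        eta = const @ model.lambdas
        raw = np.exp(eta - model.ln_z)
        np.testing.assert_allclose(raw, 1.0 / 20, rtol=1e-12)

    def test_two_feature_gain_matches_dense_grid_search(self):
        """Brute-force oracle: exhaustive lambda grid, step 0.01 over
        [-10, 10]^2, on a 20-cell background."""
        pres_F, bg_F, exp = tiny_problem(n_bg=20, v=1, fc="LQ", seed=1)
        model = fit_maxent(pres_F, bg_F, exp, rm=1.0)
        betas = compute_betas(pres_F, bg_F, exp.specs, 1.0)
        mp = pres_F.mean(axis=0)
        grid = np.arange(-10.0, 10.0 + 1e-9, 0.01)
        best = -np.inf
        for l1 in grid:  # chunk one axis; vectorize the other
            eta = np.outer(grid, bg_F[:, 1]) + l1 * bg_F[:, 0]  # (G, 20)
            gains = (
                np.log(20.0)
                + l1 * mp[0] + grid * mp[1]
                - logsumexp(eta, axis=1)
                - betas[0] * abs(l1) - betas[1] * np.abs(grid)
            )
            best = max(best, float(gains.max()))
        assert model.gain >= best - 1e-9  # CD at least as good as the grid
        assert abs(model.gain - best) < 1e-3

    @pytest.mark.parametrize("rm", [0.5, 1.0, 2.0])
    def test_three_feature_gain_matches_lbfgs_split_oracle(self, rm):
        """Independent smooth oracle: split lambda into positive and
        negative parts and solve the equivalent bound-constrained
        problem with L-BFGS-B."""
        pres_F, bg_F, exp = tiny_problem(n_bg=30, n_pres=8, v=3, fc="L", seed=2)
        model = fit_maxent(pres_F, bg_F, exp, rm=rm, tol=1e-9)
        betas = compute_betas(pres_F, bg_F, exp.specs, rm)
        mp = pres_F.mean(axis=0)

        def neg_gain_split(u):
            lam = u[:3] - u[3:]
            return -(mp @ lam - logsumexp(bg_F @ lam) - betas @ (u[:3] + u[3:]))

        res = minimize(
            neg_gain_split, np.zeros(6), method="L-BFGS-B",
            bounds=[(0, None)] * 6, options={"ftol": 1e-14, "gtol": 1e-12},
        )
        oracle_gain = np.log(30.0) - res.fun
        assert abs(model.gain - oracle_gain) < 1e-3

    def test_perfectly_separating_binary_feature_concentrates_mass(self):
        """With weak regularization, a binary variable on which all
        presences sit at 1 should carry nearly all raw probability."""
        bg_X = np.repeat([[0.0], [1.0]], 10, axis=0)
        bg_F, exp = build_features(bg_X, ["v0"], "L")
        pres_F = np.ones((12, 1))
        model = fit_maxent(pres_F, bg_F, exp, rm=0.1)
        eta = bg_F @ model.lambdas
        raw = np.exp(eta - model.ln_z)
        assert raw[bg_X[:, 0] == 1.0].sum() >= 0.95


class TestFitInvariants:
    def test_penalized_gain_non_decreasing_per_cycle(self, small_occurrences, small_stack):
        model = fit_occurrence_model(small_occurrences, small_stack, fc="LQH", rm=1.0)
        gains = np.asarray(model.cycle_gains)
        assert np.all(np.diff(gains) >= -1e-10)

    def test_raw_sums_to_one_on_training_background(self, small_occurrences, small_stack):
        model = fit_occurrence_model(small_occurrences, small_stack, fc="LQ", rm=1.0)
        raw = predict(model, small_stack, transform="raw")
        assert raw.valid().sum() == pytest.approx(1.0, abs=1e-9)

    def test_l1_norm_non_increasing_in_rm(self, small_occurrences, small_stack):
        norms = [
            np.abs(
                fit_occurrence_model(small_occurrences, small_stack, fc="LQ", rm=rm).lambdas
            ).sum()
            for rm in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_warm_start_reaches_same_optimum(self, small_occurrences, small_stack):
        cold = fit_occurrence_model(small_occurrences, small_stack, fc="LQ", rm=1.0)
        hot = fit_occurrence_model(
            small_occurrences, small_stack, fc="LQ", rm=1.0,
            lam0=np.ones_like(cold.lambdas),
        )
        assert hot.gain == pytest.approx(cold.gain, abs=1e-4)

    def test_non_convergence_flagged_not_raised(self, small_occurrences, small_stack):
        model = fit_occurrence_model(
            small_occurrences, small_stack, fc="LQ", rm=1.0, max_cycles=1
        )
        assert model.converged is False

    def test_huge_penalty_gives_null_model(self, small_occurrences, small_stack):
        model = fit_occurrence_model(small_occurrences, small_stack, fc="LQ", rm=1e6)
        assert model.k == 0
        assert model.gain == pytest.approx(0.0, abs=1e-12)

    def test_gain_equals_reference_objective(self, small_occurrences, small_stack):
        """The incremental objective the fitter tracks equals the
        reference penalized-gain evaluated at the final coefficients."""
        from maxsdm.maxent import background_matrix, presence_matrix

        bg_X = background_matrix(small_stack)
        bg_F, exp = build_features(bg_X, small_stack.names, "LQ")
        pres_X = presence_matrix(small_occurrences, small_stack, exp.var_names)
        pres_F = exp.transform(pres_X)
        model = fit_maxent(pres_F, bg_F, exp, rm=1.0)
        betas = compute_betas(pres_F, bg_F, exp.specs, 1.0)
        ref = penalized_gain(model.lambdas, pres_F, bg_F, betas)
        assert model.gain == pytest.approx(ref, abs=1e-9)


class TestPredict:
    def test_null_model_predicts_uniform_cloglog(self, small_occurrences, small_stack):
        model = fit_occurrence_model(small_occurrences, small_stack, fc="LQ", rm=1e6)
        pred = predict(model, small_stack)
        assert pred.valid() == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_projection_beyond_range_clamps_to_boundary(self, small_occurrences, small_stack):
        model = fit_occurrence_model(small_occurrences, small_stack, fc="LQH", rm=1.0)
        far = make_future_stack(
            small_stack, ScenarioDelta(label="far", shift={"bio9": 1e4})
        )
        farther = make_future_stack(
            small_stack, ScenarioDelta(label="farther", shift={"bio9": 1e6})
        )
        np.testing.assert_array_equal(
            predict(model, far).values, predict(model, farther).values
        )

    def test_missing_variable_raises_key_error(self, small_occurrences, small_stack):
        model = fit_occurrence_model(small_occurrences, small_stack, fc="L", rm=1.0)
        with pytest.raises(KeyError):
            predict(model, small_stack.subset(small_stack.names[:2]))

    def test_json_round_trip_preserves_predictions(self, tmp_path, small_occurrences, small_stack):
        model = fit_occurrence_model(small_occurrences, small_stack, fc="LQH", rm=1.0)
        model.to_json(tmp_path / "m.json")
        back = MaxentModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(
            predict(model, small_stack).values, predict(back, small_stack).values
        )


class TestInterpretation:
    def test_single_variable_contribution_is_100(self, small_stack, small_truth):
        occ = sample_occurrences(small_truth, 40, seed=3, species="s")
        occ = thin_to_grid(occ, small_stack.grid, small_stack.joint_mask)
        stack = small_stack.subset(["bio2"])
        model = fit_occurrence_model(occ, stack, fc="LQ", rm=1.0, trace=True)
        contrib = percent_contribution(model)
        assert contrib["bio2"] == pytest.approx(100.0)

    def test_contributions_sum_to_100(self, small_occurrences, small_stack):
        model = fit_occurrence_model(
            small_occurrences, small_stack, fc="LQH", rm=1.0, trace=True
        )
        assert percent_contribution(model).sum() == pytest.approx(100.0, abs=1e-9)

    def test_exact_twin_layers_credit_is_deterministic(self, small_occurrences, small_stack):
        """Cyclic descent credits the first-visited member of an exact
        duplicate pair; the twins' combined share is stable and the
        attribution is reproducible run to run."""
        twin = small_stack["bio2"].copy(name="zz_twin")
        stack = assemble_stack(small_stack.layers + [twin])
        a = percent_contribution(
            fit_occurrence_model(small_occurrences, stack, fc="LQ", rm=1.0, trace=True)
        )
        b = percent_contribution(
            fit_occurrence_model(small_occurrences, stack, fc="LQ", rm=1.0, trace=True)
        )
        pd.testing.assert_series_equal(a, b)
        solo = percent_contribution(
            fit_occurrence_model(small_occurrences, small_stack, fc="LQ", rm=1.0, trace=True)
        )
        assert a["bio2"] + a["zz_twin"] == pytest.approx(solo["bio2"], abs=5.0)

    def test_trace_required_for_contribution(self, small_occurrences, small_stack):
        model = fit_occurrence_model(small_occurrences, small_stack, fc="LQ", rm=1.0)
        with pytest.raises(ValueError, match="trace"):
            percent_contribution(model)

    def test_jackknife_noise_variable_has_negligible_solo_gain(self):
        specs = {
            "signal": {"mean": 0.0, "sd": 1.0, "smoothness": 3.0},
            "noise": {"mean": 0.0, "sd": 1.0, "smoothness": 3.0},
        }
        stack = generate_env_stack(
            n_rows=64, n_cols=64, var_specs=specs, target_corr=np.eye(2), seed=13
        )
        truth = true_suitability(
            TrueModel(intercept=-4.0, linear_coeffs={"signal": -5.0},
                      quadratic_coeffs={}),
            stack,
        )
        occ = sample_occurrences(truth, 200, seed=1, noise=0.0, species="s")
        occ = thin_to_grid(occ, stack.grid, stack.joint_mask)
        table = jackknife_importance(occ, stack, fc="LQ", rm=1.0)
        assert table.loc["noise", "gain_with_only"] < 0.05
        assert table.loc["signal", "gain_with_only"] > 0.2
        # leave-one-out gains never beat the full model (nested objective)
        assert (table["gain_without"] <= table["gain_all"] + 1e-3).all()

    def test_response_monotone_for_positive_linear_model(self):
        bg = np.random.default_rng(5).uniform(0, 10, size=(50, 1))
        model = manual_model(bg, "L", [3.0])
        curve = response_curve(model, "v0")
        assert (np.diff(curve["response"]) >= -1e-12).all()

    def test_null_model_response_is_flat_at_cloglog_constant(self, small_occurrences, small_stack):
        model = fit_occurrence_model(small_occurrences, small_stack, fc="LQ", rm=1e6)
        curve = response_curve(model, "bio2")
        assert curve["response"].values == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_concave_lq_response_peaks_at_stationary_point(self):
        """eta = 4 z - 4 z^2 on the scaled axis peaks at z = 0.5, i.e.
        the middle of the background range."""
        bg = np.linspace(0.0, 10.0, 101).reshape(-1, 1)
        model = manual_model(bg, "LQ", [4.0, -4.0])
        curve = response_curve(model, "v0", n_points=201)
        peak = curve["v0"][curve["response"].idxmax()]
        assert peak == pytest.approx(5.0, abs=0.1)
        resp = curve["response"].values
        top = resp.argmax()
        assert (np.diff(resp[: top + 1]) >= -1e-12).all()
        assert (np.diff(resp[top:]) <= 1e-12).all()


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_hand_counted_half(self):
        # wins: 0.9 beats 0.5 twice; losses: 0.1 loses twice -> 2/4
        assert auc([0.9, 0.1], [0.5, 0.5]) == 0.5

    def test_all_ties_give_half(self):
        assert auc([0.3, 0.3], [0.3, 0.3, 0.3]) == 0.5

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        sp = rng.normal(1.0, 1.0, 37)
        sb = rng.normal(0.0, 1.0, 211)
        y = np.r_[np.ones(37), np.zeros(211)]
        assert auc(sp, sb) == pytest.approx(
            roc_auc_score(y, np.r_[sp, sb]), abs=1e-12
        )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.5])

    def test_replicate_auc_deterministic(self, small_occurrences, small_stack):
        a, _ = replicate_auc(small_occurrences, small_stack, "LQ", 1.0, seed=0)
        b, _ = replicate_auc(small_occurrences, small_stack, "LQ", 1.0, seed=0)
        assert a == b
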