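import numpy as np
import pytest
from scipy import stats

from velotf import dynamics as dyn
from velotf.io import GeneProblem, SkipGene

from conftest import make_problem, random_params


class TestProfiles:
    def test_profile_y_known_values(self):
        p = dyn.DynParams(np.zeros(1), alpha=1.0, beta=0.0, theta=0.0, gamma=1.0)
        assert dyn.profile_y(0.25, p) == pytest.approx(1.0)
        p2 = dyn.DynParams(np.zeros(1), alpha=2.0, beta=5.0, theta=0.0, gamma=1.0)
        assert dyn.profile_y(0.0, p2) == pytest.approx(5.0)
        p3 = dyn.DynParams(np.zeros(1), alpha=1.3, beta=0.2, theta=0.4, gamma=1.0)
        assert dyn.profile_y(0.1, p3) == pytest.approx(
            1.3 * np.sin(0.2 * np.pi + 0.4) + 0.2)

    def test_drive_identity_against_derivative(self):
        """WX(t) must equal dy/dt + gamma*y(t) analytically."""
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 100, endpoint=False)
        for _ in range(100):
            p = random_params(rng)
            dy = 2 * np.pi * p.alpha * np.cos(2 * np.pi * t + p.theta)
            lhs = dyn.profile_wx(t, p)
            rhs = dy + p.gamma * dyn.profile_y(t, p)
            assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_small_gamma_limit_is_pure_derivative(self):
        p = dyn.DynParams(np.zeros(1), alpha=1.5, beta=0.3, theta=0.7,
                          gamma=1e-9)
        t = np.linspace(0, 1, 50, endpoint=False)
        expect = 2 * np.pi * 1.5 * np.cos(2 * np.pi * t + 0.7)
        np.testing.assert_allclose(dyn.profile_wx(t, p), expect, atol=1e-6)

    def test_hand_evaluated_point(self):
        # alpha=1, beta=0, gamma=2*pi, theta=0, t=0: phi=pi/4,
        # WX = sqrt(8*pi^2)*sin(pi/4) = 2*pi
        p = dyn.DynParams(np.zeros(1), alpha=1.0, beta=0.0, theta=0.0,
                          gamma=2 * np.pi)
        assert dyn.profile_wx(0.0, p) == pytest.approx(2 * np.pi)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(alpha=-1.0), dict(gamma=0.0), dict(theta=4.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(W=np.zeros(2), alpha=1.0, beta=0.0, theta=0.0, gamma=1.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            dyn.DynParams(**base)

    def test_weight_bound_enforced(self):
        with pytest.raises(ValueError):
            dyn.DynParams(np.array([25.0]), 1.0, 0.0, 0.0, 1.0)

    def test_omega_fixed(self):
        p = dyn.DynParams(np.zeros(1), 1.0, 0.0, 0.0, 1.0)
        assert p.omega == pytest.approx(2 * np.pi)


def line_problem(p, t, rng, n_tfs=2):
    """Cells exactly on the model curve for given parameters/times."""
    y = dyn.profile_y(t, p)
    wx = dyn.profile_wx(t, p)
    x2 = rng.normal(0, 1, t.size)
    x1 = (wx - p.W[1] * x2) / p.W[0]
    return GeneProblem("T", np.vstack([x1, x2]), y, ["A", "B"],
                       np.arange(t.size), np.ones(2), 1.0)


class TestAssignLatentTime:
    def test_exact_on_grid_point_recovered(self):
        rng = np.random.default_rng(1)
        p = dyn.DynParams(np.array([2.0, -1.0]), 1.1, 0.2, 0.5, 2.0)
        t_true = np.arange(50) / 100.0  # all on the grid
        prob = line_problem(p, t_true, rng)
        t = dyn.assign_latent_time(prob, p, grid=100)
        np.testing.assert_allclose(t, t_true)

    def test_agrees_with_finer_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = random_params(rng, n_tfs=2)
            p.W = np.array([1.0, 0.5])
            n = 20
            X = rng.normal(0, 2, size=(2, n))
            y = rng.normal(0, 2, size=n)
            prob = GeneProblem("T", X, y, ["A", "B"], np.arange(n),
                               np.ones(2), 1.0)
            grid = 50
            t = dyn.assign_latent_time(prob, p, grid=grid)
            fine = 500
            tf_grid = np.arange(fine) / fine
            cx, cy = dyn.profile_wx(tf_grid, p), dyn.profile_y(tf_grid, p)
            wx = p.W @ X
            d = (wx[:, None] - cx) ** 2 + (y[:, None] - cy) ** 2
            d_fine = d.min(axis=1)
            t_fine = tf_grid[np.argmin(d, axis=1)]
            d_coarse = (wx - dyn.profile_wx(t, p)) ** 2 \
                + (y - dyn.profile_y(t, p)) ** 2
            # within one coarse spacing of the fine optimum, or (on a
            # cross-branch near-tie) within the distance achievable by
            # sliding one spacing along the curve from the fine optimum
            gap = np.minimum(np.abs(t - t_fine), 1 - np.abs(t - t_fine))
            speed = 2 * np.pi * p.alpha * np.sqrt(1 + 4 * np.pi**2 + p.gamma**2)
            bound = (np.sqrt(d_fine) + speed / grid) ** 2
            assert np.all((gap <= 1.0 / grid + 1e-12)
                          | (d_coarse <= bound + 1e-9))

    def test_identical_cells_identical_times(self):
        p = dyn.DynParams(np.array([1.0]), 1.0, 0.0, 0.0, 1.0)
        X = np.array([[0.7, 0.7]])
        y = np.array([0.3, 0.3])
        prob = GeneProblem("T", X, y, ["A"], np.arange(2), np.ones(1), 1.0)
        t = dyn.assign_latent_time(prob, p)
        assert t[0] == t[1]


class TestComputeLoss:
    def test_zero_on_curve(self):
        rng = np.random.default_rng(3)
        p = dyn.DynParams(np.array([2.0, -1.0]), 1.1, 0.2, 0.5, 2.0)
        t = rng.uniform(0, 1, 40)
        prob = line_problem(p, t, rng)
        state = dyn.compute_loss(prob, p, t)
        assert state.loss == pytest.approx(0.0, abs=1e-18)

    def test_displaced_cell_contributes_squared_distance(self):
        p = dyn.DynParams(np.array([1.0]), 1.0, 0.0, 0.0, 1.0)
        t = np.array([0.0])
        wx0, y0 = dyn.profile_wx(0.0, p), dyn.profile_y(0.0, p)
        X = np.array([[wx0 + 1.0]])
        y = np.array([y0 + 1.0])
        prob = GeneProblem("T", X, y, ["A"], np.arange(1), np.ones(1), 1.0)
        state = dyn.compute_loss(prob, p, t)
        assert state.loss == pytest.approx(2.0)
        assert state.residuals[0] == pytest.approx(2.0)  # signed by y excess

    def test_loss_matches_negative_log_likelihood_shape(self):
        """Loss and the Gaussian log-likelihood agree up to sigma terms."""
        rng = np.random.default_rng(4)
        prob, _ = make_problem(n_cells=100, seed=5, noise_sd=0.1)
        p = dyn.init_parameters(prob, 1)[0]
        t = dyn.assign_latent_time(prob, p)
        state = dyn.compute_loss(prob, p, t)
        fit = dyn.GeneDynamicsFit(
            target_name="T", tf_names=prob.tf_names, params=p, state=state,
            velocity=np.zeros(prob.n_cells), loss_trace=np.array([state.loss]),
            init_index=0, x_scale=prob.x_scale, y_scale=prob.y_scale,
            kept_cell_indices=prob.kept_cell_indices)
        n, sig = prob.n_cells, state.sigma
        expect = -n * np.log(np.sqrt(2 * np.pi) * sig) - state.loss / (2 * sig**2)
        assert fit.log_likelihood == pytest.approx(expect)


class TestUpdateWeights:
    def test_recovers_exact_single_tf_weight(self):
        rng = np.random.default_rng(5)
        p = dyn.DynParams(np.array([1.0]), 1.2, 0.1, 0.3, 2.0)
        t = rng.uniform(0, 1, 200)
        X = (dyn.profile_wx(t, p) / 3.0)[None, :]
        prob = GeneProblem("T", X, dyn.profile_y(t, p), ["A"],
                           np.arange(200), np.ones(1), 1.0)
        w = dyn.update_weights(prob, p, t)
        assert w[0] == pytest.approx(3.0, abs=1e-6)

    def test_zero_targets_give_zero_weights(self):
        rng = np.random.default_rng(6)
        # beta*gamma = -0 and alpha tiny -> targets ~0
        p = dyn.DynParams(np.array([1.0, 1.0]), 1e-5, 0.0, 0.0, 1.0)
        X = rng.normal(0, 1, size=(2, 100))
        prob = GeneProblem("T", X, np.zeros(100), ["A", "B"],
                           np.arange(100), np.ones(2), 1.0)
        w = dyn.update_weights(prob, p, rng.uniform(0, 1, 100))
        np.testing.assert_allclose(w, 0.0, atol=1e-4)

    def test_bound_is_active_when_optimum_outside(self):
        rng = np.random.default_rng(7)
        p = dyn.DynParams(np.array([1.0]), 1.2, 0.1, 0.3, 2.0)
        t = rng.uniform(0, 1, 200)
        X = (dyn.profile_wx(t, p) / 50.0)[None, :]  # unconstrained opt at 50
        prob = GeneProblem("T", X, dyn.profile_y(t, p), ["A"],
                           np.arange(200), np.ones(1), 1.0)
        w = dyn.update_weights(prob, p, t)
        assert w[0] == pytest.approx(20.0, abs=1e-6)

    def test_non_finite_input_rejected(self):
        p = dyn.DynParams(np.array([1.0]), 1.0, 0.0, 0.0, 1.0)
        prob = GeneProblem("T", np.array([[np.nan]]), np.array([1.0]), ["A"],
                           np.arange(1), np.ones(1), 1.0)
        with pytest.raises(ValueError):
            dyn.update_weights(prob, p, np.array([0.1]))


class TestUpdateShapeParams:
    def test_noiseless_parameter_recovery_at_true_times(self):
        rng = np.random.default_rng(8)
        p_true = dyn.DynParams(np.array([2.0, -1.0]), 1.4, 0.6, -0.9, 3.0)
        t = rng.uniform(0, 1, 400)
        prob = line_problem(p_true, t, rng)
        p0 = dyn.DynParams(p_true.W.copy(), 1.0, 0.0, 0.1, 1.0)
        alpha, beta, theta, gamma = dyn.update_shape_params(prob, p0, t)
        assert alpha == pytest.approx(p_true.alpha, rel=1e-3)
        assert beta == pytest.approx(p_true.beta, rel=1e-3, abs=1e-3)
        assert theta == pytest.approx(p_true.theta, rel=1e-3, abs=1e-3)
        assert gamma == pytest.approx(p_true.gamma, rel=1e-3)

    def test_no_increase_from_optimum(self):
        rng = np.random.default_rng(9)
        p_true = dyn.DynParams(np.array([2.0, -1.0]), 1.4, 0.6, -0.9, 3.0)
        t = rng.uniform(0, 1, 200)
        prob = line_problem(p_true, t, rng)
        before = dyn.compute_loss(prob, p_true, t).loss
        out = dyn.DynParams(p_true.W, *dyn.update_shape_params(prob, p_true, t))
        after = dyn.compute_loss(prob, out, t).loss
        assert after <= before + 1e-9

    def test_constraints_respected(self):
        prob, _ = make_problem(n_cells=150, seed=10, noise_sd=0.1)
        p = dyn.init_parameters(prob, 1)[0]
        t = dyn.assign_latent_time(prob, p)
        alpha, beta, theta, gamma = dyn.update_shape_params(prob, p, t)
        assert alpha > 0 and gamma > 0 and -np.pi < theta < np.pi


class TestInitParameters:
    def one_tf_problem(self, x, y):
        return GeneProblem("T", np.asarray(x, float)[None, :],
                           np.asarray(y, float), ["A"],
                           np.arange(len(y)), np.ones(1), 1.0)

    def test_monotone_tf_initial_weight_one(self):
        prob = self.one_tf_problem([1, 2, 3, 4, 5], [2, 4, 5, 8, 9])
        p = dyn.init_parameters(prob, 1)[0]
        assert p.W[0] == pytest.approx(1.0)

    def test_anticorrelated_tf_initial_weight_minus_one(self):
        prob = self.one_tf_problem([5, 4, 3, 2, 1], [2, 4, 5, 8, 9])
        assert dyn.init_parameters(prob, 1)[0].W[0] == pytest.approx(-1.0)

    def test_alpha_beta_from_range(self):
        prob = self.one_tf_problem([1, 2, 3], [0.5, 1.5, 2.5])
        p = dyn.init_parameters(prob, 1)[0]
        assert p.alpha == pytest.approx(1.0)
        assert p.beta == pytest.approx(1.5)

    def test_constant_target_skips(self):
        prob = self.one_tf_problem([1, 2, 3], [2, 2, 2])
        with pytest.raises(SkipGene):
            dyn.init_parameters(prob, 1)

    def test_theta_starts_evenly_spaced(self):
        prob = self.one_tf_problem([1, 2, 3, 4], [1, 3, 2, 4])
        thetas = [p.theta for p in dyn.init_parameters(prob, 4)]
        np.testing.assert_allclose(
            thetas, [-3 * np.pi / 4, -np.pi / 4, np.pi / 4, 3 * np.pi / 4])


class TestFitGene:
    def test_noiseless_recovery(self):
        prob, truth = make_problem(n_cells=500, n_tfs=10, seed=12, noise_sd=0.0)
        fit = dyn.fit_gene(prob, n_iters=40)
        assert fit.state.loss < 0.01 * prob.n_cells
        rho = stats.spearmanr(truth.true_velocity[prob.kept_cell_indices],
                              fit.velocity).statistic
        assert rho > 0.99
        wn = dyn.normalize_weights(fit.params.W, prob.X.mean(axis=1))
        strong = np.abs(wn) > 0.5
        w_raw = fit.params.W * prob.y_scale / prob.x_scale
        assert np.all(np.sign(w_raw[strong]) == np.sign(truth.true_W[strong]))

    def test_loss_trace_non_increasing(self):
        prob, _ = make_problem(n_cells=300, n_tfs=8, seed=13, noise_sd=0.1)
        fit = dyn.fit_gene(prob)
        diffs = np.diff(fit.loss_trace)
        assert np.all(diffs <= 1e-9)
        assert fit.state.loss == pytest.approx(fit.loss_trace[-1])

    def test_deterministic_across_runs(self):
        prob, _ = make_problem(n_cells=200, n_tfs=6, seed=14, noise_sd=0.1)
        f1 = dyn.fit_gene(prob, seed=0)
        f2 = dyn.fit_gene(prob, seed=0)
        np.testing.assert_array_equal(f1.params.W, f2.params.W)
        assert f1.params.gamma == f2.params.gamma
        np.testing.assert_array_equal(f1.state.t, f2.state.t)

    def test_velocity_is_definitional(self):
        prob, _ = make_problem(n_cells=200, n_tfs=6, seed=15, noise_sd=0.1)
        fit = dyn.fit_gene(prob)
        expect = fit.params.W @ prob.X - fit.params.gamma * prob.y
        np.testing.assert_allclose(fit.velocity, expect)


class TestNormalizeWeights:
    def test_stated_example(self):
        wn = dyn.normalize_weights(np.array([2.0, -4.0, 1.0]), np.ones(3))
        np.testing.assert_allclose(wn, [0.5, -1.0, 0.25])
        sel = dyn.select_high_influence_tfs(np.array([2.0, -4.0, 1.0]), np.ones(3))
        np.testing.assert_array_equal(sel, [1])  # 0.5 is not > 0.5

    def test_single_tf_is_unit(self):
        np.testing.assert_allclose(
            np.abs(dyn.normalize_weights(np.array([-3.0]), np.array([2.0]))), 1.0)

    def test_expression_scale_invariance(self):
        w = np.array([1.0, -2.0, 0.5])
        x = np.array([3.0, 1.0, 2.0])
        np.testing.assert_allclose(dyn.normalize_weights(w, x),
                                   dyn.normalize_weights(w, 10 * x))

    def test_all_zero_influence_rejected(self):
        with pytest.raises(ValueError):
            dyn.normalize_weights(np.zeros(3), np.ones(3))
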