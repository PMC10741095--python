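"""Network forward/gradient, the adaptive update rule, PSO and training."""

import numpy as np
import pytest

from etorque import bpnet
from etorque.dataio import NetworkParams
from etorque.errors import IntegrityError


def _random_params(seed=0, scale=1.0, target=(-1.0, 1.0)) -> NetworkParams:
    rng = np.random.default_rng(seed)
    return NetworkParams(w_in=scale * rng.normal(size=(3, 5)),
                         b_in=scale * rng.normal(size=3),
                         w_out=scale * rng.normal(size=(1, 3)),
                         b_out=scale * rng.normal(size=1),
                         target_scale=target)


class TestForward:
    def test_tansig_worked_values(self):
        assert bpnet.tansig(0.0) == 0.0
        assert bpnet.tansig(1.0) == pytest.approx(2 / (1 + np.exp(-2)) - 1, rel=1e-12)
        assert bpnet.tansig(1.0) == pytest.approx(0.76159, abs=1e-5)
        np.testing.assert_allclose(bpnet.tansig(np.array([0.3, -0.3])),
                                   np.tanh([0.3, -0.3]), atol=1e-14)

    def test_zero_network_outputs_zero(self):
        params = NetworkParams(np.zeros((3, 5)), np.zeros(3), np.zeros((1, 3)),
                               np.zeros(1), target_scale=(-2.0, 2.0))
        tau_scaled, tau = bpnet.forward(params, np.ones(5))
        assert tau_scaled == 0.0
        # scaled 0 is the midpoint of the torque range
        assert tau == pytest.approx(0.0)

    def test_output_always_inside_tansig_range(self, rng):
        params = _random_params(scale=5.0)
        S = rng.normal(size=(100, 5)) * 10
        tau_scaled, _ = bpnet.forward(params, S)
        assert np.all(np.abs(tau_scaled) < 1.0)

    def test_wrong_input_dimension(self):
        with pytest.raises(IntegrityError):
            bpnet.forward(_random_params(), np.ones(4))

    def test_target_scaling_round_trip(self):
        scale = (-1.5, 6.0)
        y = np.linspace(-1.5, 6.0, 13)
        np.testing.assert_allclose(
            bpnet.unscale_targets(bpnet.scale_targets(y, scale), scale), y,
            atol=1e-12)
        s = bpnet.scale_targets(y, scale)
        assert s.min() == pytest.approx(-0.9) and s.max() == pytest.approx(0.9)


class TestGradient:
    def test_zero_at_perfect_fit(self, rng):
        params = _random_params(1)
        S = rng.normal(size=(20, 5))
        y, _ = bpnet.forward(params, S)
        g = bpnet.gradient(params, S, y)
        assert np.max(np.abs(g.ravel())) < 1e-14

    def test_matches_finite_differences(self, rng):
        """Central-difference oracle, 3 random parameter points."""
        S = rng.normal(size=(10, 5))
        y = rng.uniform(-0.8, 0.8, 10)
        eps = 1e-6
        for seed in range(3):
            params = _random_params(seed)
            g = bpnet.gradient(params, S, y).ravel()
            fd = np.empty_like(g)
            theta = np.concatenate([params.w_in.ravel(), params.b_in,
                                    params.w_out.ravel(), params.b_out])
            for i in range(theta.size):
                tp, tm = theta.copy(), theta.copy()
                tp[i] += eps
                tm[i] -= eps
                fd[i] = (bpnet.batch_mse(bpnet._decode(tp, (-1, 1)), S, y)
                         - bpnet.batch_mse(bpnet._decode(tm, (-1, 1)), S, y)) / (2 * eps)
            rel = np.max(np.abs(g - fd)) / max(np.max(np.abs(fd)), 1e-12)
            assert rel < 1e-4

    def test_batch_duplication_invariance(self, rng):
        params = _random_params(2)
        S = rng.normal(size=(8, 5))
        y = rng.uniform(-0.5, 0.5, 8)
        g1 = bpnet.gradient(params, S, y).ravel()
        g2 = bpnet.gradient(params, np.vstack([S, S]),
                            np.concatenate([y, y])).ravel()
        np.testing.assert_allclose(g1, g2, atol=1e-14)


class TestUpdateStep:
    def _grads(self, rng, flip=1.0):
        g = bpnet.Gradients(w_in=rng.normal(size=(3, 5)), b_in=rng.normal(size=3),
                            w_out=rng.normal(size=(1, 3)), b_out=rng.normal(size=1))
        g2 = bpnet.Gradients(w_in=flip * g.w_in, b_in=flip * g.b_in,
                             w_out=flip * g.w_out, b_out=flip * g.b_out)
        return g, g2

    def test_no_momentum_is_plain_descent(self, rng):
        cfg = bpnet.TrainingConfig(momentum=0.0)
        params = _random_params(0)
        g, g_prev = self._grads(rng)
        new, eta, lam = bpnet.update_step(params, g, g_prev, 0.01, cfg)
        assert lam == 1  # identical direction
        np.testing.assert_allclose(new.w_in, params.w_in - eta * g.w_in, atol=1e-15)

    def test_aligned_gradients_double_rate(self, rng):
        cfg = bpnet.TrainingConfig()
        g, g_prev = self._grads(rng, flip=1.0)
        _, eta, lam = bpnet.update_step(_random_params(), g, g_prev, 0.01, cfg)
        assert (lam, eta) == (1, pytest.approx(0.02))

    def test_opposed_gradients_halve_rate(self, rng):
        cfg = bpnet.TrainingConfig()
        g, g_prev = self._grads(rng, flip=-1.0)
        _, eta, lam = bpnet.update_step(_random_params(), g, g_prev, 0.01, cfg)
        assert (lam, eta) == (-1, pytest.approx(0.005))

    def test_rate_clamped_to_bounds(self, rng):
        cfg = bpnet.TrainingConfig(lr_bounds=(1e-5, 0.015))
        g, g_prev = self._grads(rng, flip=1.0)
        _, eta, _ = bpnet.update_step(_random_params(), g, g_prev, 0.01, cfg)
        assert eta == pytest.approx(0.015)

    def test_first_step_without_history(self, rng):
        cfg = bpnet.TrainingConfig()
        g, _ = self._grads(rng)
        new, eta, lam = bpnet.update_step(_random_params(), g, None, 0.01, cfg)
        assert (lam, eta) == (0, 0.01)


class TestSplit:
    def test_printed_cohort_arithmetic(self):
        tr, va, te = bpnet.split_622(1680, seed=0)
        assert (len(tr), len(va), len(te)) == (1008, 336, 336)

    def test_minimum_size(self):
        tr, va, te = bpnet.split_622(10, seed=0)
        assert (len(tr), len(va), len(te)) == (6, 2, 2)
        with pytest.raises(IntegrityError):
            bpnet.split_622(9, seed=0)

    def test_disjoint_cover_and_determinism(self):
        a = bpnet.split_622(100, seed=5)
        b = bpnet.split_622(100, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        allidx = np.concatenate(a)
        assert np.array_equal(np.sort(allidx), np.arange(100))


def _toy_problem(n=200, seed=0):
    """Realizable regression problem: targets from a standard-normal teacher net."""
    rng = np.random.default_rng(seed)
    S = rng.normal(size=(n, 5))
    teacher = _random_params(seed=seed + 100, scale=1.0)
    y_scaled, _ = bpnet.forward(teacher, S)
    return S, y_scaled, teacher


class TestPSO:
    def test_zero_iterations_returns_valid_params(self):
        S, y, _ = _toy_problem(50)
        cfg = bpnet.PSOConfig(t_max=0, n_particles=10, seed=0)
        params = bpnet.pso_init(S, y, cfg)
        assert params.w_in.shape == (3, 5)

    def test_swarm_improves_over_initial_best(self):
        S, y, _ = _toy_problem(100)
        init_best = bpnet.batch_mse(
            bpnet.pso_init(S, y, bpnet.PSOConfig(t_max=0, n_particles=20, seed=9)),
            S, y)
        final_best = bpnet.batch_mse(
            bpnet.pso_init(S, y, bpnet.PSOConfig(t_max=60, n_particles=20, seed=9)),
            S, y)
        assert final_best <= init_best

    def test_beats_uniform_random_init_on_linear_target(self):
        """Median over 10 seeds: PSO start MSE below random-init start MSE."""
        rng = np.random.default_rng(0)
        S = rng.normal(size=(100, 5))
        y = np.clip(0.3 * S[:, 0] - 0.2 * S[:, 3], -0.9, 0.9)
        wins = 0
        for seed in range(10):
            cfg = bpnet.PSOConfig(t_max=40, n_particles=20, seed=seed)
            pso_mse = bpnet.batch_mse(bpnet.pso_init(S, y, cfg), S, y)
            r = np.random.default_rng(seed + 500)
            rand_mse = bpnet.batch_mse(
                bpnet._decode(r.uniform(-0.5, 0.5, bpnet.N_PARAMS), (-1, 1)), S, y)
            wins += pso_mse < rand_mse
        assert wins >= 6  # median strictly better

    def test_determinism(self):
        S, y, _ = _toy_problem(60)
        cfg = bpnet.PSOConfig(t_max=30, n_particles=15, seed=3)
        p1 = bpnet.pso_init(S, y, cfg)
        p2 = bpnet.pso_init(S, y, cfg)
        np.testing.assert_array_equal(p1.w_in, p2.w_in)
        np.testing.assert_array_equal(p1.b_out, p2.b_out)


class TestTraining:
    def test_realizable_targets_reach_goal(self):
        """Targets produced by a 5-3-1 teacher net are learnable to 1e-3."""
        hits = 0
        for seed in range(10):
            S, y_scaled, _ = _toy_problem(n=150, seed=seed)
            y = bpnet.unscale_targets(y_scaled, (-2.0, 2.0))
            cfg = bpnet.TrainingConfig(seed=seed, patience=3000)
            _, hist = bpnet.train(S, y, S[:30], y[:30], cfg,
                                  target_scale=(-2.0, 2.0))
            hits += hist.train_mse[-1] <= 1e-3
        assert hits >= 8

    def test_goal_met_at_init_returns_immediately(self):
        S, y_scaled, teacher = _toy_problem(50, seed=4)
        y = bpnet.unscale_targets(y_scaled, (-1.0, 1.0))
        cfg = bpnet.TrainingConfig(seed=0)
        params, hist = bpnet.train(S, y, S, y, cfg, init=teacher,
                                   target_scale=(-1.0, 1.0))
        assert len(hist.train_mse) == 1
        assert hist.stop_reason == "goal"

    def test_early_stop_index_is_argmin_plus_patience(self, rng):
        # unlearnable noise: validation MSE stops improving quickly
        S = rng.normal(size=(40, 5))
        y = rng.uniform(-3, 3, 40)
        S_val = rng.normal(size=(40, 5))
        y_val = rng.uniform(-3, 3, 40)
        cfg = bpnet.TrainingConfig(seed=1, patience=10, goal_mse=1e-12)
        _, hist = bpnet.train(S, y, S_val, y_val, cfg)
        if hist.stop_reason == "early-stop":
            assert len(hist.val_mse) == hist.best_epoch + cfg.patience
            assert np.argmin(hist.val_mse) + 1 == hist.best_epoch

    def test_history_is_deterministic(self):
        S, y_scaled, _ = _toy_problem(80, seed=6)
        y = bpnet.unscale_targets(y_scaled, (-1.0, 1.0))
        cfg = bpnet.TrainingConfig(seed=2, max_epochs=200, patience=200)
        _, h1 = bpnet.train(S[:60], y[:60], S[60:], y[60:], cfg)
        _, h2 = bpnet.train(S[:60], y[:60], S[60:], y[60:], cfg)
        np.testing.assert_array_equal(h1.train_mse, h2.train_mse)
        np.testing.assert_array_equal(h1.lr, h2.lr)

    def test_best_validation_params_returned(self):
        S, y_scaled, _ = _toy_problem(100, seed=8)
        y = bpnet.unscale_targets(y_scaled, (-1.0, 1.0))
        cfg = bpnet.TrainingConfig(seed=3, max_epochs=300, patience=300)
        params, hist = bpnet.train(S[:70], y[:70], S[70:], y[70:], cfg)
        val_mse = bpnet.batch_mse(params, S[70:],
                                  bpnet.scale_targets(y[70:], params.target_scale))
        assert val_mse == pytest.approx(min(hist.val_mse), rel=1e-9)
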