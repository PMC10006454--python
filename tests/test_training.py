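"""Loss functions, surrogate gradients, optimiser and the training loop."""

import numpy as np
import pytest

import spikecog as sc


class TestMaskedMSE:
    def test_hand_worked_two_step_example(self):
        """1 output, 1 trial, 2 steps, mask (1, 5): (0.25 + 5) / (2 * 6)."""
        y = np.array([[0.5], [0.0]])
        yhat = np.array([[0.0], [1.0]])
        m = np.array([[1.0], [5.0]])
        assert sc.masked_mse(y, yhat, m) == pytest.approx(0.4375, abs=1e-15)

    def test_zero_when_outputs_match(self, rng):
        y = rng.random((10, 2, 3))
        m = rng.random((10, 2, 3)) + 0.1
        assert sc.masked_mse(y, y, m) == 0.0

    def test_invariant_to_mask_rescaling(self, rng):
        y = rng.random((8, 2, 3))
        t = rng.random((8, 2, 3))
        m = rng.random((8, 2, 3))
        for mode in ("paper", "masked_mean"):
            a = sc.masked_mse(y, t, m, mode)
            b = sc.masked_mse(y, t, 2 * m, mode)
            assert a == pytest.approx(b, rel=1e-12)

    def test_denominator_modes_differ_by_constant_factor(self, rng):
        y, t = rng.random((6, 2, 3)), rng.random((6, 2, 3))
        m = np.ones((6, 2, 3))
        paper = sc.masked_mse(y, t, m, "paper")
        mean = sc.masked_mse(y, t, m, "masked_mean")
        assert mean == pytest.approx(paper * 3 * 2 * 6, rel=1e-12)

    def test_all_zero_mask_is_an_error(self):
        with pytest.raises(ValueError):
            sc.masked_mse(np.ones((4, 1, 3)), np.ones((4, 1, 3)),
                          np.zeros((4, 1, 3)))


class TestRateRegularizer:
    def test_rates_above_threshold_sum(self):
        # f = [10, 40, 50] Hz at dt = 1 ms over 1000 steps
        Z = np.zeros((1000, 3))
        for i, f in enumerate((10, 40, 50)):
            Z[:f, i] = 1.0
        assert sc.rate_regularizer(Z, f_th=30.0) == pytest.approx(90.0)

    def test_zero_below_threshold(self):
        Z = np.zeros((1000, 4))
        Z[:20] = 1.0  # 20 Hz everywhere
        assert sc.rate_regularizer(Z, f_th=30.0) == 0.0

    def test_threshold_zero_sums_all_rates(self):
        Z = np.zeros((1000, 3))
        Z[:10, 0] = 1.0
        Z[:25, 2] = 1.0
        assert sc.rate_regularizer(Z, f_th=0.0) == pytest.approx(35.0)

    def test_exact_threshold_counts(self):
        """H(0) = 1: a neuron firing exactly at f_th is penalised."""
        Z = np.zeros((1000, 1))
        Z[:30] = 1.0
        assert sc.rate_regularizer(Z, f_th=30.0) == pytest.approx(30.0)


class TestSurrogate:
    def test_peak_and_printed_value(self):
        assert sc.surrogate_derivative(0.65, 0.65) == 1.0
        assert sc.surrogate_derivative(0.66, 0.65, alpha=100.0) == \
            pytest.approx(0.25, rel=1e-9)

    def test_even_and_decreasing(self):
        v_th = 0.65
        d = np.linspace(0.001, 0.2, 50)
        up = sc.surrogate_derivative(v_th + d, v_th)
        dn = sc.surrogate_derivative(v_th - d, v_th)
        assert np.allclose(up, dn, rtol=1e-12)
        assert np.all(np.diff(up) < 0)


class TestGradientEquivalence:
    @pytest.mark.parametrize("seed,n_neurons,variant", [
        (0, 2, "mse"), (1, 3, "mse"), (2, 4, "mse_reg")])
    def test_forward_mode_equals_reverse_mode(self, seed, n_neurons, variant):
        """Forward sensitivity recursion vs backprop-through-time with the
        same surrogate: same gradient to high relative precision."""
        rng = np.random.default_rng(seed)
        w = sc.init_weights(n_neurons, rng=rng)
        # strong drive so spikes occur and the surrogate pathway is active
        w.w_in *= 4.0
        p = sc.default_params(n_neurons)
        maker = sc.mse_config if variant == "mse" else sc.regularized_config
        cfg = maker(n_batch=2, f_th=5.0)
        timing = sc.scaled_timing(stim_range=(10.0, 14.0), t_resp=8.0,
                                  delay_range=(4.0, 6.0))
        batch = sc.sample_batch(list(sc.ALL_TASKS), 2, rng, 0.05,
                                cfg.mask_values, timing)
        assert batch.n_steps <= 50
        gf, pf = sc.forward_sensitivities(w, p, batch, cfg)
        gb, pb = sc.bptt_gradients(w, p, batch, cfg)
        assert pf["loss"] == pb["loss"]
        for k, a in gf.as_dict().items():
            b = gb.as_dict()[k]
            scale = max(np.abs(b).max(), 1e-30)
            assert np.abs(a - b).max() / scale < 1e-6, k

    def test_readout_gradient_matches_finite_differences(self, rng,
                                                         small_batch):
        """W_out does not influence spiking, so central differences are an
        exact oracle for the analytic readout gradient."""
        batch, cfg = small_batch
        w = sc.init_weights(5, rng=rng)
        p = sc.default_params(5)
        g, _ = sc.bptt_gradients(w, p, batch, cfg)

        def loss(weights):
            tr = sc.simulate_batch(weights, batch.inputs, p, cfg.kappa)
            return sc.masked_mse(tr.Y, batch.targets, batch.mask)

        h = 1e-5
        for i, j in ((0, 0), (1, 3), (2, 4)):
            wp, wm = w.copy(), w.copy()
            wp.w_out[i, j] += h
            wm.w_out[i, j] -= h
            fd = (loss(wp) - loss(wm)) / (2 * h)
            assert g.dw_out[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-12)

    def test_unmasked_residual_carries_no_gradient(self, rng):
        """Gradients vanish when every masked entry has zero residual; an
        all-zero mask itself is rejected as an undefined loss."""
        w = sc.init_weights(3, rng=rng)
        p = sc.default_params(3)
        cfg = sc.mse_config(n_batch=1)
        timing = sc.scaled_timing(stim_range=(10.0, 10.0), t_resp=5.0)
        batch = sc.sample_batch([sc.ALL_TASKS[0]], 1, rng, 0.05,
                                (1.0, 5.0), timing)
        trace = sc.simulate_batch(w, batch.inputs, p, cfg.kappa)
        batch.mask[:] = 0.0
        batch.mask[3, 0, 1] = 5.0
        batch.targets = trace.Y.copy()   # masked entries match exactly
        g, parts = sc.bptt_gradients(w, p, batch, cfg)
        assert parts["loss"] == 0.0
        for arr in g.as_dict().values():
            assert np.all(arr == 0.0)
        batch.mask[:] = 0.0
        with pytest.raises(ValueError):
            sc.bptt_gradients(w, p, batch, cfg)

    def test_loss_decomposes_exactly(self, rng):
        w = sc.init_weights(4, rng=rng)
        w.w_in *= 4.0
        p = sc.default_params(4)
        timing = sc.scaled_timing(stim_range=(20.0, 20.0), t_resp=10.0)
        reg = sc.regularized_config(n_batch=2, lambda_reg=0.7, f_th=5.0)
        batch = sc.sample_batch(list(sc.ALL_TASKS[:4]), 2, rng, 0.05,
                                reg.mask_values, timing)
        _, parts = sc.bptt_gradients(w, p, batch, reg)
        assert parts["loss"] == parts["mse"] + 0.7 * parts["e_r"]
        # lambda = 0 recovers the pure-MSE gradient bit for bit
        g0, _ = sc.bptt_gradients(w, p, batch,
                                  sc.regularized_config(n_batch=2,
                                                        lambda_reg=0.0))
        g1, _ = sc.bptt_gradients(w, p, batch,
                                  sc.mse_config(n_batch=2,
                                                mask_values=(0.1, 1.0),
                                                tau_out=50.0))
        for k, a in g0.as_dict().items():
            assert np.array_equal(a, g1.as_dict()[k])


class TestOptimizer:
    def test_sgd_is_plain_descent(self, rng):
        w = sc.init_weights(4, rng=rng)
        before = w.copy()
        g = sc.GradientSet(np.ones_like(w.w_in), np.ones_like(w.w_rec),
                           np.ones_like(w.w_out), np.ones_like(w.b))
        cfg = sc.mse_config(optimizer="sgd", eta=0.1)
        sc.apply_update(w, g, sc.OptimizerState(), cfg)
        assert np.allclose(w.w_in, before.w_in - 0.1)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(w.w_rec[off], before.w_rec[off] - 0.1)
        assert np.all(np.diag(w.w_rec) == 0.0)

    def test_adam_constant_gradient_step_magnitude(self, rng):
        """With a constant gradient the bias-corrected Adam step is eta."""
        w = sc.init_weights(3, rng=rng)
        g = sc.GradientSet(np.full_like(w.w_in, 0.37),
                           np.full_like(w.w_rec, 0.37),
                           np.full_like(w.w_out, -2.0),
                           np.full_like(w.b, -2.0))
        cfg = sc.mse_config(eta=0.01)
        opt = sc.OptimizerState()
        before = w.copy()
        sc.apply_update(w, g, opt, cfg)
        assert np.allclose(np.abs(w.b - before.b), 0.01, rtol=1e-6)
        steps = np.abs(w.w_in - before.w_in)
        assert np.allclose(steps, 0.01, rtol=1e-6)

    def test_non_finite_gradient_aborts(self, rng):
        w = sc.init_weights(3, rng=rng)
        g = sc.GradientSet(np.zeros_like(w.w_in), np.zeros_like(w.w_rec),
                           np.full_like(w.w_out, np.nan), np.zeros_like(w.b))
        with pytest.raises(FloatingPointError):
            sc.apply_update(w, g, sc.OptimizerState(), sc.mse_config())


class TestTrainLoop:
    def test_zero_learning_rate_leaves_weights_unchanged(self, rng):
        w = sc.init_weights(6, rng=rng)
        before = w.copy()
        p = sc.default_params(6)
        cfg = sc.mse_config(n_epoch=1, n_batch=2, eta=0.0, optimizer="sgd")
        timing = sc.scaled_timing(stim_range=(20.0, 20.0), t_resp=10.0)
        _, hist = sc.train(w, p, cfg, list(sc.ALL_TASKS[:2]), rng,
                           timing=timing)
        assert np.array_equal(w.w_rec, before.w_rec)
        assert np.array_equal(w.w_out, before.w_out)
        assert np.isfinite(hist[0]["loss"])

    def test_same_seed_reproduces_weight_trajectory(self):
        p = sc.default_params(6)
        cfg = sc.mse_config(n_epoch=3, n_batch=2, eta=5e-3)
        timing = sc.scaled_timing(stim_range=(20.0, 30.0), t_resp=10.0)
        results = []
        for _ in range(2):
            streams = sc.seed_streams(42)
            w = sc.init_weights(6, rng=streams["weights"])
            w, hist = sc.train(w, p, cfg, list(sc.ALL_TASKS[:2]),
                               streams["trials"], timing=timing)
            results.append((w, [h["loss"] for h in hist]))
        (w1, l1), (w2, l2) = results
        assert np.array_equal(w1.w_rec, w2.w_rec)
        assert np.array_equal(w1.w_out, w2.w_out)
        assert l1 == l2

    def test_smoke_training_reduces_loss(self):
        """Short DM-only run: the trailing-epoch loss falls below the
        opening-epoch loss."""
        streams = sc.seed_streams(7)
        N = 32
        w = sc.init_weights(N, rng=streams["weights"])
        p = sc.default_params(N)
        cfg = sc.mse_config(n_epoch=60, n_batch=8, eta=5e-3, seed=7)
        timing = sc.scaled_timing(stim_range=(100.0, 200.0), t_resp=100.0)
        _, hist = sc.train(w, p, cfg, [sc.task_by_name("DM1"),
                                       sc.task_by_name("Go1")],
                           streams["trials"], timing=timing)
        L = [h["loss"] for h in hist]
        assert np.mean(L[-15:]) < np.mean(L[:15])
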