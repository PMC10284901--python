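"""Tests of the recurrent spiking network: discretized dynamics, forward
equivalence with a brute-force recurrence, surrogate gradients and training
plumbing."""

import math

import numpy as np
import pytest

from memspike.lsnn import (LSNN, LSNNConfig, NeuronConstants, alif_step,
                           classify, lif_step, load_model, save_model,
                           soft_spike, surrogate, total_loss, train)


@pytest.fixture(scope="module")
def constants():
    return NeuronConstants()


class TestNeuronConstants:
    def test_decay_factors_are_exact_exponentials(self, constants):
        assert constants.decay_alpha == pytest.approx(
            math.exp(-constants.dt / (constants.r_eff * constants.c1)), abs=0)
        assert constants.adapt_beta == pytest.approx(
            math.exp(-constants.dt / (constants.r3 * constants.c2)), abs=0)
        assert constants.adapt_beta > constants.decay_alpha

    def test_invalid_orderings_rejected(self):
        with pytest.raises(ValueError):
            NeuronConstants(v_hold_eff=5.0)  # holding above threshold
        with pytest.raises(ValueError):
            NeuronConstants(r3=1.0, c2=1e-9)  # adaptation faster than membrane


class TestLifStep:
    def test_zero_input_decays_geometrically(self, constants):
        v = 1.0
        for k in range(1, 6):
            v, z = lif_step(v, constants, 0.0)
            assert z == 0.0
            assert v == pytest.approx(constants.decay_alpha ** k)

    def test_subthreshold_fixed_point(self, constants):
        x = 0.5 * constants.v_th_eff / constants.r_eff
        v = 0.0
        for _ in range(500):
            v, z = lif_step(v, constants, x)
        assert z == 0.0
        assert v == pytest.approx(constants.r_eff * x, rel=1e-6)

    def test_matches_continuous_rc_solution_at_fine_dt(self):
        # dt = tau/100: discrete trajectory tracks v(t) = R*x*(1-exp(-t/tau))
        c = NeuronConstants(dt=1e-3, r_eff=1e5, c1=1e-6)  # tau = 0.1 s
        x = 0.9 * c.v_th_eff / c.r_eff
        tau = c.r_eff * c.c1
        v = 0.0
        for k in range(1, 200):
            v, _ = lif_step(v, c, x)
            expected = c.r_eff * x * (1.0 - math.exp(-k * c.dt / tau))
            assert v == pytest.approx(expected, rel=1e-10)

    def test_reset_contract(self, constants):
        v, z = lif_step(constants.v_th_eff * 1.5, constants,
                        constants.v_th_eff / constants.r_eff)
        assert z == 1.0
        assert v == constants.v_hold_eff


class TestAlifStep:
    def test_reduces_to_lif_without_leak(self):
        c = NeuronConstants(g_leak=0.0)
        x = 0.8 * c.v_th_eff / c.r_eff
        v1 = v2 = 0.3
        vg = 5.0  # would leak heavily if g_leak were nonzero
        for _ in range(50):
            v1, _ = lif_step(v1, c, x)
            v2, vg, _ = alif_step(v2, vg, c, x)
        assert v1 == v2

    def test_gate_decays_geometrically_without_spikes(self, constants):
        vg = 2.0
        v = 0.0
        for k in range(1, 6):
            v, vg, z = alif_step(v, vg, constants, 0.0)
            assert z == 0.0
            assert vg == pytest.approx(2.0 * constants.adapt_beta ** k)

    def test_gate_fixed_point_under_continuous_firing(self, constants):
        v, vg = 0.0, 0.0
        # drive large enough to out-compete the leak at the gate's fixed
        # point, so the unit genuinely fires every step
        x = 10.0 * constants.v_th_eff / constants.r_eff \
            + 2.0 * constants.g_leak * constants.r3 * constants.i_a
        for _ in range(20000):
            v, vg, z = alif_step(v, vg, constants, x)
        assert z == 1.0
        assert vg == pytest.approx(constants.r3 * constants.i_a, rel=1e-3)


class TestSurrogate:
    def test_triangular_shape(self):
        g = 0.4
        assert surrogate(0.0, g) == pytest.approx(g)
        assert surrogate(0.5, g) == pytest.approx(0.5 * g)
        assert surrogate(1.0, g) == 0.0
        assert surrogate(-2.0, g) == 0.0

    def test_soft_spike_derivative_is_surrogate(self):
        g = 0.3
        xs = np.linspace(-1.5, 1.5, 41)
        h = 1e-6
        fd = (soft_spike(xs + h, g) - soft_spike(xs - h, g)) / (2 * h)
        np.testing.assert_allclose(fd, surrogate(xs, g), atol=1e-5)


def small_config(**kw):
    defaults = dict(n_in=3, n_hidden=5, n_alif=2, n_out=2, max_delay=2,
                    lowpass_tau=5.0, surrogate_gamma=0.5, reg_lambda=0.01,
                    target_rate=20.0, seed=3, input_gain=1.0)
    defaults.update(kw)
    return LSNNConfig(**defaults)


class TestForward:
    def test_zero_input_zero_state_stays_silent(self):
        model = LSNN(small_config())
        fwd = model.forward(np.zeros((1, 20, 3)))
        assert fwd.z.sum() == 0
        np.testing.assert_allclose(fwd.logits, 0.0)

    def test_spikes_are_binary_and_membrane_below_threshold_after_reset(self):
        cfg = small_config(input_gain=8.0)
        model = LSNN(cfg)
        rng = np.random.default_rng(0)
        X = (rng.random((4, 60, 3)) < 0.4).astype(float)
        fwd = model.forward(X, cache=True)
        assert set(np.unique(fwd.z)) <= {0.0, 1.0}
        k = cfg.constants
        v_post = fwd.v_pre + fwd.z * (k.v_hold_eff - fwd.v_pre)
        assert np.all(v_post <= k.v_th_eff)

    @pytest.mark.parametrize("n_alif", [0, 1])
    def test_single_unit_equals_brute_force_recurrence(self, n_alif):
        """forward() with one hidden unit and no delays must match a direct
        transcription of the update equations, across 100 random instances."""
        for case in range(100):
            rng = np.random.default_rng(1000 + case)
            cfg = small_config(n_hidden=1, n_alif=n_alif, max_delay=0,
                              seed=int(rng.integers(1 << 16)))
            model = LSNN(cfg)
            T = 30
            X = (rng.random((T, 3)) < 0.4).astype(float)
            fwd = model.forward(X)

            k = cfg.constants
            a, b = k.decay_alpha, k.adapt_beta
            kap = cfg.lowpass_kappa
            w_in = model.w_in[:, 0]
            w_rec = model.w_rec[0, 0]  # structurally zero
            v = vg = f = zprev = 0.0
            logits = []
            for t in range(T):
                drive = X[t] @ w_in + w_rec * zprev
                i_leak = (k.g_leak * max(0.0, vg - k.vt_m3)) if n_alif else 0.0
                v = a * v + (1 - a) * k.r_eff * (cfg.i_unit * drive - i_leak)
                z = 1.0 if v >= k.v_th_eff else 0.0
                if z:
                    v = k.v_hold_eff
                if n_alif:
                    vg = b * vg + (1 - b) * k.r3 * k.i_a * z
                f = kap * f + z
                logits.append(f * model.w_out[0])
                zprev = z
            np.testing.assert_allclose(fwd.logits[0], np.array(logits),
                                       rtol=0, atol=1e-12)


class TestLoss:
    def test_perfect_prediction_at_target_rate_vanishes(self):
        cfg = small_config(reg_lambda=0.5)
        k = cfg.constants
        T, N = 50, cfg.n_hidden
        # raster firing exactly at the target rate
        p_fire = cfg.target_rate * k.dt
        n_spikes = int(round(p_fire * T))
        z = np.zeros((1, T, N))
        z[0, :n_spikes, :] = 1.0
        logits = np.array([[50.0, -50.0]])
        total, ce, reg = total_loss(logits, np.array([0]), z, cfg)
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_silent_network_pays_full_rate_penalty(self):
        cfg = small_config(reg_lambda=0.5)
        z = np.zeros((1, 40, cfg.n_hidden))
        _, _, reg = total_loss(np.array([[0.0, 0.0]]), np.array([0]), z, cfg)
        assert reg == pytest.approx(cfg.reg_lambda * cfg.target_rate ** 2)


class TestBackward:
    def test_bptt_gradient_matches_finite_differences(self):
        """Analytic BPTT vs central finite differences on the continuous
        surrogate-activation twin of a 3x5x2 network, to 1e-5 relative."""
        cfg = small_config()
        model = LSNN(cfg)
        rng = np.random.default_rng(0)
        X = (rng.random((2, 12, 3)) < 0.3).astype(float)
        y = np.array([0, 1])
        model.w_in *= 3
        model.w_rec *= 3
        model.w_out *= 2

        def loss():
            return model.loss(model.forward(X, mode="soft"), y)[0]

        fwd = model.forward(X, mode="soft", cache=True)
        grads = model.backward(fwd, y)
        h = 1e-5
        for key in ("w_in", "w_rec", "w_out"):
            W = getattr(model, key)
            G = grads[key]
            for idx in np.ndindex(W.shape):
                if key == "w_rec" and idx[0] == idx[1]:
                    continue  # structural zero: no autapses
                w0 = W[idx]
                W[idx] = w0 + h
                lp = loss()
                W[idx] = w0 - h
                lm = loss()
                W[idx] = w0
                fd = (lp - lm) / (2 * h)
                denom = max(abs(fd), abs(G[idx]), 1e-8)
                assert abs(fd - G[idx]) / denom < 1e-5, (key, idx)


class TestTraining:
    def _toy_data(self, n=48, T=40):
        rng = np.random.default_rng(0)
        X = np.zeros((n, T, 3), dtype=np.uint8)
        y = rng.integers(0, 2, n)
        for i in range(n):
            X[i, 5:25, int(y[i])] = 1
            X[i, 30:, 2] = 1
        return X, y

    def test_zero_epochs_returns_initial_weights(self):
        X, y = self._toy_data()
        cfg = small_config()
        ref = LSNN(cfg)
        model, hist = train(cfg, (X, y), epochs=0, seed=3)
        assert hist.losses == [] and hist.test_accuracy == []
        assert model.weights_digest() == ref.weights_digest()

    def test_identical_seed_gives_identical_history(self):
        X, y = self._toy_data()
        cfg = small_config(input_gain=8.0)
        _, h1 = train(cfg, (X, y), epochs=3, seed=3)
        _, h2 = train(cfg, (X, y), epochs=3, seed=3)
        assert h1.weights_digest == h2.weights_digest
        assert h1.losses == h2.losses

    def test_regularizer_pulls_rates_toward_target(self):
        """Starting from an over-active network, the rate penalty shrinks
        |mean rate - target| over early epochs."""
        X, y = self._toy_data()
        cfg = small_config(input_gain=8.0, reg_lambda=0.5, target_rate=20.0)
        model = LSNN(cfg)

        def rate_gap(m):
            fwd = m.forward(X.astype(float))
            fbar = fwd.z.sum(axis=(0, 1)) / (cfg.constants.dt * X.shape[0] * X.shape[1])
            return np.mean(np.abs(fbar - cfg.target_rate))

        before = rate_gap(model)
        model, _ = train(model, (X, y), epochs=25, lr=2e-2, seed=3)
        assert rate_gap(model) < before

    def test_divergence_aborts_with_report(self):
        X, y = self._toy_data()
        cfg = small_config(input_gain=8.0)
        with pytest.raises(RuntimeError, match="diverged"):
            train(cfg, (X, y), epochs=3, lr=1e308, seed=3)


class TestClassify:
    def test_softmax_probabilities(self):
        cfg = small_config()
        model = LSNN(cfg)
        # force deterministic logits via a crafted readout on a silent net
        X = np.zeros((10, 3))
        label, probs = classify(model, X)
        assert label == 0  # equal (zero) logits: tie broken to lowest index
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = small_config(input_gain=8.0)
        model = LSNN(cfg)
        rng = np.random.default_rng(0)
        X = (rng.random((30, 3)) < 0.4).astype(float)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.weights_digest() == model.weights_digest()
        assert back.classify(X)[0] == model.classify(X)[0]
        np.testing.assert_array_equal(back.d_in, model.d_in)
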