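import itertools
import json

import numpy as np
import pytest
from scipy.integrate import quad

from piezodenoise import dbn_core as dc
from piezodenoise.dbn_core import (AdamState, DBNModel, LossConfig,
                                   RBMLayer, TrainConfig, adam_step,
                                   cd_update, denoise,
                                   exact_bernoulli_loglik, fine_tune,
                                   forward, hidden_probability, joint_loss,
                                   joint_loss_grad, load_checkpoint,
                                   pretrain, rbm_energy, save_checkpoint,
                                   visible_mean)


def random_layer(D, F, unit_type, seed, scale=0.7):
    rng = np.random.default_rng(seed)
    return RBMLayer(W=scale * rng.standard_normal((D, F)),
                    a=scale * rng.standard_normal(D),
                    b=scale * rng.standard_normal(F),
                    sigma=(rng.uniform(0.5, 2.0, D)
                           if unit_type == "gauss_bernoulli"
                           else np.ones(D)),
                    unit_type=unit_type)


def bits(n):
    return np.array(list(itertools.product([0.0, 1.0], repeat=n)))


class TestEnergy:
    def test_zero_parameters_zero_energy(self):
        layer = RBMLayer(W=np.zeros((3, 2)), a=np.zeros(3), b=np.zeros(2),
                         sigma=np.ones(3))
        assert rbm_energy(np.array([1.0, 0, 1]), np.array([1.0, 1]),
                          layer) == 0.0

    def test_gaussian_energy_vanishes_at_mean_with_no_hidden(self):
        layer = random_layer(3, 2, "gauss_bernoulli", 0)
        assert rbm_energy(layer.a, np.zeros(2), layer) == pytest.approx(0.0)

    def test_direct_scalar_evaluation(self):
        layer = RBMLayer(W=np.array([[3.0]]), a=np.array([1.0]),
                         b=np.array([2.0]), sigma=np.ones(1))
        assert rbm_energy([1.0], [1.0], layer) == -6.0

    def test_shape_mismatch(self):
        layer = random_layer(3, 2, "bernoulli", 0)
        with pytest.raises(ValueError, match="match"):
            rbm_energy(np.zeros(2), np.zeros(2), layer)


class TestConditionals:
    def test_zero_parameters_give_half(self):
        layer = RBMLayer(W=np.zeros((3, 4)), a=np.zeros(3), b=np.zeros(4),
                         sigma=np.ones(3))
        np.testing.assert_allclose(
            hidden_probability(np.array([1.0, -2.0, 0.5]), layer), 0.5)
        np.testing.assert_allclose(visible_mean(np.zeros(4), layer), 0.5)

    def test_large_bias_saturates(self):
        layer = RBMLayer(W=np.zeros((2, 2)), a=np.zeros(2),
                         b=np.full(2, 30.0), sigma=np.ones(2))
        np.testing.assert_allclose(
            hidden_probability(np.zeros(2), layer), 1.0, atol=1e-9)

    def test_visible_mean_at_zero_hidden_is_bias(self):
        layer = random_layer(4, 3, "gauss_bernoulli", 1)
        np.testing.assert_allclose(visible_mean(np.zeros(3), layer),
                                   layer.a)

    @pytest.mark.parametrize("unit_type", ["bernoulli", "gauss_bernoulli"])
    @pytest.mark.parametrize("D,F", [(1, 1), (2, 3), (4, 4), (3, 2)])
    def test_hidden_conditional_matches_boltzmann_enumeration(
            self, unit_type, D, F):
        """P(h_j=1|v) from the sigmoid formula equals the posterior of the
        energy model obtained by enumerating every hidden state."""
        layer = random_layer(D, F, unit_type, seed=D * 10 + F)
        v = np.random.default_rng(7).standard_normal(D)
        if unit_type == "bernoulli":
            v = (v > 0).astype(float)
        hs = bits(F)
        weights = np.array([np.exp(-rbm_energy(v, h, layer)) for h in hs])
        posterior = (hs * weights[:, None]).sum(axis=0) / weights.sum()
        np.testing.assert_allclose(hidden_probability(v, layer), posterior,
                                   atol=1e-10)

    @pytest.mark.parametrize("D,F", [(1, 1), (2, 2), (3, 2)])
    def test_gaussian_visible_mean_matches_quadrature(self, D, F):
        """E[v_i|h] from the affine formula equals numerical integration of
        the Boltzmann conditional density."""
        layer = random_layer(D, F, "gauss_bernoulli", seed=D + 5 * F)
        h = bits(F)[-1]
        act = layer.W @ h
        for i in range(D):
            a, s, c = layer.a[i], layer.sigma[i], act[i]

            def unnorm(v):
                return np.exp(-((v - a) ** 2) / (2 * s ** 2) + (v / s) * c)

            lo, hi = a - 12 * s, a + 12 * s + 12 * abs(c) * s
            Z, _ = quad(unnorm, lo, hi, epsabs=1e-13)
            m, _ = quad(lambda v: v * unnorm(v), lo, hi, epsabs=1e-13)
            np.testing.assert_allclose(visible_mean(h, layer)[i], m / Z,
                                       rtol=1e-8)


class TestAdam:
    def test_first_step_magnitude(self):
        state = AdamState.zeros_like(np.zeros(1), alpha=0.005)
        theta, state = adam_step(np.zeros(1), np.ones(1), state)
        assert theta[0] == pytest.approx(-0.005 / (1 + 1e-8))
        assert state.t == 1

    def test_zero_gradient_no_movement(self):
        p = np.array([1.0, -2.0])
        out, _ = adam_step(p, np.zeros(2), AdamState.zeros_like(p))
        np.testing.assert_array_equal(out, p)

    def test_beta_zero_reduces_to_sign_descent(self):
        p = np.zeros(3)
        g = np.array([2.0, -0.5, 1e-3])
        state = AdamState.zeros_like(p, alpha=0.01, beta1=0.0, beta2=0.0)
        out, _ = adam_step(p, g, state)
        np.testing.assert_array_equal(out, -0.01 * g / (np.abs(g) + 1e-8))

    def test_constant_gradient_limit_is_signed_rate(self):
        p = np.zeros(2)
        g = np.array([3.0, -7.0])
        state = AdamState.zeros_like(p, alpha=0.005)
        for _ in range(10000):
            p, state = adam_step(p, g, state)
        # displacement of the final step
        p2, _ = adam_step(p, g, state)
        np.testing.assert_allclose(p2 - p, -0.005 * np.sign(g), atol=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            adam_step(np.zeros(2), np.zeros(3),
                      AdamState.zeros_like(np.zeros(2)))


class TestJointLoss:
    def test_identical_batches_zero(self, rng):
        x = rng.standard_normal((4, 8))
        assert joint_loss(x, x) == 0.0

    def test_direct_evaluation(self):
        loss = joint_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]]))
        assert loss == pytest.approx(0.7 * 0.5 + 0.3 * 1.0)

    def test_bounded_below_by_weighted_mse(self, rng):
        x, y = rng.standard_normal((3, 16)), rng.standard_normal((3, 16))
        assert joint_loss(x, y) >= 0.7 * np.mean((x - y) ** 2) - 1e-12

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.standard_normal((2, 8))
        y = rng.standard_normal((2, 8))
        _, g = joint_loss_grad(x, y)
        eps = 1e-6
        num = np.zeros_like(y)
        for idx in np.ndindex(y.shape):
            yp, ym = y.copy(), y.copy()
            yp[idx] += eps
            ym[idx] -= eps
            num[idx] = (joint_loss(x, yp) - joint_loss(x, ym)) / (2 * eps)
        np.testing.assert_allclose(g, num, atol=1e-7)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            joint_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestContrastiveDivergence:
    def test_zero_rate_is_identity(self, rng):
        layer = random_layer(4, 3, "bernoulli", 3)
        batch = (rng.random((10, 4)) > 0.5).astype(float)
        out = cd_update(layer, batch, rate=0.0, rng=rng)
        np.testing.assert_array_equal(out.W, layer.W)
        np.testing.assert_array_equal(out.a, layer.a)
        np.testing.assert_array_equal(out.b, layer.b)

    def test_empty_batch_rejected(self):
        layer = random_layer(2, 2, "bernoulli", 0)
        with pytest.raises(ValueError, match="non-empty"):
            cd_update(layer, np.empty((0, 2)), rate=0.1)

    def test_model_samples_are_a_fixed_point_on_average(self):
        """A batch drawn exactly from the RBM's own distribution produces
        a mean CD update statistically indistinguishable from zero."""
        layer = random_layer(3, 2, "bernoulli", 11, scale=0.5)
        vs = bits(3)
        hs = bits(2)
        E = np.array([[rbm_energy(v, h, layer) for h in hs] for v in vs])
        pv = np.exp(-E).sum(axis=1)
        pv /= pv.sum()
        reps = 200
        updates = np.empty((reps, layer.W.size))
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            batch = vs[rng.choice(len(vs), size=100, p=pv)]
            out = cd_update(layer, batch, rate=1.0, rng=rng)
            updates[r] = (out.W - layer.W).ravel()
        mean = updates.mean(axis=0)
        se = updates.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean) < 3.5 * se + 1e-4)

    def test_cd1_direction_aligns_with_exact_gradient(self):
        """The expected CD-1 weight update points uphill along the exact
        log-likelihood gradient (full enumeration, D=4, F=2)."""
        layer = random_layer(4, 2, "bernoulli", 21, scale=0.4)
        rng = np.random.default_rng(5)
        data = (rng.random((60, 4)) > rng.random(4)).astype(float)
        # exact gradient: data term minus model term
        vs, hs = bits(4), bits(2)
        E = np.array([[rbm_energy(v, h, layer) for h in hs] for v in vs])
        p_joint = np.exp(-E)
        p_joint /= p_joint.sum()
        model_term = np.einsum("vh,vi,hj->ij", p_joint, vs, hs)
        data_term = (data.T @ hidden_probability(data, layer)) / len(data)
        exact_grad = data_term - model_term
        # expected CD-1 direction over many seeded runs
        acc = np.zeros_like(layer.W)
        for r in range(300):
            out = cd_update(layer, data, rate=1.0, k=1,
                            rng=np.random.default_rng(r))
            acc += out.W - layer.W
        acc /= 300
        inner = np.sum(acc * exact_grad)
        assert inner > 0.0


class TestExactLikelihood:
    def test_uniform_model_loglik(self):
        layer = RBMLayer(W=np.zeros((2, 1)), a=np.zeros(2), b=np.zeros(1),
                         sigma=np.ones(2))
        data = bits(2)
        assert exact_bernoulli_loglik(layer, data) == pytest.approx(
            -2 * np.log(2))

    def test_probabilities_sum_to_one(self):
        layer = random_layer(3, 2, "bernoulli", 31)
        total = sum(np.exp(exact_bernoulli_loglik(layer, v[None, :]))
                    for v in bits(3))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_monotone_under_exact_gradient_ascent(self):
        layer = random_layer(3, 2, "bernoulli", 41, scale=0.3)
        rng = np.random.default_rng(8)
        data = (rng.random((20, 3)) > 0.4).astype(float)
        prev = exact_bernoulli_loglik(layer, data)
        eps, rate = 1e-6, 0.2
        for _ in range(50):
            gW = np.zeros_like(layer.W)
            for idx in np.ndindex(layer.W.shape):
                layer.W[idx] += eps
                up = exact_bernoulli_loglik(layer, data)
                layer.W[idx] -= 2 * eps
                down = exact_bernoulli_loglik(layer, data)
                layer.W[idx] += eps
                gW[idx] = (up - down) / (2 * eps)
            layer.W += rate * gW
            cur = exact_bernoulli_loglik(layer, data)
            assert cur > prev - 1e-12
            prev = cur

    def test_size_guard(self):
        layer = random_layer(10, 8, "bernoulli", 0)
        with pytest.raises(ValueError, match="large"):
            exact_bernoulli_loglik(layer, np.zeros((1, 10)))


class TestForward:
    def test_zero_weights_constant_head_bias(self):
        model = DBNModel.initialize(6, (4, 3, 2), seed=0)
        for layer in model.layers:
            layer.W[:] = 0.0
        model.head_W[:] = 0.0
        model.head_b[:] = 3.25
        np.testing.assert_allclose(forward(model, np.ones(6)), 3.25)

    def test_deterministic_and_finite_under_huge_inputs(self):
        model = DBNModel.initialize(8, (6, 5, 4), seed=1)
        v = np.full(8, 1e6)
        out1, out2 = forward(model, v), forward(model, v)
        np.testing.assert_array_equal(out1, out2)
        assert np.all(np.isfinite(out1))

    def test_dim_mismatch(self):
        model = DBNModel.initialize(8, (6, 5, 4), seed=1)
        with pytest.raises(ValueError, match="dim"):
            forward(model, np.zeros(9))


class TestTraining:
    def test_pretrain_zero_epochs_is_identity(self, rng):
        model = DBNModel.initialize(8, (6, 5, 4), seed=2)
        data = rng.standard_normal((16, 8))
        out = pretrain(model, data, TrainConfig(pretrain_epochs=0))
        np.testing.assert_array_equal(out.layers[0].W, model.layers[0].W)

    def test_pretrain_reduces_first_layer_reconstruction_error(self, rng):
        model = DBNModel.initialize(8, (16, 8, 4), seed=3)
        data = rng.standard_normal((128, 8)) * 0.5
        cfg = TrainConfig(pretrain_epochs=20, pretrain_rate=5e-3,
                          batch_size=16, seed=0)
        trained = pretrain(model, data, cfg)

        def recon_mse(m):
            p = hidden_probability(data, m.layers[0])
            return np.mean((visible_mean(p, m.layers[0]) - data) ** 2)

        assert recon_mse(trained) <= recon_mse(model)

    def test_pretrain_deterministic(self, rng):
        data = rng.standard_normal((32, 8))
        cfg = TrainConfig(pretrain_epochs=3, seed=9)
        outs = []
        for _ in range(2):
            model = DBNModel.initialize(8, (6, 5, 4), seed=2)
            outs.append(pretrain(model, data, cfg))
        np.testing.assert_array_equal(outs[0].layers[2].W,
                                      outs[1].layers[2].W)

    def test_fine_tune_reduces_loss_and_is_deterministic(self, rng):
        noisy = rng.standard_normal((64, 8))
        clean = noisy * 0.5
        cfg = TrainConfig(pretrain_epochs=0, finetune_epochs=15,
                          batch_size=16, seed=4)
        hists = []
        for _ in range(2):
            model = DBNModel.initialize(8, (12, 10, 8), seed=4)
            _, hist = fine_tune(model, noisy, clean, cfg)
            hists.append(hist)
        assert hists[0][-1]["train_loss"] < hists[0][0]["train_loss"]
        assert hists[0] == hists[1]

    def test_learning_rate_schedule_honored(self, rng):
        noisy = rng.standard_normal((20, 6))
        cfg = TrainConfig(finetune_epochs=92, batch_size=20, seed=0)
        model = DBNModel.initialize(6, (4, 3, 2), seed=0)
        _, hist = fine_tune(model, noisy, noisy, cfg)
        assert hist[0]["learning_rate"] == 5e-3
        assert hist[88]["learning_rate"] == 5e-3
        assert hist[89]["learning_rate"] == 2.5e-3  # epoch 90
        assert hist[91]["learning_rate"] == 2.5e-3

    def test_mismatched_pairs_rejected(self):
        model = DBNModel.initialize(6, (4, 3, 2), seed=0)
        with pytest.raises(ValueError, match="paired"):
            fine_tune(model, np.zeros((4, 6)), np.zeros((5, 6)))


def near_identity_model(L, eps=1e-5):
    """A stack whose sigmoids operate in their linear regime so the network
    reproduces its input to high accuracy."""
    eye = np.eye(L)
    layers = [
        RBMLayer(W=eps * eye, a=np.zeros(L), b=np.zeros(L),
                 sigma=np.ones(L), unit_type="gauss_bernoulli"),
        RBMLayer(W=4.0 * eye, a=np.zeros(L), b=np.full(L, -2.0),
                 sigma=np.ones(L), unit_type="bernoulli"),
        RBMLayer(W=4.0 * eye, a=np.zeros(L), b=np.full(L, -2.0),
                 sigma=np.ones(L), unit_type="bernoulli"),
    ]
    return DBNModel(layers=layers, head_W=(4.0 / eps) * eye,
                    head_b=np.full(L, -2.0 / eps))


class TestDenoisePipeline:
    def test_identity_model_reproduces_signal(self, rng):
        x = rng.standard_normal(200)
        out = denoise(near_identity_model(16), x, L=16)
        np.testing.assert_allclose(out.samples, x, atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_output_length_matches_input(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(20, 400))
        model = near_identity_model(8)
        assert len(denoise(model, rng.standard_normal(T), L=8)) == T

    def test_wrong_window_rejected(self):
        with pytest.raises(ValueError, match="window length"):
            denoise(near_identity_model(8), np.zeros(100), L=16)


class TestCheckpoint:
    def test_roundtrip_is_byte_identical(self, tmp_path):
        model = DBNModel.initialize(8, (6, 5, 4), seed=7)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_checkpoint(p1, model, config={"window_length": 8})
        loaded, meta = load_checkpoint(p1)
        save_checkpoint(p2, loaded, config=meta)
        assert p1.read_bytes() == p2.read_bytes()
        np.testing.assert_array_equal(loaded.layers[0].W,
                                      model.layers[0].W)

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"format": "other"}))
        with pytest.raises(ValueError, match="format"):
            load_checkpoint(path)
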