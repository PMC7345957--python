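"""The adversarial autoencoder synthesis model and its objective."""

import numpy as np
import pytest

from sctmorph.caegan import (
    TrainConfig,
    adversarial_loss,
    build_model,
    load_model,
    reconstruction_loss,
    sample_latent,
    save_model,
    synthesize,
    total_loss,
    train,
)
from sctmorph.nn import autograd as ag
from sctmorph.nn.autograd import Tensor
from sctmorph.volume import Volume, extract_patches

LN2, LN3 = np.log(2.0), np.log(3.0)


class TestSampleLatent:
    def test_zero_spread_is_deterministic_encoding(self):
        mu = np.arange(6.0).reshape(2, 3)
        z = np.ones((2, 3))
        assert np.array_equal(sample_latent(mu, np.zeros_like(mu), z), mu)

    def test_unit_spread_zero_mean_returns_noise(self):
        z = np.random.default_rng(0).standard_normal((4, 4))
        out = sample_latent(np.zeros((4, 4)), np.ones((4, 4)), z)
        assert np.array_equal(out, z)

    def test_seeded_noise_reproduces_sample(self):
        mu = np.full((3, 3), 0.5)
        delta = np.full((3, 3), 0.2)
        z1 = np.random.default_rng(42).standard_normal((3, 3))
        z2 = np.random.default_rng(42).standard_normal((3, 3))
        assert np.array_equal(sample_latent(mu, delta, z1), sample_latent(mu, delta, z2))

    def test_shape_mismatch_and_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            sample_latent(np.zeros((2, 2)), np.zeros((3, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            sample_latent(np.zeros((2, 2)), -np.ones((2, 2)), np.zeros((2, 2)))


class TestLosses:
    def test_reconstruction_identity_offset_and_checkerboard(self):
        y = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)
        assert reconstruction_loss(y, y) == 0.0
        assert reconstruction_loss(y, y + 0.3) == pytest.approx(0.3)
        assert reconstruction_loss(y, np.full((8, 8), 0.5)) == pytest.approx(0.5)

    def test_uninformative_discriminator_costs_ln2_per_binary_term(self):
        n = 4
        half = np.full(n, 0.5)
        uniform = np.full((n, 3), 1 / 3)
        labels = np.array([0, 1, 2, 1])
        loss_d, loss_g = adversarial_loss(half, half, uniform, uniform, labels)
        assert loss_d == pytest.approx(2 * LN2 + 2 * LN3)
        assert loss_g == pytest.approx(LN2 + LN3)

    def test_perfect_discriminator_limit(self):
        n = 3
        labels = np.array([0, 1, 2])
        sharp = np.eye(3)[labels] * (1 - 3e-7) + 1e-7
        loss_d, loss_g = adversarial_loss(np.full(n, 1 - 1e-7), np.full(n, 1e-7), sharp, sharp, labels)
        assert loss_d < 1e-5
        assert loss_g > 10.0

    def test_total_loss_linear_combination(self):
        assert total_loss(2.0, 0.3, 100.0) == pytest.approx(32.0)
        assert total_loss(1.7, 0.9, 0.0) == pytest.approx(1.7)
        assert total_loss(0.0, 0.0, 100.0) == 0.0
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, -1.0)

    def test_tensor_and_numpy_paths_agree(self):
        rng = np.random.default_rng(1)
        d_r, d_f = rng.uniform(0.1, 0.9, 5), rng.uniform(0.1, 0.9, 5)
        c_r = rng.dirichlet(np.ones(3), size=5)
        c_f = rng.dirichlet(np.ones(3), size=5)
        labels = rng.integers(0, 3, 5)
        np_d, np_g = adversarial_loss(d_r, d_f, c_r, c_f, labels)
        t_d, t_g = adversarial_loss(Tensor(d_r), Tensor(d_f), Tensor(c_r), Tensor(c_f), labels)
        assert t_d.item() == pytest.approx(np_d)
        assert t_g.item() == pytest.approx(np_g)


class TestModel:
    def test_forward_shape_contract(self):
        model = build_model(base_channels=8, depth=2, seed=0)
        xs = [Tensor(np.random.default_rng(i).random((2, 1, 32, 32))) for i in range(3)]
        y, mu, delta = model.forward_synthesis(xs)
        assert y.shape == (2, 1, 32, 32)
        assert np.all(delta.data >= 0)

    def test_discriminator_and_classifier_heads(self):
        model = build_model(base_channels=8, depth=2, seed=0)
        y = Tensor(np.random.default_rng(0).random((3, 1, 32, 32)))
        d, c = model.discriminate(y)
        assert d.shape == (3,)
        assert np.all((d.data > 0) & (d.data < 1))
        assert c.shape == (3, 3)
        assert np.allclose(c.data.sum(axis=1), 1.0)

    def test_eval_forward_is_deterministic(self):
        model = build_model(base_channels=8, depth=2, seed=3)
        xs = [Tensor(np.random.default_rng(9).random((1, 1, 16, 16)))] * 3
        y1, _, _ = model.forward_synthesis(xs, z=None, training=False)
        y2, _, _ = model.forward_synthesis(xs, z=None, training=False)
        assert np.array_equal(y1.data, y2.data)

    def test_generator_gradient_descends_adversarial_loss_with_frozen_discriminator(self):
        # one E+G step along the analytic gradient must reduce the
        # adversarial objective; parameters are perturbed off their
        # symmetric initialization so the loss is not at a stationary kink
        model = build_model(base_channels=4, depth=1, seed=3)
        rng = np.random.default_rng(1)
        for p in model.parameters():
            p.data = p.data + 0.02 * rng.standard_normal(p.data.shape)
        xs = [Tensor(rng.random((2, 1, 8, 8))) for _ in range(3)]

        def g_loss():
            y, _, _ = model.forward_synthesis(xs, z=None, training=False)
            d, c = model.discriminate(y)
            _, loss_g = adversarial_loss(d.detach(), d, c.detach(), c, np.array([1, 0]))
            return loss_g

        loss = g_loss()
        loss.backward()
        gparams = model.generator_parameters()
        gnorm = np.sqrt(sum((p.grad**2).sum() for p in gparams if p.grad is not None))
        assert gnorm > 0
        # analytic gradient matches central differences on the output layer
        p = model.out_conv.weight
        g = p.grad.copy()
        for idx in [(0, 0, 0, 0), (0, 2, 1, 1)]:
            orig = p.data[idx]
            p.data[idx] = orig + 1e-6
            lp = g_loss().item()
            p.data[idx] = orig - 1e-6
            lm = g_loss().item()
            p.data[idx] = orig
            assert (lp - lm) / 2e-6 == pytest.approx(g[idx], abs=1e-6)
        # and following it descends
        for param in gparams:
            if param.grad is not None:
                param.data = param.data - (1e-3 / gnorm) * param.grad
        assert g_loss().item() < loss.item()

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            build_model(dim=3)
        with pytest.raises(ValueError):
            build_model(base_channels=0)


class TestTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(base_channels=4, depth=1, seed=0), [], TrainConfig(steps=1))

    def test_zero_steps_leaves_model_unchanged(self):
        model = build_model(base_channels=4, depth=1, seed=0)
        before = model.state_arrays()
        data = [(np.zeros((3, 8, 8)), np.zeros((8, 8)), 0)]
        hist = train(model, data, TrainConfig(steps=0, seed=0))
        assert hist == []
        for a, b in zip(before, model.state_arrays()):
            assert np.array_equal(a, b)

    def test_history_lengths_and_finiteness(self, smoke_run):
        _, history = smoke_run
        assert len(history) == 200
        for rec in history:
            for key in ("loss_d", "loss_g_adv", "loss_l1", "loss_total"):
                assert np.isfinite(rec[key])

    def test_classifier_beats_chance_on_tissue_classes(self, smoke_run):
        _, history = smoke_run
        assert np.mean([h["class_acc"] for h in history[-20:]]) > 1 / 3

    def test_huge_lambda_approximates_pure_regression(self):
        rng = np.random.default_rng(2)
        data = [(rng.random((3, 8, 8)), rng.random((8, 8)), int(rng.integers(3))) for _ in range(8)]
        model = build_model(base_channels=4, depth=1, seed=2)
        hist = train(model, data, TrainConfig(steps=60, lambda_l1=1e6, seed=2))
        first = np.mean([h["loss_l1"] for h in hist[:10]])
        last = np.mean([h["loss_l1"] for h in hist[-10:]])
        assert last < first

    def test_training_is_seed_deterministic(self):
        rng = np.random.default_rng(3)
        data = [(rng.random((3, 8, 8)), rng.random((8, 8)), 0) for _ in range(4)]
        runs = []
        for _ in range(2):
            model = build_model(base_channels=4, depth=1, seed=4)
            hist = train(model, data, TrainConfig(steps=5, seed=4))
            runs.append((model.state_arrays(), [h["loss_total"] for h in hist]))
        for a, b in zip(runs[0][0], runs[1][0]):
            assert np.array_equal(a, b)
        assert runs[0][1] == runs[1][1]


class TestSynthesize:
    def test_identity_overfit_reproduces_input(self, clean_phantom):
        v = clean_phantom.mr["fat"]
        data = [(np.stack([p.data] * 3), p.data, 1) for _, p in extract_patches(v, 16, 8)]
        model = build_model(seed=13)
        train(model, data, TrainConfig(steps=200, seed=13))
        sct = synthesize(model, [v, v, v], 16, 8)
        assert reconstruction_loss(v, sct) < 0.15

    def test_same_inputs_give_bit_identical_output(self, smoke_run, clean_phantom):
        model, _ = smoke_run
        contrasts = [clean_phantom.mr[n] for n in sorted(clean_phantom.mr)]
        a = synthesize(model, contrasts, 16, 8)
        b = synthesize(model, contrasts, 16, 8)
        assert np.array_equal(a.data, b.data)

    def test_output_full_shape_with_non_divisible_stride(self, smoke_run):
        model, _ = smoke_run
        vols = [Volume(np.random.default_rng(i).random((48, 40))) for i in range(3)]
        out = synthesize(model, vols, 16, 12)
        assert out.shape == (48, 40)

    def test_contrast_shape_mismatch_rejected(self, smoke_run):
        model, _ = smoke_run
        vols = [Volume(np.zeros((32, 32))), Volume(np.zeros((32, 32))), Volume(np.zeros((32, 16)))]
        with pytest.raises(ValueError):
            synthesize(model, vols, 16, 8)

    def test_checkpoint_round_trip(self, smoke_run, tmp_path, clean_phantom):
        model, _ = smoke_run
        path = tmp_path / "model.npz"
        save_model(model, path, TrainConfig(steps=200, seed=11))
        restored = load_model(path)
        contrasts = [clean_phantom.mr[n] for n in sorted(clean_phantom.mr)]
        a = synthesize(model, contrasts, 16, 8)
        b = synthesize(restored, contrasts, 16, 8)
        assert np.array_equal(a.data, b.data)
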