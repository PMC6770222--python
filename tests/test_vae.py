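import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm, pearsonr

from vaemda import vae
from vaemda.vae import (
    LossValue,
    TrainedVAE,
    TrainingDivergedError,
    VAEConfig,
    _forward_backward,
    decode,
    encode,
    init_vae,
    load_checkpoint,
    reparameterize,
    save_checkpoint,
    train_vae,
    vae_loss,
)


def tiny_config(**overrides):
    defaults = dict(
        input_dim=12, hidden1=8, latent_dim=4, hidden3=6,
        batch_size=5, epochs=3, seed=0,
    )
    defaults.update(overrides)
    return VAEConfig(**defaults)


def zero_model(config):
    model = init_vae(config, np.random.default_rng(0))
    for key in model.params:
        model.params[key] = np.zeros_like(model.params[key])
    model.params["gamma"] = np.ones_like(model.params["gamma"])
    return model


def kl_quadrature(mu: float, logvar: float) -> float:
    """High-precision numeric KL(N(mu, sigma^2) || N(0, 1)) for one dimension."""
    sigma = np.exp(0.5 * logvar)

    def integrand(x):
        p = norm.pdf(x, loc=mu, scale=sigma)
        return p * (norm.logpdf(x, loc=mu, scale=sigma) - norm.logpdf(x))

    lo, hi = mu - 12 * sigma, mu + 12 * sigma
    value, _ = quad(integrand, lo, hi, limit=200)
    return value


class TestConfig:
    def test_rejects_bad_dims(self):
        with pytest.raises(ValueError):
            tiny_config(latent_dim=0)

    def test_rejects_bad_validation_fraction(self):
        with pytest.raises(ValueError):
            tiny_config(validation_fraction=1.0)

    def test_paper_defaults(self):
        cfg = VAEConfig(input_dim=878)
        assert (cfg.hidden1, cfg.latent_dim, cfg.hidden3) == (300, 100, 300)
        assert cfg.batch_size == 20
        assert cfg.learning_rate == 0.001
        assert cfg.epsilon_std == 1.0
        assert cfg.epochs == 50
        assert cfg.validation_fraction == 0.1


class TestEncode:
    def test_zero_input_zero_heads(self):
        model = zero_model(tiny_config())
        mu, logvar = encode(model, np.zeros(12))
        np.testing.assert_array_equal(mu, 0.0)
        np.testing.assert_array_equal(logvar, 0.0)

    def test_identical_rows_identical_output(self):
        model = init_vae(tiny_config(), np.random.default_rng(1))
        x = np.tile(np.linspace(0, 1, 12), (2, 1))
        mu, logvar = encode(model, x)
        np.testing.assert_array_equal(mu[0], mu[1])
        np.testing.assert_array_equal(logvar[0], logvar[1])

    def test_batch_equals_row_loop(self):
        rng = np.random.default_rng(2)
        model = train_vae(rng.random((40, 12)), tiny_config(epochs=2))
        X = rng.random((7, 12))
        mu_batch, lv_batch = encode(model, X)
        for i in range(7):
            mu_row, lv_row = encode(model, X[i])
            np.testing.assert_allclose(mu_batch[i], mu_row[0], atol=1e-6)
            np.testing.assert_allclose(lv_batch[i], lv_row[0], atol=1e-6)

    def test_width_mismatch_errors(self):
        model = init_vae(tiny_config(), np.random.default_rng(0))
        with pytest.raises(ValueError, match="width"):
            encode(model, np.zeros(13))


class TestReparameterize:
    def test_zero_std_returns_mu(self):
        mu = np.array([0.3, -1.2])
        z = reparameterize(mu, np.zeros(2), 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(z, mu)

    def test_seeded_reproducibility(self):
        mu, logvar = np.zeros(3), np.full(3, -0.5)
        z1 = reparameterize(mu, logvar, 1.0, np.random.default_rng(5))
        z2 = reparameterize(mu, logvar, 1.0, np.random.default_rng(5))
        np.testing.assert_array_equal(z1, z2)

    def test_monte_carlo_variance(self):
        # Var(z) = epsilon_std^2 * exp(logvar); check within 3 sigma of the
        # sampling distribution of the variance estimate over 1e5 draws.
        logvar = 0.7
        n = 100_000
        rng = np.random.default_rng(11)
        z = reparameterize(
            np.zeros(n), np.full(n, logvar), 1.0, rng
        )
        target = np.exp(logvar)
        sample_var = z.var(ddof=1)
        # std of the variance of n normal draws ~ target * sqrt(2/(n-1))
        assert abs(sample_var - target) < 3 * target * np.sqrt(2 / (n - 1))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reparameterize(np.zeros(2), np.zeros(3), 1.0, np.random.default_rng(0))


class TestDecode:
    def test_zero_weights_give_half(self):
        model = zero_model(tiny_config())
        out = decode(model, np.zeros(4))
        np.testing.assert_allclose(out, 0.5)

    def test_output_in_open_interval(self):
        model = init_vae(tiny_config(), np.random.default_rng(3))
        out = decode(model, np.random.default_rng(4).standard_normal((5, 4)))
        assert (out > 0).all() and (out < 1).all()

    def test_continuity(self):
        model = init_vae(tiny_config(), np.random.default_rng(3))
        z = np.ones(4)
        base = decode(model, z)
        for delta in (1e-3, 1e-5, 1e-7):
            shifted = decode(model, z + delta)
            assert np.linalg.norm(shifted - base) < delta * 1e3

    def test_width_mismatch(self):
        model = init_vae(tiny_config(), np.random.default_rng(0))
        with pytest.raises(ValueError, match="latent"):
            decode(model, np.zeros(5))


class TestLoss:
    def test_prior_match_zero_kl(self):
        loss = vae_loss(np.full((1, 2), 0.5), np.full((1, 2), 0.5),
                        np.zeros((1, 3)), np.zeros((1, 3)))
        assert loss.kl == 0.0

    def test_unit_mean_kl_half(self):
        loss = vae_loss(np.full((1, 1), 0.5), np.full((1, 1), 0.5),
                        np.array([[1.0]]), np.array([[0.0]]))
        assert loss.kl == pytest.approx(0.5, abs=1e-12)
        assert loss.kl == pytest.approx(kl_quadrature(1.0, 0.0), abs=1e-9)

    def test_bce_closed_form(self):
        loss = vae_loss(np.array([[0.5]]), np.array([[0.5]]),
                        np.zeros((1, 1)), np.zeros((1, 1)))
        assert loss.reconstruction == pytest.approx(np.log(2), abs=1e-12)

    def test_total_is_sum(self):
        loss = LossValue(1.25, 0.5)
        assert loss.total == 1.75

    def test_extreme_xhat_clamped_finite(self):
        loss = vae_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]),
                        np.zeros((1, 1)), np.zeros((1, 1)))
        assert np.isfinite(loss.total)

    def test_kl_matches_quadrature_on_random_pairs(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            mu = float(rng.uniform(-2, 2))
            logvar = float(rng.uniform(-2, 2))
            loss = vae_loss(np.full((1, 1), 0.5), np.full((1, 1), 0.5),
                            np.array([[mu]]), np.array([[logvar]]))
            assert loss.kl == pytest.approx(kl_quadrature(mu, logvar), abs=1e-6)


class TestGradients:
    def test_backprop_matches_numeric_gradient(self):
        config = VAEConfig(input_dim=7, hidden1=5, latent_dim=3, hidden3=4,
                           batch_size=3, epochs=1, seed=0)
        rng = np.random.default_rng(42)
        model = init_vae(config, rng)
        x = rng.random((3, 7))
        noise = rng.standard_normal((3, 3))
        _, grads = _forward_backward(model, x, noise, update_running=False)
        eps = 1e-6
        for key, value in model.params.items():
            numeric = np.zeros_like(value)
            flat = value.ravel()
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + eps
                up, _ = _forward_backward(model, x, noise, update_running=False)
                flat[idx] = orig - eps
                down, _ = _forward_backward(model, x, noise, update_running=False)
                flat[idx] = orig
                numeric.ravel()[idx] = (up - down) / (2 * eps)
            np.testing.assert_allclose(
                grads[key], numeric, atol=1e-5, rtol=1e-4,
                err_msg=f"gradient mismatch for {key}",
            )


class TestTraining:
    def test_loss_decreases_on_fixture(self):
        rng = np.random.default_rng(0)
        data = rng.random((100, 30))
        model = train_vae(data, tiny_config(input_dim=30, epochs=10, seed=0))
        assert model.history[-1]["train_loss"] < model.history[0]["train_loss"]

    @pytest.mark.parametrize("seed", range(5))
    def test_median_loss_drops_every_seed(self, seed):
        rng = np.random.default_rng(seed)
        # low-rank structure so there is something to learn
        data = 1 / (1 + np.exp(-rng.standard_normal((60, 20)) @ rng.standard_normal((20, 24)) / 4))
        cfg = tiny_config(input_dim=24, epochs=12, seed=seed)
        history = [h["train_loss"] for h in train_vae(data, cfg).history]
        assert np.median(history[-5:]) < np.median(history[:5])

    def test_seeded_determinism(self):
        data = np.random.default_rng(1).random((50, 12))
        cfg = tiny_config(epochs=4, seed=7)
        h1 = train_vae(data, cfg).history
        h2 = train_vae(data, cfg).history
        assert h1 == h2

    def test_zero_epochs_returns_initialized_model(self):
        data = np.random.default_rng(1).random((30, 12))
        model = train_vae(data, tiny_config(epochs=0))
        assert model.history == []
        init = init_vae(tiny_config(epochs=0), np.random.default_rng(0))
        np.testing.assert_array_equal(model.params["W1"], init.params["W1"])

    def test_reconstruction_improves_over_initialization(self):
        rng = np.random.default_rng(3)
        data = rng.random((80, 12))
        cfg = tiny_config(epochs=15, seed=3)
        trained = train_vae(data, cfg)
        initial = train_vae(data, tiny_config(epochs=0, seed=3))

        def recon_error(model):
            mu, logvar = encode(model, data)
            return vae_loss(data, decode(model, mu), mu, logvar).reconstruction

        assert recon_error(trained) < recon_error(initial)

    def test_reconstruction_correlates_with_input(self):
        rng = np.random.default_rng(4)
        data = rng.random((80, 16))
        model = train_vae(data, tiny_config(input_dim=16, epochs=15, seed=4))
        mu, _ = encode(model, data)
        recon = decode(model, mu)
        r, _ = pearsonr(data.ravel(), recon.ravel())
        assert r > 0

    def test_validation_loss_recorded(self):
        data = np.random.default_rng(5).random((50, 12))
        model = train_vae(data, tiny_config(epochs=2))
        assert all(np.isfinite(h["val_loss"]) for h in model.history)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            train_vae(np.zeros((10, 5)), tiny_config(input_dim=12))

    def test_divergence_raises(self):
        data = np.random.default_rng(6).random((30, 12))
        cfg = tiny_config(epochs=2, learning_rate=1e12)
        with pytest.raises((TrainingDivergedError, FloatingPointError)):
            with np.errstate(over="raise"):
                train_vae(data, cfg)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        data = np.random.default_rng(8).random((40, 12))
        model = train_vae(data, tiny_config(epochs=2, seed=8))
        path = tmp_path / "model.json"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.config == model.config
        assert back.history == model.history
        for key in model.params:
            np.testing.assert_array_equal(back.params[key], model.params[key])
        mu1, _ = encode(model, data[:3])
        mu2, _ = encode(back, data[:3])
        np.testing.assert_allclose(mu1, mu2)

    def test_rejects_foreign_json(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text('{"format": "other"}')
        with pytest.raises(ValueError):
            load_checkpoint(path)
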