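"""Variational autoencoder: architecture, loss, and training loop.

The network is a 300-100-300 bottleneck: the encoder maps the input through
an affine layer with batch normalization and a rectifier to 300 hidden units,
then to separate 100-dimensional mean and log-variance heads; the decoder
maps a latent sample through a 300-unit rectified layer to a sigmoid output
of the input width.  Training minimizes summed binary cross-entropy plus the
Gaussian KL divergence to the standard normal prior, with Adam.

Implemented directly on NumPy arrays with hand-derived gradients so the
whole pipeline is dependency-light and bit-reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_CLAMP = 1e-7


class TrainingDivergedError(RuntimeError):
    """Raised when a non-finite loss appears during training."""


@dataclass(frozen=True)
class VAEConfig:
    input_dim: int
    hidden1: int = 300
    latent_dim: int = 100
    hidden3: int = 300
    batch_size: int = 20
    learning_rate: float = 0.001
    epsilon_std: float = 1.0
    epochs: int = 50
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_dim", "hidden1", "latent_dim", "hidden3", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class LossValue:
    reconstruction: float
    kl: float

    @property
    def total(self) -> float:
        return self.reconstruction + self.kl


@dataclass
class TrainedVAE:
    """Fitted parameters plus batch-norm running statistics and loss history."""

    config: VAEConfig
    params: dict[str, np.ndarray]
    running_mean: np.ndarray
    running_var: np.ndarray
    history: list[dict[str, float]] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.config.input_dim


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_vae(config: VAEConfig, rng: np.random.Generator) -> TrainedVAE:
    """Glorot-uniform weights, zero biases, identity batch-norm scale."""
    D, H1, L, H3 = config.input_dim, config.hidden1, config.latent_dim, config.hidden3
    params = {
        "W1": _glorot(rng, D, H1), "b1": np.zeros(H1),
        "gamma": np.ones(H1), "beta": np.zeros(H1),
        "Wmu": _glorot(rng, H1, L), "bmu": np.zeros(L),
        "Wlv": _glorot(rng, H1, L), "blv": np.zeros(L),
        "W3": _glorot(rng, L, H3), "b3": np.zeros(H3),
        "W4": _glorot(rng, H3, D), "b4": np.zeros(D),
    }
    return TrainedVAE(config, params, np.zeros(H1), np.ones(H1))


def encode(model: TrainedVAE, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic inference-mode encoding to (mu, logvar).

    Accepts a single row or a batch; batch normalization uses the running
    statistics, so batch and row-by-row encoding agree.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"input width {x.shape[1]} != model input_dim {model.input_dim}"
        )
    p = model.params
    a1 = x @ p["W1"] + p["b1"]
    h1 = p["gamma"] * (a1 - model.running_mean) / np.sqrt(
        model.running_var + _BN_EPS
    ) + p["beta"]
    h1r = np.maximum(h1, 0.0)
    mu = h1r @ p["Wmu"] + p["bmu"]
    logvar = h1r @ p["Wlv"] + p["blv"]
    return mu, logvar


def reparameterize(
    mu: np.ndarray,
    logvar: np.ndarray,
    epsilon_std: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """z = mu + epsilon_std * exp(logvar / 2) * eps with eps ~ N(0, I)."""
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar shapes disagree")
    eps = rng.standard_normal(mu.shape)
    return mu + epsilon_std * np.exp(0.5 * logvar) * eps


def decode(model: TrainedVAE, z: np.ndarray) -> np.ndarray:
    """Deterministic decoding of latent vectors to (0, 1) reconstructions."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != model.config.latent_dim:
        raise ValueError(
            f"latent width {z.shape[1]} != latent_dim {model.config.latent_dim}"
        )
    p = model.params
    h3 = np.maximum(z @ p["W3"] + p["b3"], 0.0)
    return _sigmoid(h3 @ p["W4"] + p["b4"])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def vae_loss(
    x: np.ndarray, x_hat: np.ndarray, mu: np.ndarray, logvar: np.ndarray
) -> LossValue:
    """Per-batch loss: summed binary cross-entropy plus Gaussian KL, averaged
    over the batch.  ``x_hat`` is clamped away from {0, 1} before the logs."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.clip(np.atleast_2d(np.asarray(x_hat, dtype=float)), _CLAMP, 1 - _CLAMP)
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    if x.shape != x_hat.shape or mu.shape != logvar.shape:
        raise ValueError("shape mismatch in loss inputs")
    recon = -np.sum(x * np.log(x_hat) + (1 - x) * np.log(1 - x_hat), axis=1)
    kl = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)
    return LossValue(float(recon.mean()), float(kl.mean()))


def _forward_backward(
    model: TrainedVAE,
    x: np.ndarray,
    noise: np.ndarray,
    update_running: bool = True,
) -> tuple[float, dict[str, np.ndarray]]:
    """One training-mode forward/backward pass on a batch.

    Returns the batch loss and the gradient of the loss with respect to every
    parameter.  Batch normalization uses batch statistics and (optionally)
    updates the running averages.
    """
    p = model.params
    cfg = model.config
    B = x.shape[0]

    a1 = x @ p["W1"] + p["b1"]
    mean = a1.mean(axis=0)
    var = a1.var(axis=0)
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    xhat_bn = (a1 - mean) * inv_std
    h1 = p["gamma"] * xhat_bn + p["beta"]
    h1r = np.maximum(h1, 0.0)
    mu = h1r @ p["Wmu"] + p["bmu"]
    logvar = h1r @ p["Wlv"] + p["blv"]
    sigma = np.exp(0.5 * logvar)
    z = mu + cfg.epsilon_std * sigma * noise
    a3 = z @ p["W3"] + p["b3"]
    h3 = np.maximum(a3, 0.0)
    a4 = h3 @ p["W4"] + p["b4"]
    x_hat = _sigmoid(a4)

    loss = vae_loss(x, x_hat, mu, logvar)
    if update_running:
        model.running_mean = (1 - _BN_MOMENTUM) * model.running_mean + _BN_MOMENTUM * mean
        model.running_var = (1 - _BN_MOMENTUM) * model.running_var + _BN_MOMENTUM * var

    # Backward pass; loss is averaged over the batch.
    d_a4 = (x_hat - x) / B
    g = {"W4": h3.T @ d_a4, "b4": d_a4.sum(axis=0)}
    d_h3 = d_a4 @ p["W4"].T
    d_a3 = d_h3 * (a3 > 0)
    g["W3"] = z.T @ d_a3
    g["b3"] = d_a3.sum(axis=0)
    d_z = d_a3 @ p["W3"].T
    d_mu = d_z + mu / B
    d_logvar = d_z * (0.5 * cfg.epsilon_std * sigma * noise) + 0.5 * (
        np.exp(logvar) - 1.0
    ) / B
    g["Wmu"] = h1r.T @ d_mu
    g["bmu"] = d_mu.sum(axis=0)
    g["Wlv"] = h1r.T @ d_logvar
    g["blv"] = d_logvar.sum(axis=0)
    d_h1r = d_mu @ p["Wmu"].T + d_logvar @ p["Wlv"].T
    d_h1 = d_h1r * (h1 > 0)
    g["gamma"] = (d_h1 * xhat_bn).sum(axis=0)
    g["beta"] = d_h1.sum(axis=0)
    d_xhat = d_h1 * p["gamma"]
    d_var = (d_xhat * (a1 - mean)).sum(axis=0) * (-0.5) * inv_std**3
    d_mean = -(d_xhat.sum(axis=0)) * inv_std + d_var * (-2.0) * (a1 - mean).mean(axis=0)
    d_a1 = d_xhat * inv_std + d_var * 2.0 * (a1 - mean) / B + d_mean / B
    g["W1"] = x.T @ d_a1
    g["b1"] = d_a1.sum(axis=0)
    return loss.total, g


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k in params:
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grads[k]
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grads[k] ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train_vae(data, config: VAEConfig) -> TrainedVAE:
    """Train a VAE on the rows of ``data`` (a SplicedFeatureMatrix or array).

    Rows are split 9/1 into train/validation with the config seed; the
    validation loss is monitored and logged only (no early stopping).  Rows
    are reshuffled each epoch and the final short batch is kept.  Exactly
    ``config.epochs`` epochs are run; epochs=0 returns the initialized model
    with an empty history.
    """
    X = np.asarray(getattr(data, "values", data), dtype=float)
    if X.ndim != 2 or X.shape[1] != config.input_dim:
        raise ValueError(f"data shape {X.shape} incompatible with input_dim "
                         f"{config.input_dim}")
    rng = np.random.default_rng(config.seed)
    model = init_vae(config, rng)

    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    n_val = min(n_val, n - 1)  # keep at least one training row
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X_train, X_val = X[train_idx], X[val_idx]

    optimizer = _Adam(model.params, config.learning_rate)
    for epoch in range(config.epochs):
        order = rng.permutation(len(X_train))
        total, count = 0.0, 0
        for start in range(0, len(X_train), config.batch_size):
            batch = X_train[order[start : start + config.batch_size]]
            noise = rng.standard_normal((batch.shape[0], config.latent_dim))
            loss, grads = _forward_backward(model, batch, noise)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            optimizer.step(model.params, grads)
            total += loss * batch.shape[0]
            count += batch.shape[0]
        val_loss = float("nan")
        if len(X_val):
            mu, logvar = encode(model, X_val)
            val_loss = vae_loss(X_val, decode(model, mu), mu, logvar).total
        model.history.append(
            {"epoch": epoch, "train_loss": total / count, "val_loss": val_loss}
        )
    return model


def save_checkpoint(model: TrainedVAE, path: str | Path) -> None:
    """Serialize parameters, running stats, config and history as JSON."""
    payload = {
        "format": "vaemda-vae-checkpoint",
        "version": 1,
        "config": asdict(model.config),
        "params": {k: v.tolist() for k, v in model.params.items()},
        "running_mean": model.running_mean.tolist(),
        "running_var": model.running_var.tolist(),
        "history": model.history,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_checkpoint(path: str | Path) -> TrainedVAE:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != "vaemda-vae-checkpoint":
        raise ValueError(f"{path} is not a VAE checkpoint")
    return TrainedVAE(
        VAEConfig(**payload["config"]),
        {k: np.asarray(v) for k, v in payload["params"].items()},
        np.asarray(payload["running_mean"]),
        np.asarray(payload["running_var"]),
        payload["history"],
    )
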