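"""Autoencoder and variational autoencoder embeddings of the feature table.

Both models share one architecture: an encoder of six (affine -> batch
normalization -> ReLU) blocks followed by an affine head emitting ``d``
values (AE code) or ``2d`` values split into a posterior mean E(Z) and
log-variance (VAE); the decoder mirrors the encoder back to the input width.
The training objective is

    AE:   L = (1/m) sum_j ||x_j - x_hat_j||^2
    VAE:  L = L_recon + (beta/2) * sum_i (V(Z) - log V(Z) - 1 + E(Z)^2)_i

averaged over the batch, with V(Z) = exp(logvar) so the KL penalty
v - log v - 1 + e^2 is non-negative by construction.  Optimization is Adam.
The networks are implemented directly on numpy arrays (explicit forward and
backward passes), which keeps the package dependency-light and makes every
gradient auditable; at the feature-table sizes this package targets the
training loop is CPU-friendly.

Embeddings are always extracted in inference mode: batch normalization uses
running statistics and the VAE contributes its posterior mean, so encoding
is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .feature_engineering import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "EmbeddingMatrix",
    "Autoencoder",
    "reconstruction_loss",
    "kl_term",
    "vae_loss",
    "train_autoencoder",
    "encode",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of one AE/VAE fit.

    ``beta`` weights the KL penalty (0 disables it; the AE ignores it).
    ``hidden_widths`` are the six encoder block widths; the decoder mirrors
    them.  One ``seed`` controls initialization, shuffling and sampling.
    """

    latent_dim: int = 32
    beta: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0
    hidden_widths: tuple[int, ...] = (128, 96, 64, 48, 32, 24)
    early_stop_tol: float = 1e-5
    early_stop_patience: int = 10

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if min(self.learning_rate, self.epochs, self.batch_size) <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")


@dataclass
class EmbeddingMatrix:
    """m x d latent codes, row-aligned with the feature table."""

    values: np.ndarray
    source: str  # "AE" | "VAE"
    config: TrainingConfig


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean over the batch of the per-row squared error summed over features."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean(np.sum((x - x_hat) ** 2, axis=-1)))


def kl_term(mean: np.ndarray, variance: np.ndarray, beta: float) -> float:
    """(beta/2) * sum_i (V - log V - 1 + E^2)_i, averaged over the batch.

    Each summand v - log v - 1 + e^2 is >= 0 for v > 0, so the term is
    non-negative and vanishes exactly at E(Z)=0, V(Z)=1.
    """
    variance = np.asarray(variance, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if np.any(variance <= 0):
        raise ValueError(
            "non-positive variance; the encoder must parameterize log-variance"
        )
    per_sample = np.sum(variance - np.log(variance) - 1.0 + mean**2, axis=-1)
    return float((beta / 2.0) * np.mean(per_sample))


def vae_loss(
    x: np.ndarray,
    x_hat: np.ndarray,
    mean: np.ndarray,
    variance: np.ndarray,
    beta: float,
) -> float:
    """Reconstruction loss plus the beta-weighted KL penalty."""
    return reconstruction_loss(x, x_hat) + kl_term(mean, variance, beta)


# ---------------------------------------------------------------------------
# network internals


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization suits the ReLU blocks; the heads use it too,
        # which is harmless at these widths.
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # in-place: the optimizer holds references to dW/db
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _BatchNorm:
    def __init__(self, n: int):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self._cache = None
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
        x_hat = (x - mu) * inv_sd
        if training:
            self._cache = (x_hat, inv_sd)
        return self.gamma * x_hat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_hat, inv_sd = self._cache
        n = dout.shape[0]
        self.dgamma[...] = np.sum(dout * x_hat, axis=0)  # in-place for the optimizer
        self.dbeta[...] = np.sum(dout, axis=0)
        dxhat = dout * self.gamma
        return (inv_sd / n) * (
            n * dxhat - dxhat.sum(axis=0) - x_hat * (dxhat * x_hat).sum(axis=0)
        )

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class _Stack:
    """A feed-forward stack of blocks with shared forward/backward plumbing."""

    def __init__(self, widths: list[int], rng: np.random.Generator, head_out: int):
        self.layers: list = []
        for n_in, n_out in zip(widths[:-1], widths[1:]):
            self.layers += [_Linear(n_in, n_out, rng), _BatchNorm(n_out), _ReLU()]
        self.layers.append(_Linear(widths[-1], head_out, rng))

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


class Autoencoder:
    """Encoder/decoder pair over numpy arrays; ``variational`` switches the head.

    The encoder head emits ``d`` values (AE) or ``2d`` values interpreted as
    [mean | log-variance] (VAE).  Use :func:`train_autoencoder` to fit.
    """

    def __init__(self, n_features: int, cfg: TrainingConfig, variational: bool):
        self.cfg = cfg
        self.variational = variational
        self.n_features = n_features
        rng = np.random.default_rng(cfg.seed)
        d = cfg.latent_dim
        enc_widths = [n_features, *cfg.hidden_widths]
        self.encoder = _Stack(enc_widths, rng, 2 * d if variational else d)
        dec_widths = [d, *reversed(cfg.hidden_widths)]
        self.decoder = _Stack(dec_widths, rng, n_features)
        self._rng = rng  # shuffling + reparameterization sampling

    # -- forward pieces -----------------------------------------------------

    def encode_batch(self, x: np.ndarray, training: bool = False):
        """Returns (code, mean, logvar); mean/logvar are None for the AE."""
        h = self.encoder.forward(x, training)
        if not self.variational:
            return h, None, None
        d = self.cfg.latent_dim
        return None, h[:, :d], h[:, d:]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Deterministic codes in inference mode (VAE: posterior mean)."""
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"model trained on {self.n_features} columns, got {x.shape[1]}"
            )
        code, mean, _ = self.encode_batch(x, training=False)
        return code if not self.variational else mean

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.transform(x), training=False)

    # -- one training step --------------------------------------------------

    def _train_step(self, x: np.ndarray, optimizer: _Adam) -> tuple[float, float]:
        n = x.shape[0]
        if self.variational:
            _, mean, logvar = self.encode_batch(x, training=True)
            eps = self._rng.standard_normal(mean.shape)
            z = mean + np.exp(0.5 * logvar) * eps
        else:
            z, _, _ = self.encode_batch(x, training=True)
            mean = logvar = None
        x_hat = self.decoder.forward(z, training=True)

        recon = reconstruction_loss(x, x_hat)
        kl = 0.0
        dz = self.decoder.backward(2.0 * (x_hat - x) / n)
        if self.variational:
            variance = np.exp(logvar)
            kl = kl_term(mean, variance, self.cfg.beta)
            assert kl >= -1e-9, "KL term must be non-negative"
            beta = self.cfg.beta
            dmean = dz + beta * mean / n
            # d z / d logvar = 0.5 * sd * eps; d KL / d logvar = (beta/2)(V-1)/n
            dlogvar = dz * 0.5 * (z - mean) + (beta / 2.0) * (variance - 1.0) / n
            self.encoder.backward(np.hstack([dmean, dlogvar]))
        else:
            self.encoder.backward(dz)
        optimizer.step()
        return recon, kl


def train_autoencoder(
    table: FeatureTable | np.ndarray,
    cfg: TrainingConfig,
    variational: bool = False,
) -> tuple[Autoencoder, EmbeddingMatrix, list[dict]]:
    """Fit an AE (or VAE) to the feature table and embed every row.

    Returns the trained model, the deterministic embedding (VAE: posterior
    means) and a per-epoch loss history
    (``[{"epoch", "loss", "reconstruction", "kl"}, ...]``).  Training stops
    early when the total loss improves by less than ``cfg.early_stop_tol``
    for ``cfg.early_stop_patience`` consecutive epochs.  Fully reproducible
    given ``cfg.seed``.
    """
    x = table.values if isinstance(table, FeatureTable) else np.asarray(table, float)
    m = x.shape[0]
    batch_size = cfg.batch_size
    if m < 2 * batch_size:
        batch_size = max(1, m // 2)
        warnings.warn(
            f"table has {m} rows < 2*batch_size; reducing batch_size to {batch_size}",
            stacklevel=2,
        )

    model = Autoencoder(x.shape[1], cfg, variational)
    optimizer = _Adam(model.encoder.params() + model.decoder.params(), cfg.learning_rate)

    history: list[dict] = []
    best = np.inf
    stall = 0
    for epoch in range(cfg.epochs):
        order = model._rng.permutation(m)
        recon_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, m, batch_size):
            batch = x[order[start : start + batch_size]]
            recon, kl = model._train_step(batch, optimizer)
            if not np.isfinite(recon + kl):
                raise RuntimeError(
                    f"loss became non-finite at epoch {epoch}; lower the "
                    f"learning rate (currently {cfg.learning_rate:g})"
                )
            recon_sum += recon
            kl_sum += kl
            n_batches += 1
        epoch_recon = recon_sum / n_batches
        epoch_kl = kl_sum / n_batches
        loss = epoch_recon + epoch_kl
        history.append(
            {"epoch": epoch, "loss": loss, "reconstruction": epoch_recon, "kl": epoch_kl}
        )
        if best - loss < cfg.early_stop_tol:
            stall += 1
            if stall >= cfg.early_stop_patience:
                logger.info("early stop at epoch %d (loss %.6g)", epoch, loss)
                break
        else:
            stall = 0
        best = min(best, loss)

    embedding = EmbeddingMatrix(
        values=model.transform(x),
        source="VAE" if variational else "AE",
        config=cfg,
    )
    return model, embedding, history


def encode(model: Autoencoder, table: FeatureTable | np.ndarray) -> EmbeddingMatrix:
    """Deterministic, row-aligned codes for *table* (VAE: posterior means)."""
    x = table.values if isinstance(table, FeatureTable) else np.asarray(table, float)
    return EmbeddingMatrix(
        values=model.transform(x),
        source="VAE" if model.variational else "AE",
        config=model.cfg,
    )
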