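"""Variational autoencoder denoising of the normalized feature matrix.

The encoder is a stack of fully connected layers with batch normalization
and ReLU, halving in width from ``initial_hidden`` down to mean and
log-variance heads over a low-dimensional latent space; the decoder mirrors
the widths in reverse but omits batch normalization so reconstruction is
free to match the input distribution. Log-variance is clamped to a fixed
interval before reparameterized sampling to avoid numerical blow-ups, and
the loss is mean-squared reconstruction error plus a small beta-weighted KL
divergence to a standard-normal prior.

Representation quality is judged the same way the classifier will use it:
seeded mini-batch k-means with k = 3 (the three target-effect classes)
scored by adjusted Rand index and normalized mutual information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from sklearn.cluster import MiniBatchKMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from ._nn import Activation, Adam, BatchNorm, Dense, Sequential, mlp
from .features import FeatureMatrix


class VAEConfigError(ValueError):
    pass


class TrainingDivergence(RuntimeError):
    pass


@dataclass
class VAEConfig:
    input_dim: int
    initial_hidden: int = 1500
    n_encoder_layers: int = 5
    latent_dim: int = 100
    beta: float = 0.001
    logvar_clamp: tuple[float, float] = (-5.0, 5.0)
    batch_size: int = 1024
    learning_rate: float = 0.001
    max_epochs: int = 30
    seed: int = 0

    def hidden_widths(self) -> list[int]:
        """Halving schedule; the final encoder layer is the latent heads."""
        widths = [self.initial_hidden // (2**i) for i in range(self.n_encoder_layers - 1)]
        return widths

    def validate(self) -> None:
        if self.input_dim < self.latent_dim:
            raise VAEConfigError(
                f"input_dim {self.input_dim} smaller than latent_dim {self.latent_dim}"
            )
        widths = self.hidden_widths()
        if any(b >= a for a, b in zip(widths[:-1], widths[1:])):
            raise VAEConfigError("hidden widths must be strictly decreasing")
        if widths and widths[-1] <= self.latent_dim:
            raise VAEConfigError(
                f"halving yields hidden width {widths[-1]} <= latent_dim "
                f"{self.latent_dim}; use fewer layers or a larger initial_hidden"
            )
        if self.beta < 0:
            raise VAEConfigError("beta must be >= 0")
        lo, hi = self.logvar_clamp
        if lo >= hi:
            raise VAEConfigError("logvar_clamp interval is empty")


class VAE:
    """Trained model: encoder trunk, latent heads, mirrored decoder."""

    def __init__(self, config: VAEConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = config.hidden_widths()
        self.encoder = mlp([config.input_dim, *widths], rng, batch_norm=True)
        last = widths[-1] if widths else config.input_dim
        self.mu_head = Dense(last, config.latent_dim, rng)
        self.logvar_head = Dense(last, config.latent_dim, rng)
        dec_widths = [config.latent_dim, *reversed(widths)]
        self.decoder = mlp(dec_widths, rng, batch_norm=False)
        self.out_head = Dense(dec_widths[-1], config.input_dim, rng)
        self.col_names: list[str] | None = None
        self.loss_history: list[dict] = []

    def _modules(self):
        return [self.encoder, self.mu_head, self.logvar_head, self.decoder, self.out_head]

    def encode_params(self, x: np.ndarray, train: bool = False):
        h = self.encoder.forward(x, train=train)
        mu = self.mu_head.forward(h, train=train)
        logvar = self.logvar_head.forward(h, train=train)
        lo, hi = self.config.logvar_clamp
        clamped = np.clip(logvar, lo, hi)
        return mu, clamped, (logvar > lo) & (logvar < hi)

    def decode_latent(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.out_head.forward(self.decoder.forward(z, train=train), train=train)

    def _loss_and_grads(self, x: np.ndarray, rng: np.random.Generator):
        """One forward/backward pass; returns (recon, kl) for the batch."""
        m = x.shape[0]
        mu, logvar, clamp_mask = self.encode_params(x, train=True)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * logvar)
        z = mu + eps * std
        xhat = self.decode_latent(z, train=True)

        recon = float(((xhat - x) ** 2).sum() / m)
        kl = float(-0.5 * (1 + logvar - mu**2 - np.exp(logvar)).sum() / m)

        dxhat = 2.0 * (xhat - x) / m
        dz = self.decoder.backward(self.out_head.backward(dxhat))
        beta = self.config.beta
        dmu = dz + beta * mu / m
        dlogvar = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(logvar) - 1.0) / m
        dlogvar = np.where(clamp_mask, dlogvar, 0.0)
        dh = self.mu_head.backward(dmu) + self.logvar_head.backward(dlogvar)
        self.encoder.backward(dh)
        return recon, kl

    def _eval_loss(self, x: np.ndarray, rng: np.random.Generator):
        mu, logvar, _ = self.encode_params(x, train=False)
        eps = rng.standard_normal(mu.shape)
        z = mu + eps * np.exp(0.5 * logvar)
        xhat = self.decode_latent(z, train=False)
        m = x.shape[0]
        recon = float(((xhat - x) ** 2).sum() / m)
        kl = float(-0.5 * (1 + logvar - mu**2 - np.exp(logvar)).sum() / m)
        return recon, kl


def build_vae(config: VAEConfig) -> VAE:
    """Construct an untrained model from a validated configuration."""
    return VAE(config)


def train_vae(
    F: FeatureMatrix,
    config: VAEConfig,
    holdout_fraction: float = 0.10,
) -> VAE:
    """Train on a normalized feature matrix with a seeded 10% row holdout.

    Per-epoch train/validation (reconstruction, KL) pairs are recorded in
    ``model.loss_history``; non-finite losses abort with the epoch index.
    """
    n = F.shape[0]
    if n < 2 / max(1e-9, 1 - holdout_fraction):
        raise ValueError("too few rows for the requested holdout fraction")
    if F.shape[1] != config.input_dim:
        raise VAEConfigError(
            f"matrix has {F.shape[1]} columns but config.input_dim={config.input_dim}"
        )
    model = build_vae(config)
    model.col_names = list(F.col_names)
    rng = np.random.default_rng(config.seed + 1)
    perm = rng.permutation(n)
    n_val = max(1, int(round(holdout_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, Xval = F.values[train_idx], F.values[val_idx]
    opt = Adam(model._modules(), lr=config.learning_rate)
    bs = config.batch_size
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        recon_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, len(Xtr), bs):
            batch = Xtr[order[start : start + bs]]
            if batch.shape[0] < 2:
                continue  # batch norm needs at least two rows
            recon, kl = model._loss_and_grads(batch, rng)
            total = recon + config.beta * kl
            if not np.isfinite(total):
                raise TrainingDivergence(f"non-finite loss at epoch {epoch}")
            opt.step()
            recon_sum += recon
            kl_sum += kl
            n_batches += 1
        val_recon, val_kl = model._eval_loss(Xval, rng)
        if not np.isfinite(val_recon + val_kl):
            raise TrainingDivergence(f"non-finite validation loss at epoch {epoch}")
        model.loss_history.append(
            {
                "epoch": epoch,
                "train_recon": recon_sum / max(1, n_batches),
                "train_kl": kl_sum / max(1, n_batches),
                "val_recon": val_recon,
                "val_kl": val_kl,
            }
        )
    return model


def encode(model: VAE, F: FeatureMatrix, sample: bool = False,
           seed: int | None = None) -> FeatureMatrix:
    """Posterior-mean latent representation (deterministic by default).

    ``sample=True`` draws one reparameterized sample per row instead; used
    only for synthetic augmentation, never for downstream scoring.
    """
    if model.col_names is not None and F.col_names != model.col_names:
        raise ValueError("feature columns do not match the trained model")
    mu, logvar, _ = model.encode_params(F.values, train=False)
    z = mu
    if sample:
        rng = np.random.default_rng(model.config.seed if seed is None else seed)
        z = mu + rng.standard_normal(mu.shape) * np.exp(0.5 * logvar)
    names = [f"z{i}" for i in range(z.shape[1])]
    return FeatureMatrix(list(F.row_ids), names, z, stage="latent")


def decode(model: VAE, latent: FeatureMatrix) -> FeatureMatrix:
    """Map latent rows back to the input feature space (same columns)."""
    if latent.shape[1] != model.config.latent_dim:
        raise ValueError("latent width does not match the model")
    xhat = model.decode_latent(latent.values, train=False)
    names = model.col_names or [f"x{i}" for i in range(xhat.shape[1])]
    return FeatureMatrix(list(latent.row_ids), list(names), xhat, stage="decoded")


def denoise(model: VAE, F: FeatureMatrix) -> FeatureMatrix:
    """decode(encode(F)) — the representation fed to the classifier."""
    return decode(model, encode(model, F))


def evaluate_representation(
    F: FeatureMatrix, labels: np.ndarray, k: int = 3, seed: int = 0
) -> dict:
    """Cluster rows with seeded mini-batch k-means and score against labels."""
    labels = np.asarray(labels)
    if F.shape[0] != labels.shape[0]:
        raise ValueError("label vector length mismatch")
    if 2 in set(labels.tolist()):
        raise ValueError("ambiguous-class labels must be excluded")
    if F.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3, batch_size=256)
    assign = km.fit_predict(F.values)
    return {
        "space": F.stage,
        "k": k,
        "ari": float(adjusted_rand_score(labels, assign)),
        "nmi": float(normalized_mutual_info_score(labels, assign)),
    }
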