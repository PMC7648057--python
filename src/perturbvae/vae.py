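"""Variational autoencoder for perturbation expression profiles.

Architecture: a tanh multilayer encoder whose last hidden layer feeds two
affine heads, the posterior mean mu(x) and log-variance (so the diagonal
covariance Sigma(x) = exp(logvar) is positive by construction); a mirrored
tanh decoder whose final affine output passes through tanh and is rescaled
by ``output_scale`` so reconstructions stay inside the z-score range
[-output_scale, +output_scale]. The latent prior is N(0, I).

Objective: reconstruction + KL. The reconstruction term is the per-sample
sum of squared errors averaged over the batch (Gaussian-likelihood ELBO
scaling; the per-element MSE is logged alongside), and the KL term is the
closed-form Gaussian divergence summed over latent dimensions and averaged
over the batch. Optimization is Adam on seeded mini-batches.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._nn import Adam, Linear, Sequential, Tanh, tanh_stack, zero_grads
from .data_model import ExpressionDataset

LOGVAR_CLIP = 15.0


class ShapeError(ValueError):
    """Input vector length does not match the model."""


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite during optimization."""


@dataclass
class VAEConfig:
    """``layer_sizes`` are the encoder hidden widths; the last entry is the
    latent (top hidden layer) dimension. The decoder mirrors the encoder."""

    input_dim: int = 978
    layer_sizes: tuple = (1000, 1000, 100)
    output_scale: float = 10.0
    epochs: int = 300
    batch_size: int = 512
    learning_rate: float = 1e-3
    seed: int = 0
    train_fraction: float = 0.9

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if len(self.layer_sizes) < 1 or self.layer_sizes[-1] < 1:
            raise ValueError("layer_sizes must end in a latent dimension >= 1")
        if self.output_scale <= 0:
            raise ValueError("output_scale must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def latent_dim(self) -> int:
        return self.layer_sizes[-1]

    @property
    def hidden_sizes(self) -> tuple:
        return self.layer_sizes[:-1]


@dataclass
class VAELossBreakdown:
    """reconstruction: per-sample SSE averaged over the batch; kl: Gaussian
    KL to N(0, I) summed over dimensions, batch-averaged; total = sum.
    ``mse_per_gene`` is the same reconstruction error per matrix element."""

    reconstruction: float
    kl: float
    total: float
    mse_per_gene: float = 0.0


class VAEModel:
    """Encoder/decoder parameter sets plus the Gaussian latent head."""

    def __init__(self, cfg: VAEConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        hidden = list(cfg.hidden_sizes)
        enc_sizes = [cfg.input_dim] + hidden
        self.enc_hidden = tanh_stack(enc_sizes, rng)
        enc_out = enc_sizes[-1]
        self.mu_head = Linear(enc_out, cfg.latent_dim, rng)
        self.logvar_head = Linear(enc_out, cfg.latent_dim, rng)
        dec_sizes = [cfg.latent_dim] + hidden[::-1]
        self.dec_hidden = tanh_stack(dec_sizes, rng)
        self.out_head = Linear(dec_sizes[-1], cfg.input_dim, rng)
        self._out_tanh: np.ndarray | None = None

    # ---- parameter plumbing -------------------------------------------
    @property
    def params(self):
        return (self.enc_hidden.params + self.mu_head.params
                + self.logvar_head.params + self.dec_hidden.params
                + self.out_head.params)

    @property
    def grads(self):
        return (self.enc_hidden.grads + self.mu_head.grads
                + self.logvar_head.grads + self.dec_hidden.grads
                + self.out_head.grads)

    # ---- forward pieces ------------------------------------------------
    def _as_batch(self, x) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        return x, single

    def encode(self, x):
        """Deterministic posterior parameters (mu, sigma2) for x."""
        xb, single = self._as_batch(x)
        if xb.shape[1] != self.cfg.input_dim:
            raise ShapeError(
                f"expected input of length {self.cfg.input_dim}, got {xb.shape[1]}")
        h = self.enc_hidden.forward(xb)
        mu = self.mu_head.forward(h)
        logvar = np.clip(self.logvar_head.forward(h), -LOGVAR_CLIP, LOGVAR_CLIP)
        sigma2 = np.exp(logvar)
        if single:
            return mu[0], sigma2[0]
        return mu, sigma2

    def decode(self, z):
        """Map latents to profiles; outputs lie in (-scale, +scale)."""
        zb, single = self._as_batch(z)
        if zb.shape[1] != self.cfg.latent_dim:
            raise ShapeError(
                f"expected latent of length {self.cfg.latent_dim}, got {zb.shape[1]}")
        h = self.dec_hidden.forward(zb)
        self._out_tanh = np.tanh(self.out_head.forward(h))
        out = self.cfg.output_scale * self._out_tanh
        if single:
            return out[0]
        return out


def reparameterized_sample(mu, sigma2, seed=None, rng=None):
    """z = mu + sqrt(sigma2) * eps with eps ~ N(0, I)."""
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if mu.shape != sigma2.shape:
        raise ShapeError("mu and sigma2 must have matching shapes")
    if np.any(sigma2 < 0):
        raise ValueError("sigma2 must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.standard_normal(mu.shape)
    return mu + np.sqrt(sigma2) * eps


def gaussian_kl(mu, sigma2):
    """Closed-form KL(N(mu, diag(sigma2)) || N(0, I)) summed over the last
    axis; batch inputs return per-sample values."""
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    return 0.5 * np.sum(mu ** 2 + sigma2 - 1.0 - np.log(sigma2), axis=-1)


def vae_loss(model: VAEModel, batch, sample: bool = False, seed=None) -> VAELossBreakdown:
    """Loss breakdown on a batch. Reconstruction decodes mu(x) by default
    (set ``sample=True`` for a reparameterized draw)."""
    x = np.atleast_2d(np.asarray(batch, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    mu, sigma2 = model.encode(x)
    z = reparameterized_sample(mu, sigma2, seed=seed) if sample else mu
    xhat = model.decode(z)
    if not np.all(np.isfinite(xhat)):
        raise TrainingDivergenceError("non-finite reconstruction")
    sq = (xhat - x) ** 2
    recon = float(sq.sum(axis=1).mean())
    kl = float(gaussian_kl(mu, sigma2).mean())
    return VAELossBreakdown(reconstruction=recon, kl=kl, total=recon + kl,
                            mse_per_gene=float(sq.mean()))


def _train_val_split(n: int, train_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return perm[:n_train], perm[n_train:]


def train_vae(data: ExpressionDataset, cfg: VAEConfig):
    """Train by seeded mini-batch Adam on a random train/validation split.

    Returns (model, log) where log is a DataFrame with per-epoch train and
    validation losses and their reconstruction/KL components.
    """
    X = data.matrix
    if X.shape[0] < cfg.batch_size:
        raise ValueError(
            f"need at least batch_size={cfg.batch_size} samples, have {X.shape[0]}")
    if X.shape[1] != cfg.input_dim:
        raise ShapeError(
            f"data has {X.shape[1]} genes but config expects {cfg.input_dim}")
    rng = np.random.default_rng(cfg.seed)
    model = VAEModel(cfg, rng=rng)
    train_idx, val_idx = _train_val_split(X.shape[0], cfg.train_fraction, rng)
    X_train, X_val = X[train_idx], X[val_idx]
    opt = Adam(model.params, lr=cfg.learning_rate)
    records = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(X_train.shape[0])
        epoch_tot = epoch_rec = epoch_kl = 0.0
        n_batches = 0
        for start in range(0, X_train.shape[0], cfg.batch_size):
            xb = X_train[order[start:start + cfg.batch_size]]
            tot, rec, kl = _vae_batch_step(model, xb, opt, rng)
            if not np.isfinite(tot):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}: total={tot}")
            epoch_tot += tot
            epoch_rec += rec
            epoch_kl += kl
            n_batches += 1
        val = vae_loss(model, X_val, sample=True,
                       seed=int(rng.integers(2 ** 31)))
        records.append({
            "epoch": epoch,
            "train_loss": epoch_tot / n_batches,
            "val_loss": val.total,
            "recon": val.reconstruction,
            "kl": val.kl,
            "mse_per_gene": val.mse_per_gene,
        })
    log = pd.DataFrame(records)
    return model, log


def _vae_batch_step(model: VAEModel, x: np.ndarray, opt: Adam, rng):
    """One Adam step; returns (total, reconstruction, kl) for the batch."""
    cfg = model.cfg
    B = x.shape[0]
    h = model.enc_hidden.forward(x)
    mu = model.mu_head.forward(h)
    logvar_raw = model.logvar_head.forward(h)
    clip_mask = (np.abs(logvar_raw) < LOGVAR_CLIP).astype(float)
    logvar = np.clip(logvar_raw, -LOGVAR_CLIP, LOGVAR_CLIP)
    sigma2 = np.exp(logvar)
    std = np.exp(0.5 * logvar)
    eps = rng.standard_normal(mu.shape)
    z = mu + std * eps
    hd = model.dec_hidden.forward(z)
    t = np.tanh(model.out_head.forward(hd))
    xhat = cfg.output_scale * t

    sq = (xhat - x) ** 2
    recon = float(sq.sum(axis=1).mean())
    kl = float((0.5 * (mu ** 2 + sigma2 - 1.0 - logvar)).sum(axis=1).mean())
    total = recon + kl

    zero_grads(model.grads)
    d_xhat = 2.0 * (xhat - x) / B
    d_pre = d_xhat * cfg.output_scale * (1.0 - t ** 2)
    d_hd = model.out_head.backward(d_pre)
    d_z = model.dec_hidden.backward(d_hd)
    d_mu = d_z + mu / B
    d_logvar = (d_z * std * eps * 0.5 + 0.5 * (sigma2 - 1.0) / B) * clip_mask
    d_h = model.mu_head.backward(d_mu) + model.logvar_head.backward(d_logvar)
    model.enc_hidden.backward(d_h)
    opt.step(model.grads)
    return total, recon, kl


def generate_samples(model: VAEModel, n: int, seed=None,
                     gene_ids=None) -> ExpressionDataset:
    """Ancestral sampling: z ~ N(0, I) decoded to profiles."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.cfg.latent_dim))
    X = model.decode(z)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(model.cfg.input_dim)]
    meta = pd.DataFrame({
        "sample_id": [f"GEN{i:06d}" for i in range(n)],
        "perturbagen_id": None,
        "pert_type": "generated",
        "cell_line": None,
        "pcl_label": None,
        "target_gene": None,
    })
    return ExpressionDataset(matrix=X, gene_ids=list(gene_ids), sample_meta=meta,
                             provenance={"source": "vae-generated", "seed": seed})


# ---- checkpointing -----------------------------------------------------

def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.save(buf, arr)
    return buf.getvalue()


def write_zip_deterministic(path, entries: dict) -> None:
    """Zip archive with fixed timestamps so identical contents give
    identical bytes (reruns with the same seed reproduce checkpoints
    bit-for-bit)."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, payload in entries.items():
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, payload)


def save_checkpoint(model: VAEModel, path) -> None:
    entries = {"config.json": json.dumps(asdict(model.cfg))}
    for i, p in enumerate(model.params):
        entries[f"p{i}.npy"] = _npy_bytes(p)
    write_zip_deterministic(path, entries)


def load_checkpoint(path) -> VAEModel:
    with zipfile.ZipFile(path) as zf:
        cfg = VAEConfig(**json.loads(zf.read("config.json")))
        model = VAEModel(cfg)
        for i, p in enumerate(model.params):
            p[...] = np.load(io.BytesIO(zf.read(f"p{i}.npy")))
    return model
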