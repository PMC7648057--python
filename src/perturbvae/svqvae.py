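"""Supervised vector-quantized VAE (S-VQ-VAE).

A codebook E of Y class embeddings (one per perturbagen class, dimension D)
is learned jointly with a tanh encoder/decoder. During training the encoder
output z_e(x) is replaced by the embedding of the sample's own class,
z_q = e_y, before decoding; at test time by the nearest code e_k,
k = argmin_j ||z_e - e_j|| (ties to the lowest index).

The objective combines five terms:

    L = l_r(x, d(e_y))                      reconstruction (decoder, and the
                                            encoder via straight-through)
      + ||sg[z_e] - e_y||^2                 dictionary: pulls e_y to z_e
      + beta * ||z_e - sg[e_y]||^2          commitment: pulls z_e to e_y
      - 1(k != y) * ( ||sg[z_e] - e_k||^2   misclass dictionary: pushes the
                                            wrong nearest code away
      + gamma * ||z_e - sg[e_k]||^2 )       divergence: pushes z_e away from
                                            the wrong nearest code

where sg[.] is stop-gradient. The quantization step has no gradient, so the
reconstruction gradient at z_q is copied straight through to z_e; codebook
rows receive gradient only from the dictionary/misclass terms and the
decoder only from reconstruction.

Class-conditional generation is ancestral: draw a class y (training-set
multinomial), draw z ~ N(e_y, diag(sigma2_y)) with sigma2_y the per-class
sample variance of training encodings, and decode.
"""

from __future__ import annotations

import io
import json
import zipfile
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._nn import Adam, Linear, tanh_stack, zero_grads
from .data_model import ExpressionDataset, SchemaError
from .vae import (ShapeError, TrainingDivergenceError, _npy_bytes,
                  write_zip_deterministic)


class LabelError(KeyError):
    """Unknown class label."""


class StateError(RuntimeError):
    """Operation requires state (codebook, class statistics) not yet built."""


@dataclass
class SVQVAEConfig:
    input_dim: int = 978
    hidden_sizes: tuple = (1000,)
    embedding_dim: int = 1000
    n_classes: int = 75
    beta: float = 0.25
    gamma: float = 0.1
    output_scale: float = 10.0
    epochs: int = 900
    batch_size: int = 256
    learning_rate: float = 1e-4
    seed: int = 0
    train_fraction: float = 0.9
    codebook_init: str = "uniform"  # or "class_means"
    codebook_init_scale: float = 0.05

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(s) for s in self.hidden_sizes)
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be non-negative")


@dataclass
class SVQVAELossBreakdown:
    """Batch-averaged loss components. ``commitment`` includes beta and
    ``divergence`` includes gamma; the misclass terms are zero whenever the
    nearest code is the sample's own class."""

    reconstruction: float
    dictionary: float
    commitment: float
    misclass_dictionary: float
    divergence: float
    total: float


class SVQVAEModel:
    def __init__(self, cfg: SVQVAEConfig, class_labels=None,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        hidden = list(cfg.hidden_sizes)
        self.enc_hidden = tanh_stack([cfg.input_dim] + hidden, rng)
        enc_out = hidden[-1] if hidden else cfg.input_dim
        self.enc_head = Linear(enc_out, cfg.embedding_dim, rng)
        dec_sizes = [cfg.embedding_dim] + hidden[::-1]
        self.dec_hidden = tanh_stack(dec_sizes, rng)
        self.out_head = Linear(dec_sizes[-1], cfg.input_dim, rng)
        s = cfg.codebook_init_scale
        self.E = rng.uniform(-s, s, size=(cfg.n_classes, cfg.embedding_dim))
        self.gE = np.zeros_like(self.E)
        if class_labels is None:
            class_labels = [f"class_{i}" for i in range(cfg.n_classes)]
        if len(class_labels) != cfg.n_classes:
            raise ValueError("class_labels length must equal n_classes")
        self.class_labels = list(class_labels)
        self._label_index = {l: i for i, l in enumerate(self.class_labels)}
        self.class_counts: np.ndarray | None = None
        self.class_sigma2: np.ndarray | None = None

    # ---- label plumbing ----------------------------------------------
    def label_to_index(self, y):
        y = np.atleast_1d(np.asarray(y, dtype=object))
        idx = np.empty(len(y), dtype=int)
        for i, lbl in enumerate(y):
            if isinstance(lbl, (int, np.integer)) and lbl not in self._label_index:
                if not 0 <= int(lbl) < self.cfg.n_classes:
                    raise LabelError(f"class index {lbl} out of range")
                idx[i] = int(lbl)
            elif lbl in self._label_index:
                idx[i] = self._label_index[lbl]
            else:
                raise LabelError(f"unknown class label {lbl!r}")
        return idx

    # ---- forward pieces ----------------------------------------------
    @property
    def params(self):
        return (self.enc_hidden.params + self.enc_head.params
                + self.dec_hidden.params + self.out_head.params + [self.E])

    @property
    def grads(self):
        return (self.enc_hidden.grads + self.enc_head.grads
                + self.dec_hidden.grads + self.out_head.grads + [self.gE])

    def encode(self, x):
        xb = np.atleast_2d(np.asarray(x, dtype=float))
        if xb.shape[1] != self.cfg.input_dim:
            raise ShapeError(
                f"expected input of length {self.cfg.input_dim}, got {xb.shape[1]}")
        return self.enc_head.forward(self.enc_hidden.forward(xb))

    def decode(self, z):
        zb = np.atleast_2d(np.asarray(z, dtype=float))
        if zb.shape[1] != self.cfg.embedding_dim:
            raise ShapeError(
                f"expected code of length {self.cfg.embedding_dim}, got {zb.shape[1]}")
        h = self.dec_hidden.forward(zb)
        t = np.tanh(self.out_head.forward(h))
        self._out_tanh = t
        return self.cfg.output_scale * t


def nearest_embedding(E: np.ndarray, z_e: np.ndarray):
    """Index of the Euclidean-nearest codebook row; ties -> lowest index.

    ``E`` may be an ``SVQVAEModel`` (its codebook is used) or a Y x D array.
    Accepts a single vector or a batch."""
    if isinstance(E, SVQVAEModel):
        E = E.E
    E = np.asarray(E, dtype=float)
    if E.size == 0:
        raise StateError("empty codebook")
    z = np.asarray(z_e, dtype=float)
    single = z.ndim == 1
    zb = np.atleast_2d(z)
    if zb.shape[1] != E.shape[1]:
        raise ShapeError(
            f"encoding length {zb.shape[1]} != codebook dimension {E.shape[1]}")
    # squared distances via expansion; argmin keeps the first minimum
    d2 = (zb ** 2).sum(1)[:, None] - 2.0 * zb @ E.T + (E ** 2).sum(1)[None, :]
    k = np.argmin(d2, axis=1)
    return int(k[0]) if single else k


def svqvae_forward(model: SVQVAEModel, x, y=None, mode: str = "train"):
    """Returns (reconstruction, z_e, z_q, k). In train mode z_q = e_y (label
    lookup); in test mode z_q = e_k (nearest code). k is reported in both."""
    if mode not in ("train", "test"):
        raise ValueError(f"unknown mode {mode!r}")
    xb = np.atleast_2d(np.asarray(x, dtype=float))
    z_e = model.encode(xb)
    k = np.atleast_1d(nearest_embedding(model.E, z_e))
    if mode == "train":
        if y is None:
            raise LabelError("train mode requires class labels")
        y_idx = model.label_to_index(y)
        if len(y_idx) == 1 and len(z_e) > 1:
            y_idx = np.repeat(y_idx, len(z_e))
        z_q = model.E[y_idx]
    else:
        z_q = model.E[k]
    recon = model.decode(z_q)
    single = np.asarray(x).ndim == 1
    if single:
        return recon[0], z_e[0], z_q[0], int(k[0])
    return recon, z_e, z_q, k


def svqvae_loss(model: SVQVAEModel, x, y) -> SVQVAELossBreakdown:
    """Batch-averaged loss components; reconstruction uses the train-mode
    quantization z_q = e_y."""
    xb = np.atleast_2d(np.asarray(x, dtype=float))
    recon, z_e, z_q, k = svqvae_forward(model, xb, y, mode="train")
    y_idx = model.label_to_index(y)
    if len(y_idx) == 1 and len(xb) > 1:
        y_idx = np.repeat(y_idx, len(xb))
    k = np.atleast_1d(k)
    e_y = model.E[y_idx]
    e_k = model.E[k]
    mis = (k != y_idx).astype(float)
    l_r = float(((recon - xb) ** 2).sum(axis=1).mean())
    dict_core = float(((z_e - e_y) ** 2).sum(axis=1).mean())
    mis_core = float((mis * ((z_e - e_k) ** 2).sum(axis=1)).mean())
    out = SVQVAELossBreakdown(
        reconstruction=l_r,
        dictionary=dict_core,
        commitment=model.cfg.beta * dict_core,
        misclass_dictionary=mis_core,
        divergence=model.cfg.gamma * mis_core,
        total=0.0,
    )
    out.total = (out.reconstruction + out.dictionary + out.commitment
                 - out.misclass_dictionary - out.divergence)
    if not np.isfinite(out.total):
        raise TrainingDivergenceError("non-finite S-VQ-VAE loss")
    return out


def _svqvae_backward(model: SVQVAEModel, x: np.ndarray, y_idx: np.ndarray):
    """Forward + gradient accumulation (no optimizer step). Returns the
    loss breakdown. Gradients land in ``model.grads``."""
    cfg = model.cfg
    B = x.shape[0]
    z_e = model.encode(x)
    k = np.atleast_1d(nearest_embedding(model.E, z_e))
    e_y = model.E[y_idx]
    e_k = model.E[k]
    mis = k != y_idx

    xhat = model.decode(e_y)
    t = model._out_tanh
    sq = (xhat - x) ** 2
    l_r = float(sq.sum(axis=1).mean())
    dict_core = float(((z_e - e_y) ** 2).sum(axis=1).mean())
    mis_core = float((mis * ((z_e - e_k) ** 2).sum(axis=1)).mean())

    zero_grads(model.grads)
    # reconstruction -> decoder, and straight-through copy to the encoder
    d_xhat = 2.0 * (xhat - x) / B
    d_pre = d_xhat * cfg.output_scale * (1.0 - t ** 2)
    d_hd = model.out_head.backward(d_pre)
    d_zq = model.dec_hidden.backward(d_hd)
    d_ze = d_zq.copy()
    # commitment pulls z_e toward sg[e_y]
    d_ze += 2.0 * cfg.beta * (z_e - e_y) / B
    # divergence pushes z_e away from sg[e_k] when k != y
    d_ze[mis] -= 2.0 * cfg.gamma * (z_e - e_k)[mis] / B
    d_h = model.enc_head.backward(d_ze)
    model.enc_hidden.backward(d_h)
    # codebook: dictionary pulls e_y toward sg[z_e]; misclass pushes e_k away
    np.add.at(model.gE, y_idx, 2.0 * (e_y - z_e) / B)
    if mis.any():
        np.add.at(model.gE, k[mis], 2.0 * (z_e - e_k)[mis] / B)

    breakdown = SVQVAELossBreakdown(
        reconstruction=l_r,
        dictionary=dict_core,
        commitment=cfg.beta * dict_core,
        misclass_dictionary=mis_core,
        divergence=cfg.gamma * mis_core,
        total=l_r + dict_core + cfg.beta * dict_core
              - mis_core - cfg.gamma * mis_core,
    )
    return breakdown


def _stratified_split(y_idx: np.ndarray, train_fraction: float, rng):
    """Per-class split so every class present in the data appears in the
    training fold (classes with a single sample go entirely to training)."""
    train, val = [], []
    for c in np.unique(y_idx):
        members = np.flatnonzero(y_idx == c)
        members = members[rng.permutation(len(members))]
        n_val = int(round((1.0 - train_fraction) * len(members)))
        n_val = min(n_val, len(members) - 1)
        val.extend(members[:n_val])
        train.extend(members[n_val:])
    return np.array(sorted(train)), np.array(sorted(val))


def codebook_accuracy(model: SVQVAEModel, X: np.ndarray, y_idx: np.ndarray) -> float:
    """Fraction of samples whose nearest code is their own class."""
    k = np.atleast_1d(nearest_embedding(model.E, model.encode(X)))
    return float((k == y_idx).mean())


def train_svqvae(data: ExpressionDataset, cfg: SVQVAEConfig):
    """Train on PCL-labelled samples with a class-stratified validation
    split. Returns (model, log); the log tracks all loss components and the
    validation nearest-code label-match rate."""
    labels = data.sample_meta["pcl_label"]
    if labels.isna().any():
        raise SchemaError("every sample must carry a pcl_label")
    class_labels = sorted(labels.unique())
    if len(class_labels) != cfg.n_classes:
        cfg = SVQVAEConfig(**{**asdict(cfg), "n_classes": len(class_labels)})
    X = data.matrix
    rng = np.random.default_rng(cfg.seed)
    model = SVQVAEModel(cfg, class_labels=class_labels, rng=rng)
    y_idx = model.label_to_index(labels.to_numpy())

    train_idx, val_idx = _stratified_split(y_idx, cfg.train_fraction, rng)
    missing = set(range(cfg.n_classes)) - set(y_idx[train_idx])
    if missing:  # cannot happen with the stratified split, kept as a guard
        warnings.warn("classes absent from training split; re-splitting")
        train_idx, val_idx = _stratified_split(y_idx, cfg.train_fraction, rng)
    X_train, y_train = X[train_idx], y_idx[train_idx]
    X_val, y_val = X[val_idx], y_idx[val_idx]

    if cfg.codebook_init == "class_means":
        z0 = model.encode(X_train)
        for c in range(cfg.n_classes):
            members = y_train == c
            if members.any():
                model.E[c] = z0[members].mean(axis=0)

    opt = Adam(model.params, lr=cfg.learning_rate)
    records = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X_train))
        sums = np.zeros(6)
        n_batches = 0
        for start in range(0, len(X_train), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            br = _svqvae_backward(model, X_train[sel], y_train[sel])
            if not np.isfinite(br.total):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}")
            opt.step(model.grads)
            sums += [br.reconstruction, br.dictionary, br.commitment,
                     br.misclass_dictionary, br.divergence, br.total]
            n_batches += 1
        rec = dict(zip(
            ["reconstruction", "dictionary", "commitment",
             "misclass_dictionary", "divergence", "total"],
            sums / n_batches))
        rec["epoch"] = epoch
        rec["val_code_accuracy"] = (codebook_accuracy(model, X_val, y_val)
                                    if len(X_val) else np.nan)
        records.append(rec)

    # post-training statistics used for ancestral generation
    z_all = model.encode(X_train)
    model.class_counts = np.bincount(y_train, minlength=cfg.n_classes)
    sigma2 = np.zeros_like(model.E)
    for c in range(cfg.n_classes):
        members = y_train == c
        if members.sum() >= 2:
            sigma2[c] = z_all[members].var(axis=0, ddof=0)
    model.class_sigma2 = sigma2
    return model, pd.DataFrame(records)


def generate_class_conditional(model: SVQVAEModel, y, n: int,
                               sigma2_hat=None, seed=None) -> ExpressionDataset:
    """Decode n draws of z ~ N(e_y, diag(sigma2)) for class y."""
    if n <= 0:
        raise ValueError("n must be positive")
    y_idx = int(model.label_to_index(y)[0])
    if sigma2_hat is None:
        if model.class_sigma2 is None:
            raise StateError("per-class sigma2 unavailable; train first or "
                             "pass sigma2_hat")
        if model.class_counts is not None and model.class_counts[y_idx] == 0:
            raise StateError(f"class {y!r} never seen in training")
        sigma2_hat = model.class_sigma2[y_idx]
    sigma2_hat = np.asarray(sigma2_hat, dtype=float)
    rng = np.random.default_rng(seed)
    z = model.E[y_idx][None, :] + np.sqrt(sigma2_hat)[None, :] * \
        rng.standard_normal((n, model.cfg.embedding_dim))
    X = model.decode(z)
    label = model.class_labels[y_idx]
    meta = pd.DataFrame({
        "sample_id": [f"GEN_{label}_{i:05d}" for i in range(n)],
        "perturbagen_id": None,
        "pert_type": "generated",
        "cell_line": None,
        "pcl_label": label,
        "target_gene": None,
    })
    return ExpressionDataset(
        matrix=X, gene_ids=[f"G{i:04d}" for i in range(model.cfg.input_dim)],
        sample_meta=meta, provenance={"source": "svqvae-generated", "seed": seed})


def generate_unconditional(model: SVQVAEModel, n: int, seed=None) -> ExpressionDataset:
    """Ancestral sampling with the class drawn from the training multinomial."""
    if model.class_counts is None or model.class_counts.sum() == 0:
        raise StateError("class distribution unknown; train first")
    rng = np.random.default_rng(seed)
    probs = model.class_counts / model.class_counts.sum()
    counts = rng.multinomial(n, probs)
    parts = []
    for c, m in enumerate(counts):
        if m:
            parts.append(generate_class_conditional(
                model, model.class_labels[c], m,
                seed=int(rng.integers(2 ** 31))))
    matrix = np.vstack([p.matrix for p in parts])
    meta = pd.concat([p.sample_meta for p in parts], ignore_index=True)
    meta["sample_id"] = [f"GEN{i:06d}" for i in range(len(meta))]
    return ExpressionDataset(matrix=matrix, gene_ids=parts[0].gene_ids,
                             sample_meta=meta,
                             provenance={"source": "svqvae-generated", "seed": seed})


# ---- straight-through diagnostic --------------------------------------

def _surrogate_loss(model: SVQVAEModel, x: np.ndarray, y_idx: np.ndarray,
                    frozen: dict) -> float:
    """Scalar whose exact parameter gradient equals the straight-through
    gradient: stop-gradient arguments and the quantization detour are frozen
    at the reference forward pass."""
    cfg = model.cfg
    B = x.shape[0]
    z_e = model.encode(x)
    z_q = z_e + frozen["shift"]          # z_e + sg[e_y - z_e]
    xhat = model.decode(z_q)
    l_r = ((xhat - x) ** 2).sum(axis=1).mean()
    e_y = model.E[y_idx]
    dict_term = ((frozen["z_e0"] - e_y) ** 2).sum(axis=1).mean()
    commit = cfg.beta * ((z_e - frozen["e_y0"]) ** 2).sum(axis=1).mean()
    e_k = model.E[frozen["k0"]]
    mis = frozen["mis0"]
    mis_dict = (mis * ((frozen["z_e0"] - e_k) ** 2).sum(axis=1)).mean()
    div = cfg.gamma * (mis * ((z_e - frozen["e_k0"]) ** 2).sum(axis=1)).mean()
    return float(l_r + dict_term + commit - mis_dict - div)


def straight_through_check(model: SVQVAEModel, x, y, eps: float = 1e-6) -> float:
    """Max |analytic - finite-difference| gradient discrepancy over every
    parameter, with the stop-gradient contract made explicit. Small models
    only: cost is two forward passes per scalar parameter."""
    xb = np.atleast_2d(np.asarray(x, dtype=float))
    y_idx = model.label_to_index(y)
    if len(y_idx) == 1 and len(xb) > 1:
        y_idx = np.repeat(y_idx, len(xb))

    z_e0 = model.encode(xb)
    k0 = np.atleast_1d(nearest_embedding(model.E, z_e0))
    frozen = {
        "z_e0": z_e0.copy(),
        "e_y0": model.E[y_idx].copy(),
        "e_k0": model.E[k0].copy(),
        "k0": k0.copy(),
        "mis0": (k0 != y_idx).astype(float),
        "shift": (model.E[y_idx] - z_e0).copy(),
    }
    _svqvae_backward(model, xb, y_idx)
    analytic = [g.copy() for g in model.grads]

    worst = 0.0
    for p, g in zip(model.params, analytic):
        flat = p.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            up = _surrogate_loss(model, xb, y_idx, frozen)
            flat[i] = orig - eps
            dn = _surrogate_loss(model, xb, y_idx, frozen)
            flat[i] = orig
            fd = (up - dn) / (2.0 * eps)
            worst = max(worst, abs(fd - gflat[i]))
    return worst


# ---- checkpointing -----------------------------------------------------

def save_checkpoint(model: SVQVAEModel, path) -> None:
    entries = {
        "config.json": json.dumps(asdict(model.cfg)),
        "labels.json": json.dumps(model.class_labels),
    }
    for i, p in enumerate(model.params):
        entries[f"p{i}.npy"] = _npy_bytes(p)
    if model.class_counts is not None:
        entries["class_counts.npy"] = _npy_bytes(model.class_counts)
    if model.class_sigma2 is not None:
        entries["class_sigma2.npy"] = _npy_bytes(model.class_sigma2)
    write_zip_deterministic(path, entries)


def load_checkpoint(path) -> SVQVAEModel:
    with zipfile.ZipFile(path) as zf:
        cfg = SVQVAEConfig(**json.loads(zf.read("config.json")))
        labels = json.loads(zf.read("labels.json"))
        model = SVQVAEModel(cfg, class_labels=labels)
        names = set(zf.namelist())
        for i, p in enumerate(model.params):
            p[...] = np.load(io.BytesIO(zf.read(f"p{i}.npy")))
        if "class_counts.npy" in names:
            model.class_counts = np.load(io.BytesIO(zf.read("class_counts.npy")))
        if "class_sigma2.npy" in names:
            model.class_sigma2 = np.load(io.BytesIO(zf.read("class_sigma2.npy")))
    return model


def export_codebook(model: SVQVAEModel, path, sep: str = "\t") -> None:
    """Y x D codebook as a delimited matrix with class-label row names
    (input for the perturbagen-class similarity graph)."""
    pd.DataFrame(model.E, index=model.class_labels).to_csv(path, sep=sep)
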