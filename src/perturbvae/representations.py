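"""Per-sample latent representations and signature-node analysis.

A trained VAE yields seven representation types per sample: the raw
profile, the post-tanh activations of each encoder hidden layer, the
deterministic top-layer posterior mean mu(x), the signature-node subset of
the top layer, and the decoder hidden activations obtained by continuing
the forward pass from mu(x).

Signature nodes are the few top-layer units whose activations stay large
across samples while the rest shrink toward the N(0, 1) prior mean; they
carry the primary characteristics of a profile. They are found by exact
two-cluster splitting of the per-node mean absolute activation (a 1-d
2-means solved by scanning sorted split points, so discovery is
deterministic and globally optimal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_model import EmptyResultError, ExpressionDataset, SchemaError
from .vae import VAEModel


class RepresentationStateError(RuntimeError):
    """A representation was requested before its prerequisite exists."""


@dataclass
class LatentCodes:
    """A matrix of per-sample vectors from one named layer."""

    values: np.ndarray            # n_samples x width
    layer_tag: str
    sample_ids: list


@dataclass
class SignatureNodeSet:
    """High-activation top-layer node subset with per-node statistics."""

    indices: np.ndarray
    mean_abs_activation: np.ndarray   # all nodes
    variance: np.ndarray              # all nodes
    high_group_mean: float
    low_group_mean: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)


@dataclass
class PCLSignaturePattern:
    """Mean signature-node activation of one perturbagen class."""

    pcl_label: str
    values: np.ndarray
    n_samples: int = 0


def available_tags(model: VAEModel) -> list[str]:
    h = len(model.cfg.hidden_sizes)
    tags = ["raw"] + [f"enc{i}" for i in range(1, h + 1)] + ["top", "signature"]
    tags += [f"dec{i}" for i in range(1, h + 1)]
    return tags


def extract_representation(model: VAEModel, data, layer_tag: str,
                           signature: SignatureNodeSet | None = None) -> LatentCodes:
    """Deterministic per-sample codes from the tagged layer.

    ``raw`` returns the input unchanged; ``top`` is mu(x); ``enc<i>`` /
    ``dec<i>`` are post-tanh hidden activations (decoder layers computed by
    decoding mu(x)); ``signature`` is the top layer restricted to a
    discovered :class:`SignatureNodeSet`.
    """
    if isinstance(data, ExpressionDataset):
        X = data.matrix
        ids = data.sample_ids
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        ids = [str(i) for i in range(X.shape[0])]
    if layer_tag == "raw":
        return LatentCodes(values=X.copy(), layer_tag="raw", sample_ids=ids)

    mu, _ = model.encode(X)
    mu = np.atleast_2d(mu)
    if layer_tag == "top":
        return LatentCodes(values=mu, layer_tag="top", sample_ids=ids)
    if layer_tag == "signature":
        if signature is None:
            raise RepresentationStateError(
                "signature representation requires a discovered SignatureNodeSet")
        return LatentCodes(values=mu[:, signature.indices],
                           layer_tag="signature", sample_ids=ids)
    if layer_tag.startswith("enc"):
        acts = model.enc_hidden.hidden_activations()
        i = int(layer_tag[3:]) - 1
        if not 0 <= i < len(acts):
            raise ValueError(f"no encoder hidden layer for tag {layer_tag!r}")
        return LatentCodes(values=acts[i].copy(), layer_tag=layer_tag, sample_ids=ids)
    if layer_tag.startswith("dec"):
        model.decode(mu)
        acts = model.dec_hidden.hidden_activations()
        i = int(layer_tag[3:]) - 1
        if not 0 <= i < len(acts):
            raise ValueError(f"no decoder hidden layer for tag {layer_tag!r}")
        return LatentCodes(values=acts[i].copy(), layer_tag=layer_tag, sample_ids=ids)
    raise ValueError(f"unknown layer tag {layer_tag!r}")


def _two_means_split_1d(stat: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Exact 2-means on a 1-d statistic: scan every sorted split point and
    keep the within-cluster-SSE minimiser. Returns (high-group member mask,
    low mean, high mean)."""
    order = np.argsort(stat, kind="stable")
    s = stat[order]
    n = len(s)
    csum = np.cumsum(s)
    total = csum[-1]
    best_cost, best_split = np.inf, 1
    for split in range(1, n):
        lo_mean = csum[split - 1] / split
        hi_mean = (total - csum[split - 1]) / (n - split)
        cost = (np.sum((s[:split] - lo_mean) ** 2)
                + np.sum((s[split:] - hi_mean) ** 2))
        if cost < best_cost - 1e-15:
            best_cost, best_split = cost, split
    mask = np.zeros(n, dtype=bool)
    mask[order[best_split:]] = True
    lo = float(s[:best_split].mean())
    hi = float(s[best_split:].mean())
    return mask, lo, hi


def find_signature_nodes(codes: LatentCodes | np.ndarray) -> SignatureNodeSet:
    """Split top-layer nodes into low/high groups by mean |activation|.

    The statistic across nodes is expected to be bimodal: a handful of
    nodes with large activations against a background shrunk toward zero.
    A warning is raised when the two group means differ by less than a
    factor of 2 (unimodal / degenerate statistics)."""
    values = codes.values if isinstance(codes, LatentCodes) else np.atleast_2d(codes)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples to profile node activations")
    stat = np.abs(values).mean(axis=0)
    var = values.var(axis=0, ddof=0)
    if np.allclose(stat, stat[0]):
        warnings.warn("node activation statistics are identical; "
                      "no bimodal structure to split")
        return SignatureNodeSet(indices=np.arange(len(stat)),
                                mean_abs_activation=stat, variance=var,
                                high_group_mean=float(stat.mean()),
                                low_group_mean=float(stat.mean()))
    mask, lo, hi = _two_means_split_1d(stat)
    if lo <= 0 or hi / max(lo, 1e-300) < 2.0:
        warnings.warn(
            f"weak separation between node groups (means {hi:.4g} vs {lo:.4g}); "
            "activation statistic may be unimodal")
    return SignatureNodeSet(indices=np.flatnonzero(mask),
                            mean_abs_activation=stat, variance=var,
                            high_group_mean=hi, low_group_mean=lo)


def pcl_signature_pattern(codes: LatentCodes, labels, signature: SignatureNodeSet,
                          major_min: int = 150) -> list[PCLSignaturePattern]:
    """Mean signature-node activation per major PCL (>= ``major_min``
    treated samples), largest class first."""
    labels = pd.Series(list(labels))
    if labels.isna().all():
        raise SchemaError("labels required for PCL patterns")
    values = codes.values[:, signature.indices]
    counts = labels.dropna().value_counts()
    major = counts[counts >= major_min]
    if major.empty:
        raise EmptyResultError(
            f"no PCL reaches major_min={major_min} samples")
    patterns = []
    for lbl, n in sorted(major.items(), key=lambda t: (-t[1], str(t[0]))):
        members = (labels == lbl).to_numpy()
        patterns.append(PCLSignaturePattern(
            pcl_label=str(lbl), values=values[members].mean(axis=0),
            n_samples=int(n)))
    return patterns


def generate_from_pattern(model: VAEModel, pattern: PCLSignaturePattern,
                          signature: SignatureNodeSet, n: int,
                          seed=None, gene_ids=None) -> ExpressionDataset:
    """Decode latent vectors whose signature positions carry the class
    pattern and whose remaining positions are N(0, 1) draws."""
    if n <= 0:
        raise ValueError("n must be positive")
    if len(pattern.values) != len(signature.indices):
        raise ValueError("pattern length does not match signature node count")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.cfg.latent_dim))
    z[:, signature.indices] = pattern.values[None, :]
    X = model.decode(z)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(model.cfg.input_dim)]
    meta = pd.DataFrame({
        "sample_id": [f"GEN_{pattern.pcl_label}_{i:05d}" for i in range(n)],
        "perturbagen_id": None,
        "pert_type": "generated",
        "cell_line": None,
        "pcl_label": pattern.pcl_label,
        "target_gene": None,
    })
    return ExpressionDataset(matrix=X, gene_ids=list(gene_ids), sample_meta=meta,
                             provenance={"source": "pattern-generated",
                                         "pcl": pattern.pcl_label, "seed": seed})


def nearest_real_neighbor(generated: ExpressionDataset,
                          real: ExpressionDataset) -> tuple[pd.DataFrame, dict]:
    """Exhaustive Euclidean nearest real neighbor for each generated sample.

    Returns (per-sample table with neighbor_id / neighbor_label / distance,
    composition dict mapping neighbor label to its fraction)."""
    if generated.gene_ids != real.gene_ids:
        raise SchemaError("generated and real datasets use different gene spaces")
    d = cdist(generated.matrix, real.matrix, metric="euclidean")
    nn = d.argmin(axis=1)
    labels = real.sample_meta["pcl_label"].to_numpy()
    table = pd.DataFrame({
        "sample_id": generated.sample_ids,
        "neighbor_id": [real.sample_ids[j] for j in nn],
        "neighbor_label": [labels[j] for j in nn],
        "distance": d[np.arange(len(nn)), nn],
    })
    comp = table["neighbor_label"].value_counts(normalize=True, dropna=False)
    composition = {k: float(v) for k, v in comp.items()}
    return table, composition


def export_codes(codes: LatentCodes, path, sep: str = "\t") -> None:
    df = pd.DataFrame(codes.values, index=codes.sample_ids)
    df.index.name = "sample_id"
    df.insert(0, "layer_tag", codes.layer_tag)
    df.to_csv(path, sep=sep)
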