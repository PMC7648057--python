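"""L1000-like synthetic data with known ground truth.

The generator plants the structure the downstream models are meant to
recover: each perturbagen class has a latent centroid in a low-dimensional
space, samples scatter around it, and a fixed random linear decoder maps
latents to gene space before a smooth tanh squash into the z-score range.
Optionally, a fraction of drug classes is given a "knockdown twin" class
whose centroid matches the drug's up to a small perturbation, so drug and
knockdown profiles correlate — a stand-in for real drug-target pairs.

Because the squash is an affine map of tanh, emitted values approach but
never reach the clip bounds; no point mass forms at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import DrugTargetTable, ExpressionDataset


@dataclass
class SyntheticConfig:
    """Ground-truth generative settings.

    ``noise_sd`` drives every stochastic deviation: the latent scatter of
    samples around their class centroid, a small gene-space observation
    noise, and the centroid offset of knockdown twins (half ``noise_sd``) —
    so ``noise_sd = 0`` makes within-class profiles identical and twins
    perfectly correlated. ``class_sep`` scales centroid norms relative to
    noise; 3.0 gives well-separated classes at the default noise.
    """

    n_genes: int = 100
    n_latent_true: int = 10
    n_classes: int = 8
    samples_per_class: int = 250
    noise_sd: float = 0.3
    clip_range: tuple = (-10.0, 10.0)
    seed: int = 0
    target_link_fraction: float = 0.5
    n_distractor_classes: int = 20
    class_sep: float = 3.0
    squash_scale: float = 2.0
    class_priors: str = "uniform"  # or "skewed"

    def __post_init__(self) -> None:
        if self.n_latent_true > self.n_genes:
            raise ValueError("n_latent_true must not exceed n_genes")
        if self.samples_per_class < 2:
            raise ValueError("samples_per_class must be at least 2")
        lo, hi = self.clip_range
        if not lo < hi:
            raise ValueError("clip_range bounds must be ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.target_link_fraction <= 1.0:
            raise ValueError("target_link_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted: the decoder, centroids and twin map."""

    W: np.ndarray                      # n_genes x n_latent_true
    centroids: dict                    # class label -> latent centroid
    class_of_sample: list              # per-sample class label
    twin_pairs: list                   # (drug_class, kd_class, target_gene)
    config: SyntheticConfig

    def save(self, path) -> None:
        payload = {
            "W": self.W.tolist(),
            "centroids": {k: np.asarray(v).tolist() for k, v in self.centroids.items()},
            "class_of_sample": list(self.class_of_sample),
            "twin_pairs": [list(t) for t in self.twin_pairs],
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["clip_range"] = tuple(cfg["clip_range"])
        return cls(
            W=np.asarray(payload["W"]),
            centroids={k: np.asarray(v) for k, v in payload["centroids"].items()},
            class_of_sample=payload["class_of_sample"],
            twin_pairs=[tuple(t) for t in payload["twin_pairs"]],
            config=SyntheticConfig(**cfg),
        )


def _squash(pre: np.ndarray, clip_range) -> np.ndarray:
    lo, hi = clip_range
    center = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    return center + half * np.tanh(pre)


def _class_sizes(cfg: SyntheticConfig, n_classes: int, rng) -> np.ndarray:
    if cfg.class_priors == "uniform":
        return np.full(n_classes, cfg.samples_per_class, dtype=int)
    if cfg.class_priors == "skewed":
        # geometric-decay multinomial mimicking unevenly populated classes
        w = 0.7 ** np.arange(n_classes)
        w = w / w.sum()
        total = cfg.samples_per_class * n_classes
        sizes = np.maximum(2, np.round(w * total).astype(int))
        return sizes
    raise ValueError(f"unknown class_priors {cfg.class_priors!r}")


def _decode_latents(latents: np.ndarray, W: np.ndarray, cfg: SyntheticConfig,
                    rng) -> np.ndarray:
    pre = latents @ W.T
    if cfg.noise_sd > 0:
        pre = pre + rng.normal(0.0, cfg.noise_sd, size=pre.shape)
    return _squash(pre / cfg.squash_scale, cfg.clip_range)


def _simulate_classes(cfg: SyntheticConfig, labels, centroids, pert_type,
                      target_gene_of, rng, id_prefix):
    sizes = _class_sizes(cfg, len(labels), rng)
    rows, meta = [], []
    class_of_sample = []
    counter = 0
    for label, size in zip(labels, sizes):
        m = centroids[label]
        eps = rng.normal(0.0, cfg.noise_sd, size=(size, cfg.n_latent_true)) \
            if cfg.noise_sd > 0 else np.zeros((size, cfg.n_latent_true))
        rows.append(m[None, :] + eps)
        for _ in range(size):
            meta.append({
                "sample_id": f"{id_prefix}{counter:06d}",
                "perturbagen_id": (f"drug_{label}" if pert_type == "small_molecule"
                                   else f"kd_{target_gene_of.get(label, label)}"),
                "pert_type": pert_type,
                "cell_line": "CL1",
                "pcl_label": label if pert_type == "small_molecule" else None,
                "target_gene": target_gene_of.get(label),
            })
            class_of_sample.append(label)
            counter += 1
    latents = np.vstack(rows)
    return latents, pd.DataFrame(meta), class_of_sample


def _gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def simulate_dataset(cfg: SyntheticConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Drug classes plus (when ``target_link_fraction`` > 0) their knockdown
    twin classes in a single dataset. Deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    W = rng.normal(0.0, 1.0 / np.sqrt(cfg.n_latent_true),
                   size=(cfg.n_genes, cfg.n_latent_true))
    drug_labels = [f"PCL{c:02d}" for c in range(cfg.n_classes)]
    centroids = {lbl: cfg.class_sep * rng.normal(size=cfg.n_latent_true)
                 for lbl in drug_labels}

    n_linked = int(round(cfg.target_link_fraction * cfg.n_classes))
    twin_pairs = []
    target_gene_of = {}
    kd_labels = []
    for c in range(n_linked):
        drug = drug_labels[c]
        kd = f"KD{c:02d}"
        gene = f"TGT{c:02d}"
        offset = 0.5 * cfg.noise_sd * rng.normal(size=cfg.n_latent_true)
        centroids[kd] = centroids[drug] + offset
        twin_pairs.append((drug, kd, gene))
        target_gene_of[kd] = gene
        kd_labels.append(kd)

    lat_d, meta_d, cls_d = _simulate_classes(
        cfg, drug_labels, centroids, "small_molecule", {}, rng, "SM")
    parts_lat, parts_meta, cls_all = [lat_d], [meta_d], list(cls_d)
    if kd_labels:
        lat_k, meta_k, cls_k = _simulate_classes(
            cfg, kd_labels, centroids, "knockdown", target_gene_of, rng, "GP")
        parts_lat.append(lat_k)
        parts_meta.append(meta_k)
        cls_all += cls_k
    latents = np.vstack(parts_lat)
    meta = pd.concat(parts_meta, ignore_index=True)
    matrix = _decode_latents(latents, W, cfg, rng)
    data = ExpressionDataset(matrix=matrix, gene_ids=_gene_ids(cfg.n_genes),
                             sample_meta=meta,
                             provenance={"source": "synthetic", "seed": cfg.seed})
    truth = GroundTruth(W=W, centroids=centroids, class_of_sample=cls_all,
                        twin_pairs=twin_pairs, config=cfg)
    return data, truth


def simulate_drug_target_benchmark(cfg: SyntheticConfig):
    """Paired (drug dataset, knockdown dataset, truth table) for retrieval.

    Every linked drug class has a knockdown twin whose centroid is the
    drug's plus small noise; ``n_distractor_classes`` extra knockdown
    classes with independent centroids act as decoy genes.
    """
    if cfg.target_link_fraction <= 0:
        raise ValueError("benchmark needs target_link_fraction > 0")
    rng = np.random.default_rng(cfg.seed)
    W = rng.normal(0.0, 1.0 / np.sqrt(cfg.n_latent_true),
                   size=(cfg.n_genes, cfg.n_latent_true))
    drug_labels = [f"PCL{c:02d}" for c in range(cfg.n_classes)]
    centroids = {lbl: cfg.class_sep * rng.normal(size=cfg.n_latent_true)
                 for lbl in drug_labels}

    n_linked = max(1, int(round(cfg.target_link_fraction * cfg.n_classes)))
    twin_pairs, target_gene_of, kd_labels = [], {}, []
    for c in range(n_linked):
        drug, kd, gene = drug_labels[c], f"KD{c:02d}", f"TGT{c:02d}"
        centroids[kd] = centroids[drug] + 0.5 * cfg.noise_sd * rng.normal(
            size=cfg.n_latent_true)
        twin_pairs.append((drug, kd, gene))
        target_gene_of[kd] = gene
        kd_labels.append(kd)
    for d in range(cfg.n_distractor_classes):
        kd, gene = f"KDX{d:02d}", f"DEC{d:02d}"
        centroids[kd] = cfg.class_sep * rng.normal(size=cfg.n_latent_true)
        target_gene_of[kd] = gene
        kd_labels.append(kd)

    lat_d, meta_d, cls_d = _simulate_classes(
        cfg, drug_labels, centroids, "small_molecule", {}, rng, "SM")
    lat_k, meta_k, cls_k = _simulate_classes(
        cfg, kd_labels, centroids, "knockdown", target_gene_of, rng, "GP")
    gene_ids = _gene_ids(cfg.n_genes)
    smp = ExpressionDataset(matrix=_decode_latents(lat_d, W, cfg, rng),
                            gene_ids=gene_ids, sample_meta=meta_d,
                            provenance={"source": "synthetic-smp", "seed": cfg.seed})
    gp = ExpressionDataset(matrix=_decode_latents(lat_k, W, cfg, rng),
                           gene_ids=gene_ids, sample_meta=meta_k,
                           provenance={"source": "synthetic-gp", "seed": cfg.seed})
    truth = DrugTargetTable(pd.DataFrame(
        [(f"drug_{drug}", gene) for drug, _, gene in twin_pairs],
        columns=["drug_id", "gene"],
    ))
    return smp, gp, truth
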