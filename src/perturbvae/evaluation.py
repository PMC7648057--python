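"""Evaluation machinery for the generative models.

* mixing score: for a k-clustering of binary-categorical items,
  MS_k = sum_i max(p_i, q_i) / N — the average proportion of the dominant
  category per cluster; 0.5 means fully mixed, 1 fully separated.
* real-vs-generated protocol: hierarchical clustering (1 - Pearson
  distance, average linkage) of pooled real and model-generated samples,
  cut at k clusters, scored by the mixing score over repeated draws.
* PCL graph: each class's nearest partner by Pearson correlation of its
  global representation becomes a directed edge (source = nearest
  neighbor, target = the class); Louvain communities and modularity on the
  weighted graph.
* classification harness: 10-fold cross-validated logistic-regression and
  linear max-margin classifiers predicting the PCL from each
  representation type.
* drug-target retrieval: rank knockdown genes by Pearson correlation with
  each drug-treated sample's representation and locate known targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, cohen_kappa_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .data_model import DrugTargetTable, ExpressionDataset
from .representations import LatentCodes
from .vae import VAEModel, generate_samples


class CorrelationUndefinedError(ValueError):
    """A constant vector makes Pearson correlation undefined."""


# ---------------------------------------------------------------------------
# mixing score
# ---------------------------------------------------------------------------

@dataclass
class MixingScoreResult:
    score: float
    k: int
    N: int
    per_cluster: list  # (p_i, q_i) pairs


def mixing_score(labels, clusters) -> MixingScoreResult:
    """MS_k = sum over clusters of the dominant category count, over N.

    ``labels`` must contain exactly two categories; ``clusters`` assigns
    each item to a cluster."""
    labels = np.asarray(labels)
    clusters = np.asarray(clusters)
    if labels.shape != clusters.shape:
        raise ValueError("labels and clusters must have the same length")
    cats = np.unique(labels)
    if len(cats) != 2:
        raise ValueError(f"mixing score needs exactly 2 categories, got {len(cats)}")
    N = len(labels)
    per_cluster = []
    dominant = 0
    for c in np.unique(clusters):
        members = clusters == c
        p = int(np.sum(labels[members] == cats[0]))
        q = int(np.sum(members) - p)
        per_cluster.append((p, q))
        dominant += max(p, q)
    return MixingScoreResult(score=dominant / N, k=len(per_cluster), N=N,
                             per_cluster=per_cluster)


# ---------------------------------------------------------------------------
# real vs generated clustering protocol
# ---------------------------------------------------------------------------

def _check_nonconstant(X: np.ndarray, what: str) -> None:
    if np.any(np.ptp(X, axis=1) == 0):
        raise CorrelationUndefinedError(
            f"{what} contains a constant profile; 1 - Pearson distance undefined")


def hierarchical_mixing_score(real: np.ndarray, generated: np.ndarray,
                              k: int, linkage_method: str = "average") -> MixingScoreResult:
    """Cluster the pooled samples with 1 - Pearson correlation distance,
    cut at k clusters, and score the real/generated mixing."""
    _check_nonconstant(real, "real data")
    _check_nonconstant(generated, "generated data")
    X = np.vstack([real, generated])
    labels = np.array(["real"] * len(real) + ["generated"] * len(generated))
    Z = linkage(X, method=linkage_method, metric="correlation")
    clusters = fcluster(Z, t=k, criterion="maxclust")
    return mixing_score(labels, clusters)


def real_vs_generated_protocol(model: VAEModel, data: ExpressionDataset,
                               n_each: int = 2000, k: int = 10,
                               repeats: int = 50, seed=None,
                               linkage_method: str = "average") -> dict:
    """Repeatedly generate ``n_each`` samples, draw ``n_each`` real ones,
    and compute the hierarchical-clustering mixing score.

    Returns per-repeat scores with their mean and a 2.5/97.5-percentile
    interval. A score near 0.5 means clustering cannot tell generated
    profiles from real ones."""
    if data.n_samples < n_each:
        raise ValueError(f"need at least n_each={n_each} real samples")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(repeats):
        gen = generate_samples(model, n_each, seed=int(rng.integers(2 ** 31)))
        idx = rng.choice(data.n_samples, size=n_each, replace=False)
        ms = hierarchical_mixing_score(data.matrix[idx], gen.matrix, k,
                                       linkage_method)
        scores.append(ms.score)
    scores = np.array(scores)
    return {
        "scores": scores,
        "mean": float(scores.mean()),
        "ci_low": float(np.percentile(scores, 2.5)),
        "ci_high": float(np.percentile(scores, 97.5)),
        "k": k,
        "n_each": n_each,
        "repeats": repeats,
        "linkage": linkage_method,
    }


# ---------------------------------------------------------------------------
# PCL embedding graph
# ---------------------------------------------------------------------------

@dataclass
class PCLGraph:
    graph: nx.DiGraph                 # edge source -> target: source is
                                      # target's nearest neighbor
    communities: dict                 # node -> community id
    modularity: float


def pcl_graph(matrix, labels=None, seed: int = 0,
              randomized_restarts: int = 0) -> PCLGraph:
    """Nearest-partner graph over class representations.

    ``matrix`` is classes x dimension (a codebook or a PCL pattern
    matrix); rows may also be given as a DataFrame whose index provides
    the labels. For each class the maximally Pearson-correlated other
    class is found and an edge (partner -> class) with the correlation as
    weight is added. Louvain communities (resolution 1, weighted) and the
    modularity of that partition are attached; set
    ``randomized_restarts`` > 0 to keep the best-modularity partition over
    that many differently-seeded runs."""
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 classes for a meaningful graph")
    if labels is None:
        labels = [f"class_{i}" for i in range(n)]
    const = np.flatnonzero(np.ptp(matrix, axis=1) == 0)
    if const.size:
        raise CorrelationUndefinedError(
            f"constant representation for class {labels[const[0]]!r}")
    corr = np.corrcoef(matrix)
    np.fill_diagonal(corr, -np.inf)
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    for target in range(n):
        source = int(np.argmax(corr[target]))
        g.add_edge(labels[source], labels[target],
                   weight=float(corr[target, source]))
    if randomized_restarts > 0:
        best, best_q = None, -np.inf
        for r in range(randomized_restarts):
            parts = nx.community.louvain_communities(
                g, weight="weight", resolution=1.0, seed=seed + r)
            q = nx.community.modularity(g, parts, weight="weight")
            if q > best_q:
                best, best_q = parts, q
        parts, q = best, best_q
    else:
        parts = nx.community.louvain_communities(
            g, weight="weight", resolution=1.0, seed=seed)
        q = nx.community.modularity(g, parts, weight="weight")
    communities = {}
    for cid, members in enumerate(parts):
        for m in members:
            communities[m] = cid
    nx.set_node_attributes(g, communities, "community")
    return PCLGraph(graph=g, communities=communities, modularity=float(q))


def export_graph(result: PCLGraph, graphml_path=None, edgelist_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(result.graph, graphml_path)
    if edgelist_path is not None:
        rows = [
            (u, v, d["weight"], result.communities[u], result.communities[v])
            for u, v, d in result.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight",
                                    "source_community", "target_community"]
                     ).to_csv(edgelist_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PCL classification harness
# ---------------------------------------------------------------------------

def _merge_minor_classes(y: np.ndarray, folds: int):
    y = np.asarray(y, dtype=object).copy()
    counts = pd.Series(y).value_counts()
    minor = set(counts[counts < folds].index)
    if minor:
        warnings.warn(
            f"{len(minor)} classes have fewer than {folds} samples; "
            "merged into '_minor_pool' for cross-validation")
        y[np.isin(y, list(minor))] = "_minor_pool"
    return y


def pcl_classification_harness(codes_by_type: dict, labels, folds: int = 10,
                               seed: int = 0) -> pd.DataFrame:
    """Cross-validated PCL prediction from each representation type.

    ``codes_by_type`` maps a layer tag to a LatentCodes or matrix. Both a
    logistic-regression (lbfgs) and a linear max-margin classifier are
    fitted per fold; mean accuracy and Cohen's kappa are reported per
    (representation, classifier), along with the frequency-weighted
    random-guess baseline sum_c (n_c / N)^2."""
    y = np.asarray(list(labels), dtype=object)
    if len(np.unique(y)) < 2:
        raise ValueError("classification needs at least 2 classes")
    y = _merge_minor_classes(y, folds)
    freq = pd.Series(y).value_counts(normalize=True)
    baseline = float((freq ** 2).sum())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for tag, codes in codes_by_type.items():
        X = codes.values if isinstance(codes, LatentCodes) else np.asarray(codes)
        for clf_name in ("logistic_regression", "linear_svm"):
            accs, kappas = [], []
            for train, test in skf.split(X, y):
                if clf_name == "logistic_regression":
                    clf = LogisticRegression(solver="lbfgs", max_iter=500,
                                             random_state=seed)
                else:
                    clf = LinearSVC(random_state=seed)
                clf.fit(X[train], y[train])
                pred = clf.predict(X[test])
                accs.append(accuracy_score(y[test], pred))
                if len(np.unique(pred)) == 1 and len(np.unique(y[test])) > 1:
                    kappas.append(0.0)  # constant predictions carry no agreement
                else:
                    kappas.append(cohen_kappa_score(y[test], pred))
            rows.append({
                "representation": tag,
                "classifier": clf_name,
                "accuracy": float(np.mean(accs)),
                "kappa": float(np.mean(kappas)),
                "baseline": baseline,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# drug-target retrieval
# ---------------------------------------------------------------------------

@dataclass
class RetrievalResult:
    """Per-drug retrieval summary. ``per_sample_target_ranks`` holds, for
    each drug-treated sample, the rank of every known target gene (rank 1
    is best); ``top_rank`` is the best and ``mean_rank`` the mean over
    samples of each sample's best known-target rank."""

    drug_id: str
    target_genes: list
    n_samples: int
    n_genes_ranked: int
    per_sample_target_ranks: list          # list of dicts gene -> rank
    top_rank: int
    mean_rank: float


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise CorrelationUndefinedError("constant representation vector")
    return (A @ B.T) / np.outer(na, nb)


def rank_targets(drug_codes: LatentCodes, drug_ids, gp_codes: LatentCodes,
                 gp_genes, truth: DrugTargetTable) -> list[RetrievalResult]:
    """Correlation-rank retrieval of knockdown genes for each drug.

    For every sample treated with a drug, Pearson correlations against all
    knockdown-sample representations are computed; a gene's score is its
    best-correlated knockdown sample, genes are ranked by decreasing score
    (ties broken by gene symbol), and the best-ranked known target's rank
    is recorded for the sample. Drugs absent from the truth table are
    skipped with a warning."""
    if drug_codes.layer_tag != gp_codes.layer_tag:
        raise ValueError("representations must come from the same layer")
    drug_ids = np.asarray(list(drug_ids), dtype=object)
    gp_genes = np.asarray(list(gp_genes), dtype=object)
    genes = np.unique(gp_genes)
    corr = _rowwise_pearson(drug_codes.values, gp_codes.values)
    # gene score per drug sample = max correlation over that gene's samples
    gene_cols = {g: np.flatnonzero(gp_genes == g) for g in genes}
    gene_scores = np.column_stack([corr[:, cols].max(axis=1)
                                   for g, cols in gene_cols.items()])
    results = []
    for drug in pd.unique(drug_ids):
        targets = truth.targets_of(drug)
        if not targets:
            warnings.warn(f"drug {drug!r} absent from truth table; skipped")
            continue
        rows = np.flatnonzero(drug_ids == drug)
        per_sample = []
        best_ranks = []
        for r in rows:
            scores = gene_scores[r]
            # rank genes by decreasing score, ties by gene symbol
            order = np.lexsort((genes, -scores))
            rank_of = {genes[j]: pos + 1 for pos, j in enumerate(order)}
            target_ranks = {g: rank_of[g] for g in targets if g in rank_of}
            if not target_ranks:
                continue
            per_sample.append(target_ranks)
            best_ranks.append(min(target_ranks.values()))
        if not per_sample:
            warnings.warn(f"no target of drug {drug!r} present among "
                          "knockdown genes; skipped")
            continue
        results.append(RetrievalResult(
            drug_id=str(drug),
            target_genes=list(targets),
            n_samples=len(per_sample),
            n_genes_ranked=len(genes),
            per_sample_target_ranks=per_sample,
            top_rank=int(min(best_ranks)),
            mean_rank=float(np.mean(best_ranks)),
        ))
    return results


def retrieval_aggregates(results: list[RetrievalResult], n_values) -> pd.DataFrame:
    """recall@n (mean fraction of a sample's true targets in the top n) and
    hit@n (fraction of samples with at least one true target in the top n),
    pooled over all drug-treated samples."""
    if not results:
        raise ValueError("no retrieval results to aggregate")
    n_genes = max(r.n_genes_ranked for r in results)
    rows = []
    for n in n_values:
        if n > n_genes:
            warnings.warn(f"n={n} exceeds the {n_genes} ranked genes; clipped")
            n = n_genes
        recalls, hits = [], []
        for r in results:
            for target_ranks in r.per_sample_target_ranks:
                in_top = sum(1 for rank in target_ranks.values() if rank <= n)
                recalls.append(in_top / len(target_ranks))
                hits.append(1.0 if in_top >= 1 else 0.0)
        rows.append({"n": int(n), "recall": float(np.mean(recalls)),
                     "hit": float(np.mean(hits)),
                     "n_samples": len(recalls)})
    return pd.DataFrame(rows)


def retrieval_table(results: list[RetrievalResult],
                    representation: str = "") -> pd.DataFrame:
    """Per-drug summary table (drug, representation, top rank, mean rank)."""
    return pd.DataFrame([
        {"drug": r.drug_id, "representation": representation,
         "top_rank": r.top_rank, "mean_rank": r.mean_rank,
         "n_samples": r.n_samples}
        for r in results
    ])
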