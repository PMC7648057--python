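"""Mixing score, clustering protocol, PCL graph, classification harness
and drug-target retrieval."""

import collections
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perturbvae import (
    hierarchical_mixing_score,
    mixing_score,
    pcl_classification_harness,
    pcl_graph,
    rank_targets,
    real_vs_generated_protocol,
    retrieval_aggregates,
)
from perturbvae.evaluation import CorrelationUndefinedError, RetrievalResult
from perturbvae.representations import LatentCodes


def brute_force_mixing(labels, clusters):
    """Independent oracle: per-cluster majority counting."""
    cats = sorted(set(labels))
    total = 0
    for c in set(clusters):
        counts = collections.Counter(l for l, cl in zip(labels, clusters)
                                     if cl == c)
        total += max(counts.get(cats[0], 0), counts.get(cats[1], 0))
    return total / len(labels)


class TestMixingScore:
    def test_perfect_separation_gives_one(self):
        r = mixing_score(["a"] * 4 + ["b"] * 4, [0, 0, 0, 0, 1, 1, 1, 1])
        assert r.score == 1.0

    def test_even_mixture_gives_half(self):
        r = mixing_score(["a", "b"] * 4, [0, 0, 0, 0, 1, 1, 1, 1])
        assert r.score == 0.5

    def test_hand_computed_case(self):
        # clusters {3A,1B} and {1A,3B}: (3+3)/8 = 0.75
        labels = ["A", "A", "A", "B", "A", "B", "B", "B"]
        clusters = [1, 1, 1, 1, 2, 2, 2, 2]
        assert mixing_score(labels, clusters).score == 0.75

    def test_more_than_two_categories_rejected(self):
        with pytest.raises(ValueError):
            mixing_score(["a", "b", "c"], [0, 0, 1])

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(2, 200), st.integers(1, 8), st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(["real", "gen"], size=n)
        if len(set(labels)) < 2:
            labels[0], labels[1] = "real", "gen"
        clusters = rng.integers(0, k, size=n)
        r = mixing_score(labels, clusters)
        assert r.score == pytest.approx(brute_force_mixing(labels, clusters))
        assert 0.5 - 1e-12 <= r.score <= 1.0
        assert sum(p + q for p, q in r.per_cluster) == n


class TestRealVsGenerated:
    def test_identical_sets_score_half(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 10))
        r = hierarchical_mixing_score(X, X.copy(), k=5)
        assert r.score == pytest.approx(0.5)

    def test_disjoint_clouds_score_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=10)
        real = base + rng.normal(0, 0.01, size=(30, 10))
        fake = -base + rng.normal(0, 0.01, size=(30, 10))
        r = hierarchical_mixing_score(real, fake, k=4)
        assert r.score == 1.0

    def test_constant_profile_rejected(self):
        with pytest.raises(CorrelationUndefinedError):
            hierarchical_mixing_score(np.ones((5, 4)),
                                      np.random.default_rng(0).normal(size=(5, 4)),
                                      k=2)

    def test_trained_model_scores_below_seven_tenths(self, trained_vae, synth):
        data, _ = synth
        model, _ = trained_vae
        res = real_vs_generated_protocol(model, data, n_each=500, k=10,
                                         repeats=10, seed=7)
        assert res["mean"] < 0.7
        assert res["ci_low"] <= res["mean"] <= res["ci_high"]

    def test_affine_rescaling_of_profiles_leaves_clusters_unchanged(self):
        # 1 - Pearson distance ignores per-sample location/scale
        rng = np.random.default_rng(3)
        real = rng.normal(size=(25, 12))
        fake = rng.normal(size=(25, 12))
        r1 = hierarchical_mixing_score(real, fake, k=6)
        r2 = hierarchical_mixing_score(real * 3.0 + 2.0, fake, k=6)
        assert r1.score == pytest.approx(r2.score)


class TestPCLGraph:
    def test_nearest_partner_matches_brute_force(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(5, 8))
        labels = [f"c{i}" for i in range(5)]
        res = pcl_graph(M, labels, seed=0)
        # oracle: full correlation table, row argmax off-diagonal
        for t in range(5):
            cors = [np.corrcoef(M[t], M[s])[0, 1] if s != t else -np.inf
                    for s in range(5)]
            expected_source = labels[int(np.argmax(cors))]
            preds = [u for u, v in res.graph.in_edges(labels[t])]
            assert preds == [expected_source]

    def test_duplicated_rows_form_bidirectional_pair(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(4, 6))
        M[3] = M[0]
        res = pcl_graph(M, ["a", "b", "c", "a2"], seed=0)
        assert res.graph.has_edge("a", "a2") and res.graph.has_edge("a2", "a")
        assert res.graph.edges["a", "a2"]["weight"] == pytest.approx(1.0)

    def test_each_node_has_one_incoming_nearest_edge_no_self_loops(self):
        rng = np.random.default_rng(2)
        res = pcl_graph(rng.normal(size=(7, 5)), seed=0)
        for node in res.graph.nodes:
            assert res.graph.in_degree(node) == 1
            assert not res.graph.has_edge(node, node)

    def test_modularity_matches_formula_for_single_community(self):
        import networkx as nx
        rng = np.random.default_rng(3)
        res = pcl_graph(rng.normal(size=(5, 6)), seed=0)
        part = [set(res.graph.nodes)]
        assert nx.community.modularity(res.graph, part, weight="weight") == \
            pytest.approx(0.0, abs=1e-12)

    def test_constant_row_names_offending_class(self):
        M = np.random.default_rng(0).normal(size=(4, 5))
        M[2] = 1.0
        with pytest.raises(CorrelationUndefinedError, match="c2"):
            pcl_graph(M, ["c0", "c1", "c2", "c3"], seed=0)


class TestClassificationHarness:
    def test_separable_representation_reaches_high_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(loc=i * 10, size=(30, 5)) for i in range(3)])
        y = np.repeat(list("abc"), 30)
        table = pcl_classification_harness({"toy": X}, y, folds=5, seed=0)
        assert (table["accuracy"] > 0.95).all()
        assert np.allclose(table["baseline"], 1 / 3)

    def test_label_shuffled_control_sits_near_baseline(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(loc=i * 10, size=(40, 4)) for i in range(2)])
        y = rng.permutation(np.repeat(["a", "b"], 40))
        table = pcl_classification_harness({"toy": X}, y, folds=5, seed=0)
        # permutation control: accuracy within a few fold-sds of 0.5 baseline
        assert (table["accuracy"] < 0.75).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pcl_classification_harness({"x": np.zeros((10, 2))}, ["a"] * 10)

    def test_minor_classes_merged_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(43, 3))
        y = ["a"] * 20 + ["b"] * 20 + ["rare"] * 3
        with pytest.warns(UserWarning, match="merged"):
            pcl_classification_harness({"x": X}, y, folds=5, seed=0)


def _codes(values, tag="top"):
    values = np.asarray(values, float)
    return LatentCodes(values, tag, [f"s{i}" for i in range(len(values))])


class TestRankTargets:
    def _truth(self, pairs):
        from perturbvae.data_model import DrugTargetTable
        return DrugTargetTable(pd.DataFrame(pairs, columns=["drug_id", "gene"]))

    def test_identical_profile_ranks_first(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=8)
        gp_vals = np.vstack([profile, rng.normal(size=(3, 8))])
        res = rank_targets(_codes([profile]), ["d1"], _codes(gp_vals),
                           ["GT", "A", "B", "C"], self._truth([["d1", "GT"]]))
        assert res[0].top_rank == 1 and res[0].mean_rank == 1.0

    def test_anticorrelated_decoy_ranks_last(self):
        rng = np.random.default_rng(1)
        profile = rng.normal(size=8)
        gp_vals = np.vstack([profile + rng.normal(0, 0.1, 8),
                             rng.normal(size=8), -profile])
        res = rank_targets(_codes([profile]), ["d1"], _codes(gp_vals),
                           ["GT", "N", "DECOY"], self._truth([["d1", "GT"]]))
        ranks = res[0].per_sample_target_ranks[0]
        assert ranks["GT"] == 1
        # the decoy gene occupies the last rank
        assert res[0].n_genes_ranked == 3

    def test_unknown_drug_skipped_with_notice(self):
        with pytest.warns(UserWarning, match="absent"):
            res = rank_targets(_codes(np.random.default_rng(0).normal(size=(1, 5))),
                               ["mystery"], _codes(np.random.default_rng(1).normal(size=(2, 5))),
                               ["A", "B"], self._truth([["d1", "A"]]))
        assert res == []

    def test_invariance_to_gene_order_and_affine_transform(self, retrieval_benchmark):
        smp, gp, truth = retrieval_benchmark
        dc = _codes(smp.matrix, "raw")
        gids = list(smp.sample_meta["perturbagen_id"])
        genes = list(gp.sample_meta["target_gene"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = rank_targets(dc, gids, _codes(gp.matrix, "raw"), genes, truth)
            perm = np.random.default_rng(0).permutation(len(genes))
            shuffled = rank_targets(dc, gids,
                                    _codes(gp.matrix[perm], "raw"),
                                    [genes[i] for i in perm], truth)
            scaled = rank_targets(_codes(smp.matrix * 2.5 + 1.0, "raw"), gids,
                                  _codes(gp.matrix, "raw"), genes, truth)
        for a, b, c in zip(base, shuffled, scaled):
            assert a.top_rank == b.top_rank == c.top_rank
            assert a.mean_rank == pytest.approx(b.mean_rank)
            assert a.mean_rank == pytest.approx(c.mean_rank)

    def test_planted_twin_benchmark_median_rank(self, retrieval_benchmark):
        smp, gp, truth = retrieval_benchmark
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = rank_targets(_codes(smp.matrix, "raw"),
                               smp.sample_meta["perturbagen_id"],
                               _codes(gp.matrix, "raw"),
                               gp.sample_meta["target_gene"], truth)
        med = np.median([r.top_rank for r in res])
        assert med <= 3


class TestAggregates:
    def _single(self, target_ranks, n_genes=30):
        return RetrievalResult(
            drug_id="d", target_genes=list(target_ranks),
            n_samples=1, n_genes_ranked=n_genes,
            per_sample_target_ranks=[target_ranks],
            top_rank=min(target_ranks.values()),
            mean_rank=float(min(target_ranks.values())))

    def test_always_rank_one(self):
        table = retrieval_aggregates([self._single({"G": 1})], [1])
        assert table.loc[0, "recall"] == 1.0 and table.loc[0, "hit"] == 1.0

    def test_hand_counted_two_targets(self):
        # targets at ranks {1, 5}: recall@3 = 0.5, hit@3 = 1.0
        table = retrieval_aggregates([self._single({"G1": 1, "G2": 5})], [3])
        assert table.loc[0, "recall"] == 0.5
        assert table.loc[0, "hit"] == 1.0

    def test_n_equal_gene_count_gives_full_recall(self):
        table = retrieval_aggregates(
            [self._single({"G1": 7, "G2": 30})], [30])
        assert table.loc[0, "recall"] == 1.0

    def test_oversized_n_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            table = retrieval_aggregates([self._single({"G": 2})], [999])
        assert table.loc[0, "n"] == 30
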