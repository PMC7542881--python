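import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from gsclust import (
    PlantedDesign,
    build_similarity_matrix,
    cluster_gene_sets,
    create_collection,
    dissimilarity,
    generate_planted_collection,
    genes_per_cluster,
    highlight_score,
    lloyd_kmeans,
    optimal_k,
)
from gsclust.model import GeneSetCollection


class TestClusterGeneSets:
    @pytest.mark.parametrize("method", ["kmeans", "hierarchical"])
    def test_planted_three_groups_recovered(self, planted_rr, method):
        m, truth = planted_rr
        res = cluster_gene_sets(m, 3, method, seed=7)
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_labels_canonical_by_size_then_id(self, planted_rr):
        m, _ = planted_rr
        res = cluster_gene_sets(m, 3, "kmeans", seed=3)
        sizes = [res.labels.count(l) for l in range(1, 4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_k_n_minus_one_gives_one_pair(self):
        coll = create_collection(
            [
                dict(name="s0", genes=["A", "B", "C"]),
                dict(name="s1", genes=["A", "B", "D"]),
                dict(name="s2", genes=["E", "F"]),
                dict(name="s3", genes=["G", "H"]),
                dict(name="s4", genes=["I", "J"]),
            ]
        )
        m = build_similarity_matrix(coll, "jaccard")
        res = cluster_gene_sets(m, 4, "hierarchical", seed=0)
        sizes = sorted((res.labels.count(l) for l in range(1, 5)), reverse=True)
        assert sizes == [2, 1, 1, 1]
        assert res.labels[0] == res.labels[1]  # the overlapping pair merges

    @pytest.mark.parametrize("method", ["kmeans", "hierarchical"])
    def test_identical_sets_share_label(self, method):
        coll = create_collection(
            [
                dict(name="t1", genes=["A", "B", "C"], experiment="e1"),
                dict(name="t2", genes=["A", "B", "C"], experiment="e2"),
                dict(name="u", genes=["X", "Y", "Z"]),
                dict(name="v", genes=["P", "Q"]),
            ]
        )
        m = build_similarity_matrix(coll, "jaccard")
        for k in (2, 3):
            res = cluster_gene_sets(m, k, method, seed=1)
            assert res.labels[0] == res.labels[1]

    def test_k_out_of_range_rejected(self, planted_rr):
        m, _ = planted_rr
        for k in (1, m.n, m.n + 3):
            with pytest.raises(ValueError):
                cluster_gene_sets(m, k, "kmeans", seed=0)

    def test_custom_clusterer(self, planted_rr):
        m, _ = planted_rr
        res = cluster_gene_sets(
            m, 2, lambda mat, k, seed: [0] * 12 + [1] * 12, seed=0
        )
        assert res.method.value == "CUSTOM"
        assert res.k == 2

    def test_hierarchical_invariant_to_row_order(self, planted):
        coll, truth = planted
        rng = np.random.default_rng(4)
        perm = list(rng.permutation(len(coll)))
        permuted = GeneSetCollection(tuple(coll.gene_sets[i] for i in perm))
        m1 = build_similarity_matrix(coll, "kappa")
        m2 = build_similarity_matrix(permuted, "kappa")
        r1 = cluster_gene_sets(m1, 3, "hierarchical")
        r2 = cluster_gene_sets(m2, 3, "hierarchical")
        assign1 = dict(zip(r1.set_ids, r1.labels))
        assign2 = dict(zip(r2.set_ids, r2.labels))
        assert assign1 == assign2  # canonical labels make them directly comparable

    def test_lloyd_agrees_with_sklearn_partition(self, planted_rr):
        """Independent cross-check: on well-separated data our Lloyd k-means
        and scikit-learn's find the same partition."""
        m, _ = planted_rr
        ours, _ = lloyd_kmeans(m.scores, 3, seed=5)
        theirs = KMeans(n_clusters=3, n_init=25, random_state=5).fit_predict(m.scores)
        assert adjusted_rand_score(ours, theirs) == 1.0

    def test_parameter_recovery_over_replicates(self):
        """Median ARI >= 0.9 across 20 seeded replicates for both methods."""
        aris = {"kmeans": [], "hierarchical": []}
        for rep in range(20):
            coll, truth = generate_planted_collection(PlantedDesign(seed=200 + rep))
            m = build_similarity_matrix(coll, "rr")
            for method in aris:
                res = cluster_gene_sets(m, 3, method, seed=rep)
                aris[method].append(adjusted_rand_score(truth, res.labels))
        assert np.median(aris["kmeans"]) >= 0.9
        assert np.median(aris["hierarchical"]) >= 0.9


class TestOptimalK:
    def test_silhouette_recommends_planted_k(self, planted_rr):
        m, _ = planted_rr
        curve = optimal_k(m, "silhouette", [2, 3, 4, 5], seed=7)
        assert curve.recommended_k == 3
        i3 = curve.k_values.index(3)
        assert curve.criterion_values[i3] > curve.criterion_values[i3 - 1]
        assert curve.criterion_values[i3] > curve.criterion_values[i3 + 1]

    def test_gap_recommends_planted_k(self, planted_rr):
        m, _ = planted_rr
        curve = optimal_k(m, "gap", [2, 3, 4, 5], seed=7, gap_B=50)
        assert curve.recommended_k == 3
        assert curve.gap_se is not None and len(curve.gap_se) == 4

    def test_elbow_recommends_planted_k(self, planted_rr):
        m, _ = planted_rr
        curve = optimal_k(m, "elbow", [2, 3, 4, 5], seed=7)
        assert curve.recommended_k == 3
        # WSS is non-increasing in k
        assert all(a >= b - 1e-9 for a, b in zip(curve.criterion_values, curve.criterion_values[1:]))

    def test_short_k_range_rejected(self, planted_rr):
        m, _ = planted_rr
        with pytest.raises(ValueError):
            optimal_k(m, "elbow", [2, 3], seed=0)
        with pytest.raises(ValueError):
            optimal_k(m, "gap", [3], seed=0)

    def test_k_range_bounds_checked(self, planted_rr):
        m, _ = planted_rr
        with pytest.raises(ValueError):
            optimal_k(m, "silhouette", [1, 2, 3], seed=0)


class TestHighlight:
    def test_per_set_fraction(self, tiny_collection):
        m = build_similarity_matrix(tiny_collection, "jaccard")
        res = cluster_gene_sets(m, 2, "hierarchical")
        out = highlight_score(tiny_collection, res, ["A", "B"])
        scores = dict(zip(out.set_ids, out.highlight_scores))
        assert scores[tiny_collection[0].set_id] == pytest.approx(2 / 3)
        assert scores[tiny_collection[2].set_id] == 0.0

    def test_superset_saturates(self, tiny_collection):
        m = build_similarity_matrix(tiny_collection, "jaccard")
        res = cluster_gene_sets(m, 2, "hierarchical")
        out = highlight_score(tiny_collection, res, list(tiny_collection.universe))
        assert all(s == 1.0 for s in out.highlight_scores)

    def test_cluster_mean(self):
        coll = create_collection(
            [
                dict(name="a", genes=["H1", "X", "Y", "Z", "W"]),  # score 0.2
                dict(name="b", genes=["H1", "H2", "X", "Y", "Z"]),  # score 0.4
                dict(name="c", genes=["P", "Q"]),
            ]
        )
        m = build_similarity_matrix(coll, "jaccard")
        res = cluster_gene_sets(m, 2, "hierarchical")
        out = highlight_score(coll, res, ["H1", "H2"])
        lab_ab = out.labels[0]
        assert out.labels[1] == lab_ab
        assert out.cluster_summaries[lab_ab].mean_highlight == pytest.approx(0.3)

    def test_disjoint_subset_warns_all_zero(self, tiny_collection, caplog):
        m = build_similarity_matrix(tiny_collection, "jaccard")
        res = cluster_gene_sets(m, 2, "hierarchical")
        out = highlight_score(tiny_collection, res, ["NOPE1", "NOPE2"])
        assert all(s == 0.0 for s in out.highlight_scores)
        assert any("disjoint" in r.message for r in caplog.records)


class TestGenesPerCluster:
    def test_shared_and_unique(self):
        coll = create_collection(
            [
                dict(name="a", genes=["A", "B", "C"]),
                dict(name="b", genes=["B", "C", "D"]),
                dict(name="x", genes=["X", "Y"]),
                dict(name="y", genes=["X", "Z"]),
            ]
        )
        m = build_similarity_matrix(coll, "jaccard")
        res = genes_per_cluster(coll, cluster_gene_sets(m, 2, "hierarchical"))
        lab_ab = res.labels[0]
        summ = res.cluster_summaries[lab_ab]
        assert set(summ.shared_genes) == {"B", "C"}
        assert set(summ.unique_genes) == {"A", "B", "C", "D"}

    def test_singleton_cluster(self):
        coll = create_collection(
            [
                dict(name="a", genes=["A", "B"]),
                dict(name="b", genes=["A", "B"]),
                dict(name="solo", genes=["Q", "R"]),
            ]
        )
        m = build_similarity_matrix(coll, "jaccard")
        res = genes_per_cluster(coll, cluster_gene_sets(m, 2, "hierarchical"))
        solo_lab = res.labels[2]
        assert set(res.cluster_summaries[solo_lab].shared_genes) == {"Q", "R"}

    def test_unique_counts_bounded_by_universe(self, planted_rr, planted):
        coll, _ = planted
        m, _ = planted_rr
        res = genes_per_cluster(coll, cluster_gene_sets(m, 3, "kmeans", seed=2))
        total_unique = sum(len(res.cluster_summaries[l].unique_genes) for l in (1, 2, 3))
        assert total_unique <= len(coll.universe)

    def test_label_permutation_invariance(self, planted, planted_rr):
        """Relabeling clusters never changes shared/unique sets or means."""
        from dataclasses import replace

        coll, _ = planted
        m, _ = planted_rr
        res = cluster_gene_sets(m, 3, "kmeans", seed=2)
        perm = {1: 3, 2: 1, 3: 2}
        permuted = replace(
            res, labels=tuple(perm[l] for l in res.labels), cluster_summaries={}
        )
        a = genes_per_cluster(coll, res)
        b = genes_per_cluster(coll, permuted)
        for lab in (1, 2, 3):
            sa = a.cluster_summaries[lab]
            sb = b.cluster_summaries[perm[lab]]
            assert sa.shared_genes == sb.shared_genes
            assert sa.unique_genes == sb.unique_genes
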