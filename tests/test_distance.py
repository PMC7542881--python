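import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gsclust import (
    Metric,
    OverlapCounts,
    build_similarity_matrix,
    cap_matrix,
    cohens_kappa,
    create_collection,
    jaccard,
    overlap_counts,
    relative_risk,
)

from conftest import random_collection
from oracles import jaccard_oracle, kappa_oracle, rr_oracle


def make_pair(rng, universe_size):
    genes = [f"g{i}" for i in range(universe_size)]
    si = frozenset(rng.choice(genes, size=rng.integers(1, universe_size + 1), replace=False))
    sj = frozenset(rng.choice(genes, size=rng.integers(1, universe_size + 1), replace=False))
    return si, sj, genes


def counts_of(si, sj, genes):
    return OverlapCounts(len(si & sj), len(si), len(sj), len(genes))


class TestScalarMetrics:
    def test_worked_micro_case(self):
        c = OverlapCounts(2, 3, 3, 10)
        assert relative_risk(c) == pytest.approx(20 / 7, rel=1e-12)
        assert jaccard(c) == pytest.approx(0.5, rel=1e-12)
        assert cohens_kappa(c) == pytest.approx(11 / 21, rel=1e-12)

    def test_zero_overlap(self):
        c = OverlapCounts(0, 4, 5, 30)
        assert relative_risk(c) == 0.0
        assert jaccard(c) == 0.0
        assert kappa_oracle(frozenset("abcd"), frozenset("efghi"),
                            list("abcdefghi") + [f"x{i}" for i in range(21)]) == pytest.approx(
            cohens_kappa(c), rel=1e-12
        )

    def test_identical_sets(self):
        c = OverlapCounts(5, 5, 5, 20)
        assert jaccard(c) == 1.0
        assert cohens_kappa(c) == 1.0
        assert relative_risk(c) == 5 * 20 / (25 - 5)

    def test_singleton_identity_gives_infinity_sentinel(self):
        assert relative_risk(OverlapCounts(1, 1, 1, 10)) == math.inf

    def test_full_universe_kappa_convention(self):
        assert cohens_kappa(OverlapCounts(8, 8, 8, 8)) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            OverlapCounts(5, 3, 4, 10)  # c > min(p_i, p_j)
        with pytest.raises(ValueError):
            OverlapCounts(1, 3, 4, 2)  # sets exceed universe

    def test_metrics_match_contingency_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            si, sj, genes = make_pair(rng, int(rng.integers(2, 30)))
            c = counts_of(si, sj, genes)
            assert relative_risk(c) == pytest.approx(rr_oracle(si, sj, genes), rel=1e-9)
            assert jaccard(c) == pytest.approx(jaccard_oracle(si, sj, genes), rel=1e-9)
            assert cohens_kappa(c) == pytest.approx(kappa_oracle(si, sj, genes), rel=1e-9, abs=1e-12)

    @given(
        n=st.integers(2, 40),
        data=st.data(),
    )
    def test_monotone_in_overlap(self, n, data):
        """With p_i, p_j, n fixed, all three metrics are non-decreasing in c."""
        p_i = data.draw(st.integers(1, n))
        p_j = data.draw(st.integers(1, n))
        c_min = max(0, p_i + p_j - n)
        prev = (-math.inf, -math.inf, -math.inf)
        for c in range(c_min, min(p_i, p_j) + 1):
            oc = OverlapCounts(c, p_i, p_j, n)
            cur = (relative_risk(oc), jaccard(oc), cohens_kappa(oc))
            assert all(a >= b - 1e-12 for a, b in zip(cur, prev))
            prev = cur


class TestOverlapCounts:
    def test_direct_count(self, tiny_collection):
        c = overlap_counts(tiny_collection[0], tiny_collection[1], 10)
        assert (c.c_ij, c.p_i, c.p_j, c.n) == (2, 3, 3, 10)

    def test_disjoint_and_identical(self, tiny_collection):
        alpha, _, gamma = tiny_collection.gene_sets
        assert overlap_counts(alpha, gamma, 10).c_ij == 0
        ident = overlap_counts(alpha, alpha, 10)
        assert ident.c_ij == ident.p_i == ident.p_j == 3

    def test_universe_too_small_rejected(self, tiny_collection):
        with pytest.raises(ValueError, match="universe"):
            overlap_counts(tiny_collection[0], tiny_collection[1], 2)


class TestSimilarityMatrix:
    def test_entries_equal_scalar_metric(self):
        rng = np.random.default_rng(5)
        coll = random_collection(rng, n_sets=10, universe=25)
        n = len(coll.universe)
        for metric, fn in [("rr", relative_risk), ("jaccard", jaccard), ("kappa", cohens_kappa)]:
            m = build_similarity_matrix(coll, metric)
            for i in range(len(coll)):
                for j in range(len(coll)):
                    expected = fn(overlap_counts(coll[i], coll[j], n))
                    if math.isinf(expected):
                        continue  # replaced at matrix level
                    assert m.scores[i, j] == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_symmetry_and_ranges(self, planted):
        coll, _ = planted
        for metric in ("rr", "jaccard", "kappa"):
            m = build_similarity_matrix(coll, metric)
            assert np.array_equal(m.scores, m.scores.T)
            if metric == "jaccard":
                assert m.scores.min() >= 0 and m.scores.max() <= 1
            elif metric == "kappa":
                assert m.scores.min() >= -1 and m.scores.max() <= 1
            else:
                assert m.scores.min() >= 0 and np.isfinite(m.scores).all()

    def test_disjoint_sets_zero_offdiagonal(self):
        coll = create_collection(
            [dict(name=f"s{i}", genes=[f"{i}A", f"{i}B"]) for i in range(3)]
        )
        m = build_similarity_matrix(coll, "rr")
        off = m.scores[~np.eye(3, dtype=bool)]
        assert np.all(off == 0.0)

    def test_rr_diagonal_formula(self, tiny_collection):
        m = build_similarity_matrix(tiny_collection, "rr")
        n = len(tiny_collection.universe)
        for i, gs in enumerate(tiny_collection):
            assert m.scores[i, i] == pytest.approx(n / (gs.size - 1), rel=1e-12)

    def test_singleton_infinity_replaced_by_max_finite_offdiagonal(self):
        coll = create_collection(
            [
                dict(name="s1", genes=["A"]),
                dict(name="s2", genes=["A"]),
                dict(name="s3", genes=["A", "B", "C"]),
            ]
        )
        m = build_similarity_matrix(coll, "rr")
        assert m.infinite_replaced > 0
        assert np.isfinite(m.scores).all()
        # the s1-s2 pair was the infinity; it now equals the max finite off-diag
        finite_off = [
            m.scores[i, j]
            for i in range(3)
            for j in range(3)
            if i != j and not (i < 2 and j < 2)
        ]
        assert m.scores[0, 1] == pytest.approx(max(finite_off))

    def test_order_independence(self):
        rng = np.random.default_rng(9)
        coll = random_collection(rng, n_sets=8)
        m = build_similarity_matrix(coll, "kappa")
        perm = list(rng.permutation(len(coll)))
        from gsclust.model import GeneSetCollection

        permuted = GeneSetCollection(tuple(coll.gene_sets[i] for i in perm))
        mp = build_similarity_matrix(permuted, "kappa")
        assert np.allclose(mp.scores, m.scores[np.ix_(perm, perm)], rtol=1e-12)

    def test_custom_metric_callable(self, tiny_collection):
        m = build_similarity_matrix(tiny_collection, lambda c: float(c.c_ij))
        assert m.metric is Metric.CUSTOM
        assert m.scores[0, 1] == 2.0

    def test_custom_metric_nonfinite_rejected(self, tiny_collection):
        with pytest.raises(ValueError, match="non-finite"):
            build_similarity_matrix(tiny_collection, lambda c: math.nan)

    def test_too_few_sets_rejected(self):
        coll = create_collection([dict(name="only", genes=["A"])])
        with pytest.raises(ValueError):
            build_similarity_matrix(coll, "rr")


class TestCapMatrix:
    def test_clamp(self, planted_rr):
        m, _ = planted_rr
        capped = cap_matrix(m, 70.0)
        assert capped.cap_applied == 70.0
        assert capped.scores.max() <= 70.0
        below = m.scores <= 70.0
        assert np.array_equal(capped.scores[below], m.scores[below])

    def test_cap_above_max_is_identity(self, planted_rr):
        m, _ = planted_rr
        capped = cap_matrix(m, float(m.scores.max()) + 1)
        assert np.array_equal(capped.scores, m.scores)

    def test_idempotent(self, planted_rr):
        m, _ = planted_rr
        once = cap_matrix(m, 70.0)
        twice = cap_matrix(once, 70.0)
        assert np.array_equal(once.scores, twice.scores)

    def test_nonpositive_cap_rejected(self, planted_rr):
        m, _ = planted_rr
        with pytest.raises(ValueError):
            cap_matrix(m, 0.0)
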