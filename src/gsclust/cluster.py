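"""Clustering of gene-sets from a similarity matrix.

Gene-sets are clustered either by k-means on the rows of the similarity
matrix (each set described by its similarity profile to every other set) or
by average-linkage hierarchical agglomeration on a bounded dissimilarity
transform of the matrix.  The number of clusters can be chosen by the elbow,
gap-statistic or silhouette criterion.  Cluster labels are canonicalised
(1..k by decreasing cluster size, ties broken by the smallest member set_id)
so results are reproducible across platforms and input orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .distance import SimilarityMatrix, dissimilarity
from .model import GeneSetCollection


class ClusterMethod(str, Enum):
    KMEANS = "KMEANS"
    HIERARCHICAL = "HIERARCHICAL"
    CUSTOM = "CUSTOM"


class KSelection(str, Enum):
    ELBOW = "ELBOW"
    GAP = "GAP"
    SILHOUETTE = "SILHOUETTE"


@dataclass(frozen=True)
class ClusterSummary:
    n_sets: int
    shared_genes: tuple[str, ...]
    unique_genes: tuple[str, ...]
    mean_highlight: Optional[float] = None


@dataclass(frozen=True)
class ClusteringResult:
    """Cluster assignment of gene-sets: one integer label in 1..k per set."""

    set_ids: tuple[str, ...]
    labels: tuple[int, ...]
    method: ClusterMethod
    k: int
    seed: int
    highlight_scores: Optional[tuple[float, ...]] = None
    cluster_summaries: Mapping[int, ClusterSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.set_ids):
            raise ValueError("one label required per set")
        present = set(self.labels)
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k} with no empty cluster, got {sorted(present)}")
        if self.highlight_scores is not None and any(
            not (0.0 <= s <= 1.0) for s in self.highlight_scores
        ):
            raise ValueError("highlight scores must lie in [0, 1]")

    def members(self, label: int) -> tuple[str, ...]:
        return tuple(s for s, l in zip(self.set_ids, self.labels) if l == label)


def _canonical_labels(raw: np.ndarray, set_ids: Sequence[str]) -> tuple[tuple[int, ...], int]:
    """Renumber arbitrary cluster labels to 1..k by decreasing cluster size,
    ties by the lexicographically smallest member set_id."""
    groups: dict[int, list[str]] = {}
    for sid, lab in zip(set_ids, raw):
        groups.setdefault(int(lab), []).append(sid)
    order = sorted(groups, key=lambda g: (-len(groups[g]), min(groups[g])))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return tuple(remap[int(l)] for l in raw), len(order)


# ---------------------------------------------------------------------------
# Lloyd's k-means (seeded, fixed restarts, objective monotonicity asserted)
# ---------------------------------------------------------------------------

def lloyd_kmeans(
    X: np.ndarray,
    k: int,
    seed: int,
    *,
    restarts: int = 25,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Best-of-``restarts`` Lloyd's algorithm with seeded random-point
    initialisation.  Returns (labels, within-cluster sum of squares).

    The within-cluster SS is verified to be non-increasing across iterations;
    a restart that produces an empty cluster is discarded and re-seeded, and
    only if every restart fails is an error raised.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} points")
    rng = np.random.default_rng(seed)
    best_labels: Optional[np.ndarray] = None
    best_inertia = np.inf
    failures = 0
    for _ in range(restarts):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        prev_inertia = np.inf
        labels = np.zeros(n, dtype=int)
        ok = True
        for _it in range(max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels = d2.argmin(axis=1)
            inertia = float(d2[np.arange(n), labels].sum())
            assert inertia <= prev_inertia + 1e-8, "k-means objective increased"
            if np.unique(labels).size < k:
                ok = False  # empty cluster: discard this restart
                break
            for c in range(k):
                centers[c] = X[labels == c].mean(axis=0)
            if prev_inertia - inertia <= tol:
                prev_inertia = inertia
                break
            prev_inertia = inertia
        if not ok:
            failures += 1
            continue
        if prev_inertia < best_inertia:
            best_inertia = prev_inertia
            best_labels = labels.copy()
    if best_labels is None:
        raise RuntimeError(f"k-means produced an empty cluster in all {restarts} restarts")
    return best_labels, best_inertia


CustomClusterer = Callable[[SimilarityMatrix, int, int], Sequence[int]]


def cluster_gene_sets(
    matrix: SimilarityMatrix,
    k: int,
    method: Union[ClusterMethod, str, CustomClusterer] = ClusterMethod.KMEANS,
    seed: int = 0,
    *,
    hier_linkage: str = "average",
) -> ClusteringResult:
    """Partition gene-sets into ``k`` clusters.

    KMEANS runs Lloyd's algorithm (25 restarts, seeded) on the rows of the
    similarity matrix; HIERARCHICAL cuts an agglomeration (``average``
    linkage by default; ``complete``, ``single`` or ``ward`` on the feature
    rows are accepted) of the dissimilarity transform.  A custom callable
    receives (matrix, k, seed) and returns one raw label per set.
    """
    n = matrix.n
    if not (2 <= k < n):
        raise ValueError(f"k must satisfy 2 <= k < n_sets={n}, got {k}")

    if callable(method) and not isinstance(method, ClusterMethod):
        raw = np.asarray(list(method(matrix, k, seed)))
        if raw.shape != (n,):
            raise ValueError("custom clusterer must return one label per set")
        meth = ClusterMethod.CUSTOM
    else:
        meth = method if isinstance(method, ClusterMethod) else ClusterMethod(str(method).upper())
        if meth is ClusterMethod.KMEANS:
            raw, _ = lloyd_kmeans(matrix.scores, k, seed)
        elif meth is ClusterMethod.HIERARCHICAL:
            if hier_linkage == "ward":
                Z = linkage(matrix.scores, method="ward")
            else:
                D = dissimilarity(matrix)
                Z = linkage(squareform(D, checks=False), method=hier_linkage)
            # cut_tree guarantees exactly k clusters even when merge heights tie
            raw = cut_tree(Z, n_clusters=k).ravel()
        else:
            raise ValueError("CUSTOM method requires a callable")

    labels, k_eff = _canonical_labels(np.asarray(raw), matrix.set_ids)
    if k_eff != k:
        raise ValueError(f"clustering produced {k_eff} clusters, expected {k}")
    return ClusteringResult(
        set_ids=matrix.set_ids, labels=labels, method=meth, k=k, seed=seed
    )


# ---------------------------------------------------------------------------
# Choice of k: elbow / gap statistic / silhouette
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSelectionCurve:
    method: KSelection
    k_values: tuple[int, ...]
    criterion_values: tuple[float, ...]
    recommended_k: int
    gap_se: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.recommended_k not in self.k_values:
            raise ValueError("recommended_k must be one of the tested k values")


def optimal_k(
    matrix: SimilarityMatrix,
    method: Union[KSelection, str],
    k_range: Sequence[int],
    seed: int = 0,
    gap_B: int = 50,
) -> KSelectionCurve:
    """Score a range of candidate cluster counts and recommend one.

    SILHOUETTE: mean silhouette width of the k-means partition, computed on
    the dissimilarity transform; recommend the argmax.  ELBOW: within-cluster
    sum of squares per k; recommend the k of maximum curvature (largest
    second difference).  GAP: Tibshirani's gap statistic against ``gap_B``
    uniform reference draws over the feature-row bounding box; recommend the
    smallest k with Gap(k) >= Gap(k+1) - SE(k+1).
    """
    meth = method if isinstance(method, KSelection) else KSelection(str(method).upper())
    ks = sorted(int(k) for k in k_range)
    n = matrix.n
    if any(not (2 <= k <= n - 1) for k in ks):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    min_len = 3 if meth is KSelection.ELBOW else 2
    if len(ks) < min_len:
        raise ValueError(f"{meth.value} needs at least {min_len} k values, got {len(ks)}")

    X = matrix.scores
    rng = np.random.default_rng(seed)
    gap_se: Optional[tuple[float, ...]] = None

    if meth is KSelection.SILHOUETTE:
        D = dissimilarity(matrix)
        vals = []
        for k in ks:
            labels, _ = lloyd_kmeans(X, k, seed=int(rng.integers(2**31)))
            vals.append(float(silhouette_score(D, labels, metric="precomputed")))
        rec = ks[int(np.argmax(vals))]
    elif meth is KSelection.ELBOW:
        vals = [lloyd_kmeans(X, k, seed=int(rng.integers(2**31)))[1] for k in ks]
        curv = [vals[i - 1] - 2 * vals[i] + vals[i + 1] for i in range(1, len(ks) - 1)]
        rec = ks[1 + int(np.argmax(curv))]
    else:  # GAP
        if gap_B < 1:
            raise ValueError("gap_B must be >= 1")
        lo, hi = X.min(axis=0), X.max(axis=0)
        logW = np.array(
            [np.log(lloyd_kmeans(X, k, seed=int(rng.integers(2**31)), restarts=10)[1]) for k in ks]
        )
        logWref = np.empty((gap_B, len(ks)))
        for b in range(gap_B):
            Xref = rng.uniform(lo, hi, size=X.shape)
            for i, k in enumerate(ks):
                logWref[b, i] = np.log(
                    lloyd_kmeans(Xref, k, seed=int(rng.integers(2**31)), restarts=5)[1]
                )
        gaps = logWref.mean(axis=0) - logW
        se = logWref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / gap_B)
        vals = gaps.tolist()
        gap_se = tuple(float(s) for s in se)
        rec = ks[-1]
        for i in range(len(ks) - 1):
            if gaps[i] >= gaps[i + 1] - se[i + 1]:
                rec = ks[i]
                break
    return KSelectionCurve(
        method=meth,
        k_values=tuple(ks),
        criterion_values=tuple(float(v) for v in vals),
        recommended_k=rec,
        gap_se=gap_se,
    )


# ---------------------------------------------------------------------------
# Cluster annotation: highlight scores and shared/unique genes
# ---------------------------------------------------------------------------

def highlight_score(
    collection: GeneSetCollection,
    clustering: ClusteringResult,
    subset: Sequence[str],
) -> ClusteringResult:
    """Score each gene-set by the fraction of its genes found in a
    user-supplied subset (e.g. reactive-oxygen-signalling genes), and each
    cluster by the mean score of its members."""
    from .model import clean_gene_tokens

    sub = set(clean_gene_tokens(subset))
    if not sub:
        raise ValueError("highlight subset is empty")
    if not (sub & set(collection.universe)):
        import logging

        logging.getLogger("gsclust").warning(
            "highlight subset is disjoint from the collection universe; all scores are 0"
        )
    if tuple(collection.set_ids) != tuple(clustering.set_ids):
        raise ValueError("collection and clustering refer to different set_ids")
    scores = tuple(
        len(gs.gene_set() & sub) / gs.size for gs in collection.gene_sets
    )
    summaries = dict(clustering.cluster_summaries)
    per_cluster: dict[int, list[float]] = {}
    for lab, s in zip(clustering.labels, scores):
        per_cluster.setdefault(lab, []).append(s)
    for lab, vals in per_cluster.items():
        mean = float(np.mean(vals))
        if lab in summaries:
            summaries[lab] = replace(summaries[lab], mean_highlight=mean)
        else:
            summaries[lab] = ClusterSummary(
                n_sets=len(vals), shared_genes=(), unique_genes=(), mean_highlight=mean
            )
    return replace(clustering, highlight_scores=scores, cluster_summaries=summaries)


def genes_per_cluster(
    collection: GeneSetCollection, clustering: ClusteringResult
) -> ClusteringResult:
    """For each cluster, the genes shared by *every* member set and the genes
    unique to the cluster (present in no other cluster)."""
    if tuple(collection.set_ids) != tuple(clustering.set_ids):
        raise ValueError("collection and clustering refer to different set_ids")
    members: dict[int, list] = {}
    for gs, lab in zip(collection.gene_sets, clustering.labels):
        members.setdefault(lab, []).append(gs)
    unions = {lab: frozenset().union(*(g.gene_set() for g in gss)) for lab, gss in members.items()}
    summaries = dict(clustering.cluster_summaries)
    for lab, gss in members.items():
        shared = frozenset.intersection(*(g.gene_set() for g in gss))
        others = frozenset().union(*(unions[o] for o in unions if o != lab)) if len(unions) > 1 else frozenset()
        unique = unions[lab] - others
        prev = summaries.get(lab)
        summaries[lab] = ClusterSummary(
            n_sets=len(gss),
            shared_genes=tuple(sorted(shared)),
            unique_genes=tuple(sorted(unique)),
            mean_highlight=prev.mean_highlight if prev else None,
        )
    return replace(clustering, cluster_summaries=summaries)
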