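"""Pairwise gene-set similarity.

Each pair of gene-sets (i, j) is summarised by the 2x2 contingency of gene
membership over the universe of N genes: the overlap C_ij = |genes_i n genes_j|
and the set sizes P_i, P_j.  Three similarity metrics are built in:

* relative risk (the default), from comorbidity statistics:
  ``RR_ij = C_ij * N / (P_i * P_j - C_ij)`` — large when two sets co-contain
  genes more often than expected under independence;
* Jaccard index ``C / (P_i + P_j - C)`` in [0, 1] (percentage overlap);
* Cohen's kappa, the chance-corrected agreement of the two membership
  indicators over the universe, in [-1, 1].

A user-supplied callable taking :class:`OverlapCounts` can replace the metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Callable, Optional, Union

import numpy as np

from .model import GeneSet, GeneSetCollection


class Metric(str, Enum):
    RR = "RR"
    JACCARD = "JACCARD"
    KAPPA = "KAPPA"
    CUSTOM = "CUSTOM"


@dataclass(frozen=True)
class OverlapCounts:
    """Sufficient statistics for one pair of sets: overlap ``c_ij``, set sizes
    ``p_i``/``p_j`` and universe size ``n``."""

    c_ij: int
    p_i: int
    p_j: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.c_ij <= min(self.p_i, self.p_j)):
            raise ValueError(f"invalid overlap count {self}")
        if max(self.p_i, self.p_j) > self.n or self.n < 1:
            raise ValueError(f"set sizes exceed universe: {self}")


def overlap_counts(set_i: GeneSet, set_j: GeneSet, universe_size: int) -> OverlapCounts:
    """Exact intersection count for two gene-sets against a universe of
    ``universe_size`` genes."""
    p_i, p_j = set_i.size, set_j.size
    if universe_size < max(p_i, p_j):
        raise ValueError(
            f"universe_size {universe_size} smaller than a set "
            f"({set_i.set_id}: {p_i}, {set_j.set_id}: {p_j})"
        )
    c = len(set_i.gene_set() & set_j.gene_set())
    return OverlapCounts(c_ij=c, p_i=p_i, p_j=p_j, n=universe_size)


def relative_risk(counts: OverlapCounts) -> float:
    """``C*N / (P_i*P_j - C)``; 0 when C = 0, +inf when the denominator
    vanishes (only for two identical singleton sets) — the infinity is a
    sentinel replaced at matrix level."""
    c, p_i, p_j, n = counts.c_ij, counts.p_i, counts.p_j, counts.n
    if c == 0:
        return 0.0
    denom = p_i * p_j - c
    if denom == 0:
        return math.inf
    return c * n / denom


def jaccard(counts: OverlapCounts) -> float:
    """Intersection over union, in [0, 1]."""
    c, p_i, p_j = counts.c_ij, counts.p_i, counts.p_j
    denom = p_i + p_j - c
    if denom <= 0:
        raise ValueError("Jaccard undefined for two empty sets")
    return c / denom


def cohens_kappa(counts: OverlapCounts) -> float:
    """Chance-corrected agreement of the two membership indicators.

    With a = C, d = N - P_i - P_j + C: observed agreement p_o = (a + d)/N and
    expected agreement p_e = (P_i*P_j + (N-P_i)(N-P_j)) / N^2; kappa is
    (p_o - p_e)/(1 - p_e), with kappa = 1 by convention when p_e = 1 (both
    sets equal the full universe).
    """
    c, p_i, p_j, n = counts.c_ij, counts.p_i, counts.p_j, counts.n
    p_o = (c + (n - p_i - p_j + c)) / n
    p_e = (p_i * p_j + (n - p_i) * (n - p_j)) / (n * n)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


_BUILTIN: dict[Metric, Callable[[OverlapCounts], float]] = {
    Metric.RR: relative_risk,
    Metric.JACCARD: jaccard,
    Metric.KAPPA: cohens_kappa,
}


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise score matrix over an ordered list of set_ids.

    ``infinite_replaced`` counts RR infinity sentinels replaced by the largest
    finite off-diagonal score; ``cap_applied`` records an elementwise upper
    clamp if one was applied.
    """

    set_ids: tuple[str, ...]
    scores: np.ndarray
    metric: Metric
    cap_applied: Optional[float] = None
    infinite_replaced: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.shape != (len(self.set_ids), len(self.set_ids)):
            raise ValueError("scores shape does not match set_ids")
        if not np.allclose(s, s.T, atol=1e-12, rtol=0):
            raise ValueError("similarity matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.set_ids)


MetricSpec = Union[Metric, str, Callable[[OverlapCounts], float]]


def _resolve_metric(metric: MetricSpec):
    if callable(metric) and not isinstance(metric, Metric):
        return Metric.CUSTOM, metric
    m = metric if isinstance(metric, Metric) else Metric(str(metric).upper())
    if m is Metric.CUSTOM:
        raise ValueError("CUSTOM metric requires a callable")
    return m, _BUILTIN[m]


def build_similarity_matrix(
    collection: GeneSetCollection,
    metric: MetricSpec = Metric.RR,
    *,
    universe_size: Optional[int] = None,
) -> SimilarityMatrix:
    """Score every pair of gene-sets (diagonal included) in the collection.

    For the builtin metrics the computation is vectorised from the binary
    membership matrix; each entry equals the scalar metric applied to the
    pair's :func:`overlap_counts`.  The RR diagonal uses the same formula
    (``RR_ii = N/(P_i - 1)`` for P_i > 1).  Infinities are replaced by the
    largest finite off-diagonal value and counted in ``infinite_replaced``.
    """
    sets = collection.gene_sets
    if len(sets) < 2:
        raise ValueError("need at least two gene-sets to build a similarity matrix")
    n_univ = universe_size if universe_size is not None else len(collection.universe)

    m, fn = _resolve_metric(metric)
    genes = sorted(set(g for gs in sets for g in gs.genes))
    gidx = {g: i for i, g in enumerate(genes)}
    M = np.zeros((len(sets), len(genes)), dtype=np.int64)
    for i, gs in enumerate(sets):
        M[i, [gidx[g] for g in gs.genes]] = 1
    C = M @ M.T
    p = np.diag(C).astype(float)

    if m is Metric.RR:
        denom = np.outer(p, p) - C
        with np.errstate(divide="ignore", invalid="ignore"):
            S = np.where(C == 0, 0.0, np.where(denom == 0, np.inf, C * n_univ / np.where(denom == 0, 1, denom)))
    elif m is Metric.JACCARD:
        S = C / (p[:, None] + p[None, :] - C)
    elif m is Metric.KAPPA:
        p_o = (C + (n_univ - p[:, None] - p[None, :] + C)) / n_univ
        p_e = (np.outer(p, p) + np.outer(n_univ - p, n_univ - p)) / (n_univ**2)
        S = np.where(p_e == 1.0, 1.0, (p_o - p_e) / np.where(p_e == 1.0, 1.0, 1.0 - p_e))
    else:
        S = np.empty((len(sets), len(sets)))
        for i in range(len(sets)):
            for j in range(i, len(sets)):
                val = fn(overlap_counts(sets[i], sets[j], n_univ))
                if not isinstance(val, (int, float)) or not math.isfinite(float(val)):
                    raise ValueError(
                        f"custom metric returned non-finite value {val!r} for pair "
                        f"({sets[i].set_id}, {sets[j].set_id})"
                    )
                S[i, j] = S[j, i] = float(val)

    S = np.asarray(S, dtype=float)
    n_inf = int(np.isinf(S).sum())
    if n_inf:
        off = S[~np.eye(len(sets), dtype=bool)]
        finite_off = off[np.isfinite(off)]
        if finite_off.size:
            repl = float(finite_off.max())
        else:
            finite_all = S[np.isfinite(S)]
            repl = float(finite_all.max()) if finite_all.size else 0.0
        S = np.where(np.isinf(S), repl, S)
    S = (S + S.T) / 2.0  # enforce exact symmetry against float noise
    return SimilarityMatrix(
        set_ids=collection.set_ids,
        scores=S,
        metric=m,
        infinite_replaced=n_inf,
    )


def cap_matrix(matrix: SimilarityMatrix, cap: float) -> SimilarityMatrix:
    """Clamp scores elementwise at ``cap`` (used for visualisation and,
    optionally, as the clustering feature space)."""
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    return replace(matrix, scores=np.minimum(matrix.scores, cap), cap_applied=cap)


def dissimilarity(matrix: SimilarityMatrix) -> np.ndarray:
    """Monotone, bounded dissimilarity transform of a similarity matrix.

    JACCARD -> 1 - s; KAPPA -> (1 - s)/2; RR (and CUSTOM) -> 1 - s/max(s)
    over the (capped) matrix.  The diagonal is forced to zero.
    """
    S = matrix.scores
    if matrix.metric is Metric.JACCARD:
        D = 1.0 - S
    elif matrix.metric is Metric.KAPPA:
        D = (1.0 - S) / 2.0
    else:
        mx = float(S.max())
        D = np.ones_like(S) if mx <= 0 else 1.0 - S / mx
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return D
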