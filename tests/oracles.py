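"""Independent brute-force oracles used by the tests.

These recompute the package's statistics by a different route — explicit
2x2 contingency tables over an enumerated universe, exhaustive combinatorial
enumeration, double loops — and must stay independent of the implementation
they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf


def contingency(set_i: frozenset, set_j: frozenset, universe: list) -> tuple[int, int, int, int]:
    """Explicit 2x2 gene-membership table (a=both, b=i only, c=j only,
    d=neither) built by enumerating every gene in the universe."""
    a = b = c = d = 0
    for g in universe:
        in_i, in_j = g in set_i, g in set_j
        if in_i and in_j:
            a += 1
        elif in_i:
            b += 1
        elif in_j:
            c += 1
        else:
            d += 1
    return a, b, c, d


def rr_oracle(set_i, set_j, universe) -> float:
    a, b, c, d = contingency(set_i, set_j, universe)
    n = a + b + c + d
    if a == 0:
        return 0.0
    denom = (a + b) * (a + c) - a
    return inf if denom == 0 else a * n / denom


def jaccard_oracle(set_i, set_j, universe) -> float:
    a, b, c, _ = contingency(set_i, set_j, universe)
    return a / (a + b + c)


def kappa_oracle(set_i, set_j, universe) -> float:
    """Rater-agreement kappa: the two sets are two binary raters over every
    gene in the universe."""
    a, b, c, d = contingency(set_i, set_j, universe)
    n = a + b + c + d
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def hypergeom_tail_oracle(k_hits: int, universe: int, term_size: int, query_size: int) -> float:
    """P[X >= k_hits] by exhaustive enumeration of all C(N, n) draws
    (feasible for N <= 12)."""
    genes = list(range(universe))
    term = set(genes[:term_size])
    total = comb(universe, query_size)
    hits = sum(
        1 for draw in combinations(genes, query_size) if len(term & set(draw)) >= k_hits
    )
    return hits / total


def edges_oracle(set_ids, scores, threshold):
    """Brute-force strict-threshold double loop."""
    out = set()
    n = len(set_ids)
    for i in range(n):
        for j in range(n):
            if i != j and scores[i][j] > threshold:
                out.add(frozenset((set_ids[i], set_ids[j])))
    return out
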