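"""Over-representation analysis of cluster gene lists.

After clustering, each cluster's gene list (all member genes, or the genes
unique to the cluster) is tested against a user-supplied annotation
collection (GMT) with the one-sided hypergeometric test: for a universe of N
genes, an annotation term of K genes and a query of n genes with k hits, the
p-value is P[X >= k] with X ~ Hypergeometric(N, K, n).  P-values are
Benjamini-Hochberg adjusted across all terms within each cluster.

This is a fully offline, deterministic interpretation step over local
annotation files; no web service is queried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cluster import ClusteringResult, genes_per_cluster
from .model import GeneSetCollection

logger = logging.getLogger("gsclust")


@dataclass(frozen=True)
class OraResult:
    cluster: int
    term: str
    k_hits: int
    term_size: int
    query_size: int
    universe_size: int
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of range: {self.pvalue}")
        if self.fdr < self.pvalue - 1e-12:
            raise ValueError("FDR cannot be smaller than the raw p-value")
        if self.k_hits > min(self.term_size, self.query_size):
            raise ValueError("hits exceed term or query size")


def hypergeom_upper_tail(k_hits: int, universe: int, term_size: int, query_size: int) -> float:
    """P[X >= k_hits] for X ~ Hypergeometric(N=universe, K=term_size,
    n=query_size); equals 1 when k_hits = 0."""
    return float(hypergeom.sf(k_hits - 1, universe, term_size, query_size))


def ora_per_cluster(
    collection: GeneSetCollection,
    clustering: ClusteringResult,
    annotations: GeneSetCollection,
    gene_mode: str = "all",
    *,
    universe: Optional[frozenset[str]] = None,
) -> list[OraResult]:
    """Hypergeometric ORA of every cluster against every annotation term.

    ``gene_mode='all'`` queries the union of member genes per cluster;
    ``'unique'`` queries only the genes unique to the cluster (which can be
    empty — such clusters are skipped with a warning).  The default universe
    is the union of the data and annotation universes (conservative); an
    explicit universe may be supplied.  Results are sorted by (cluster, fdr,
    pvalue, term).
    """
    if gene_mode not in ("all", "unique"):
        raise ValueError(f"gene_mode must be 'all' or 'unique', got {gene_mode!r}")
    univ = (
        frozenset(universe)
        if universe is not None
        else collection.universe | annotations.universe
    )
    N = len(univ)
    with_genes = genes_per_cluster(collection, clustering)

    results: list[OraResult] = []
    for lab in range(1, clustering.k + 1):
        summ = with_genes.cluster_summaries[lab]
        if gene_mode == "all":
            query = set()
            for sid in with_genes.members(lab):
                query.update(collection[sid].genes)
        else:
            query = set(summ.unique_genes)
        query &= univ
        if not query:
            logger.warning("cluster %d: empty %s-gene query; skipped", lab, gene_mode)
            continue
        pvals, rows = [], []
        for term in annotations.gene_sets:
            tg = term.gene_set() & univ
            k = len(tg & query)
            p = hypergeom_upper_tail(k, N, len(tg), len(query))
            pvals.append(p)
            rows.append((term.name, k, len(tg)))
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
        for (name, k, K), p, q in zip(rows, pvals, fdrs):
            results.append(
                OraResult(
                    cluster=lab, term=name, k_hits=k, term_size=K,
                    query_size=len(query), universe_size=N,
                    pvalue=float(p), fdr=float(q),
                )
            )
    results.sort(key=lambda r: (r.cluster, r.fdr, r.pvalue, r.term))
    return results


def write_ora_results(results: list[OraResult], path: "str | Path") -> Path:
    path = Path(path)
    lines = ["cluster\tterm\tk_hits\tterm_size\tquery_size\tuniverse_size\tpvalue\tfdr"]
    for r in results:
        lines.append(
            f"{r.cluster}\t{r.term}\t{r.k_hits}\t{r.term_size}\t{r.query_size}"
            f"\t{r.universe_size}\t{r.pvalue!r}\t{r.fdr!r}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
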