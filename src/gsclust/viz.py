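"""Visualisation of clustered similarity matrices.

Three views: a heatmap of the (optionally capped) similarity matrix ordered
by cluster, a dendrogram of the average-linkage tree, and a network in which
nodes are gene-sets and edges connect pairs whose similarity exceeds a
threshold (strictly greater, matching "edges for gene-sets with a distance
above T").  The testable artifacts are the orderings, edge lists and merge
structures; images are rendered with matplotlib/seaborn but never asserted
on pixel content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import seaborn as sns
from scipy.cluster.hierarchy import dendrogram, linkage, to_tree
from scipy.spatial.distance import squareform

from .cluster import ClusteringResult
from .distance import SimilarityMatrix, dissimilarity


@dataclass(frozen=True)
class NetworkSpec:
    """Thresholded similarity graph: nodes carry cluster labels (and optional
    highlight scores); one edge per unordered pair with score strictly above
    the threshold; isolated nodes are retained."""

    nodes: tuple[tuple[str, int, Optional[float]], ...]  # (set_id, cluster, highlight)
    edges: tuple[tuple[str, str, float], ...]  # (id_i, id_j, score), i < j positionally
    threshold: float
    cap: Optional[float] = None

    def __post_init__(self) -> None:
        seen = set()
        for i, j, s in self.edges:
            if i == j:
                raise ValueError(f"self-edge on {i}")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate edge {i}-{j}")
            seen.add(key)
            if not s > self.threshold:
                raise ValueError(f"edge {i}-{j} score {s} not above threshold {self.threshold}")


def build_network(
    matrix: SimilarityMatrix,
    clustering: ClusteringResult,
    threshold: float,
) -> NetworkSpec:
    """Edges for every unordered off-diagonal pair with score strictly above
    ``threshold``; all nodes kept."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if matrix.set_ids != clustering.set_ids:
        raise ValueError("matrix and clustering refer to different set_ids")
    hs = clustering.highlight_scores or (None,) * matrix.n
    nodes = tuple(
        (sid, lab, h) for sid, lab, h in zip(matrix.set_ids, clustering.labels, hs)
    )
    edges = []
    S = matrix.scores
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            if S[i, j] > threshold:
                edges.append((matrix.set_ids[i], matrix.set_ids[j], float(S[i, j])))
    return NetworkSpec(
        nodes=nodes, edges=tuple(edges), threshold=threshold, cap=matrix.cap_applied
    )


def network_to_graph(spec: NetworkSpec) -> nx.Graph:
    G = nx.Graph(threshold=spec.threshold)
    for sid, lab, h in spec.nodes:
        attrs = {"cluster": lab}
        if h is not None:
            attrs["highlight"] = h
        G.add_node(sid, **attrs)
    for i, j, s in spec.edges:
        G.add_edge(i, j, score=s)
    return G


def write_edge_list(spec: NetworkSpec, path: "str | Path") -> Path:
    path = Path(path)
    lines = ["source_id\ttarget_id\tscore"]
    for i, j, s in spec.edges:
        lines.append(f"{i}\t{j}\t{s!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_graphml(spec: NetworkSpec, path: "str | Path") -> Path:
    path = Path(path)
    nx.write_graphml(network_to_graph(spec), path)
    return path


def render_network(
    spec: NetworkSpec, out_path: "str | Path", seed: int = 0
) -> Path:
    """Force-directed drawing with a seeded layout; node colour = cluster."""
    out_path = Path(out_path)
    G = network_to_graph(spec)
    pos = nx.spring_layout(G, seed=seed)
    labels = [G.nodes[n]["cluster"] for n in G.nodes]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx(
        G, pos=pos, ax=ax, node_color=labels, cmap="tab10",
        with_labels=False, node_size=120, edge_color="grey",
    )
    ax.set_axis_off()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def heatmap_order(clustering: ClusteringResult) -> tuple[str, ...]:
    """Row/column order for the heatmap: by cluster label, then set_id.
    A pure function of (labels, set_ids), independent of input order."""
    return tuple(
        sid for lab, sid in sorted(zip(clustering.labels, clustering.set_ids))
    )


def render_heatmap(
    matrix: SimilarityMatrix,
    clustering: ClusteringResult,
    out_path: "str | Path",
    cap: Optional[float] = None,
) -> Path:
    """Heatmap of the similarity matrix, rows/columns grouped by cluster,
    with a cluster-colour sidebar (and a highlight sidebar when scores are
    present).  ``cap`` bounds the colour scale only; the data are untouched."""
    if matrix.set_ids != clustering.set_ids:
        raise ValueError("matrix and clustering refer to different set_ids")
    out_path = Path(out_path)
    order = heatmap_order(clustering)
    idx = [matrix.set_ids.index(s) for s in order]
    S = matrix.scores[np.ix_(idx, idx)]
    labels = [clustering.labels[matrix.set_ids.index(s)] for s in order]

    palette = sns.color_palette("tab10", n_colors=clustering.k)
    row_colors = [palette[l - 1] for l in labels]
    vmax = cap if cap is not None else None

    fig, (ax_bar, ax_hm) = plt.subplots(
        1, 2, figsize=(8, 7), gridspec_kw={"width_ratios": [0.03, 1], "wspace": 0.02}
    )
    for i, c in enumerate(row_colors):
        ax_bar.add_patch(plt.Rectangle((0, len(order) - 1 - i), 1, 1, color=c))
    ax_bar.set_xlim(0, 1)
    ax_bar.set_ylim(0, len(order))
    ax_bar.set_axis_off()
    sns.heatmap(
        S, ax=ax_hm, vmax=vmax, xticklabels=False,
        yticklabels=[s.split("::")[-1] for s in order] if len(order) <= 40 else False,
        cmap="viridis", cbar_kws={"label": matrix.metric.value},
    )
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def _tree_to_newick(node, names: Sequence[str]) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _tree_to_newick(node.get_left(), names)
    right = _tree_to_newick(node.get_right(), names)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.10g},{right}:{dr:.10g})"


def linkage_newick(matrix: SimilarityMatrix, hier_linkage: str = "average") -> str:
    """Newick text for the hierarchical tree on the dissimilarity transform
    (leaf names = set names/ids; branch lengths from merge heights)."""
    D = dissimilarity(matrix)
    Z = linkage(squareform(D, checks=False), method=hier_linkage)
    tree = to_tree(Z)
    return _tree_to_newick(tree, list(matrix.set_ids)) + ";"


def render_dendrogram(
    matrix: SimilarityMatrix,
    out_path: "str | Path",
    *,
    newick_path: "str | Path | None" = None,
    hier_linkage: str = "average",
) -> Path:
    """Average-linkage dendrogram on the dissimilarity transform; the merge
    structure is also exported as newick text for testability."""
    if matrix.n < 2:
        raise ValueError("need at least two gene-sets for a dendrogram")
    out_path = Path(out_path)
    D = dissimilarity(matrix)
    Z = linkage(squareform(D, checks=False), method=hier_linkage)
    fig, ax = plt.subplots(figsize=(8, 5))
    dendrogram(Z, labels=list(matrix.set_ids), ax=ax, leaf_rotation=90)
    ax.set_ylabel("dissimilarity")
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    if newick_path is not None:
        Path(newick_path).write_text(linkage_newick(matrix, hier_linkage) + "\n", encoding="utf-8")
    return out_path
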