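"""End-to-end pipeline orchestration.

A :class:`PipelineConfig` (serialisable to/from YAML) describes the whole
run: inputs, harmonization, metric, clustering, highlight subset, ORA
annotations and the output directory.  :func:`run_pipeline` executes

    load -> merge -> manage -> harmonize -> distances -> optimal-k ->
    cluster -> highlight -> genes-per-cluster -> ORA -> plots -> exports

writing a manifest of every artifact.  Any stage failure is re-raised as a
:class:`StageError` naming the stage, which the CLI maps to a nonzero exit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import io as gio
from .cluster import (
    cluster_gene_sets,
    genes_per_cluster,
    highlight_score,
    optimal_k,
)
from .distance import build_similarity_matrix, cap_matrix
from .harmonize import MappingTable, harmonize, reduce_redundancy
from .model import GeneSetCollection, manage_gene_sets, merge_collections
from .ora import ora_per_cluster, write_ora_results
from .viz import (
    build_network,
    render_dendrogram,
    render_heatmap,
    render_network,
    write_edge_list,
    write_graphml,
)

logger = logging.getLogger("gsclust")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class InputSpec:
    path: str
    dialect: str  # gmt | ipa | great
    experiment: str = ""
    species: str = ""
    categories: Optional[list[str]] = None


@dataclass
class PipelineConfig:
    inputs: list[InputSpec] = field(default_factory=list)
    mapping_path: Optional[str] = None
    source_namespace: str = "SYMBOL"
    unmapped_policy: str = "keep"
    keep_categories: Optional[list[str]] = None
    drop_categories: Optional[list[str]] = None
    min_size: int = 1
    max_size: int = int(1e9)
    metric: str = "rr"
    cap: Optional[float] = None
    cluster_method: str = "kmeans"
    k: Optional[int] = None
    optimal_k_method: Optional[str] = None  # elbow | gap | silhouette
    k_min: int = 2
    k_max: int = 6
    gap_B: int = 50
    seed: int = 0
    highlight_path: Optional[str] = None
    annotation_path: Optional[str] = None
    ora_gene_mode: str = "all"
    network_threshold: float = 0.0
    out_dir: str = "gsclust_out"

    def to_yaml(self, path: "str | Path") -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        path.write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        inputs = [InputSpec(**i) for i in d.pop("inputs", [])]
        return cls(inputs=inputs, **d)


def load_input(spec: InputSpec):
    dialect = spec.dialect.lower()
    if dialect == "gmt":
        return gio.read_gmt(spec.path, spec.experiment, species=spec.species)
    if dialect == "ipa":
        return gio.read_ipa(spec.path, spec.experiment, species=spec.species)
    if dialect == "great":
        return gio.read_great(
            spec.path, spec.experiment, species=spec.species, categories=spec.categories
        )
    raise ValueError(f"unknown dialect {spec.dialect!r}")


def read_gene_list(path: "str | Path") -> list[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute the full pipeline; returns a manifest dict with artifact
    paths, the chosen k, and per-stage counts.  Also writes the manifest as a
    TSV in the output directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"artifacts": [], "params": dataclasses.asdict(config)}

    def _stage(name: str):
        logger.info("[%s] starting", name)

        class _Ctx:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with _stage("load"):
        if not config.inputs:
            raise ValueError("no inputs configured")
        loaded = [load_input(s) for s in config.inputs]
        collections = [c for c, _ in loaded]
        for (_, rep), spec in zip(loaded, config.inputs):
            logger.info("[load] %s: %d sets (%d rows skipped)", spec.path, rep.sets_created, rep.rows_skipped)

    with _stage("merge"):
        coll = collections[0] if len(collections) == 1 else merge_collections(collections)

    with _stage("manage"):
        if (
            config.keep_categories is not None
            or config.drop_categories is not None
            or config.min_size > 1
            or config.max_size < int(1e9)
        ):
            coll = manage_gene_sets(
                coll,
                keep_categories=config.keep_categories,
                drop_categories=config.drop_categories,
                min_size=config.min_size,
                max_size=config.max_size,
            )

    with _stage("harmonize"):
        if config.mapping_path:
            mapping = MappingTable.from_tsv(config.mapping_path)
            coll, h_report = harmonize(
                coll, mapping, config.source_namespace, config.unmapped_policy
            )
            manifest["harmonization"] = {
                "mapped": h_report.total_mapped,
                "unmapped": h_report.total_unmapped,
                "high_unmapped_flag": h_report.high_unmapped_flag,
            }
        coll, merged_dupes = reduce_redundancy(coll)
        manifest["duplicates_merged"] = len(merged_dupes)

    with _stage("distances"):
        matrix = build_similarity_matrix(coll, config.metric)
        feature_matrix = cap_matrix(matrix, config.cap) if config.cap is not None else matrix

    with _stage("optimal-k"):
        if config.optimal_k_method:
            ks = list(range(config.k_min, min(config.k_max, len(coll) - 1) + 1))
            curve = optimal_k(
                feature_matrix, config.optimal_k_method, ks,
                seed=config.seed, gap_B=config.gap_B,
            )
            k = curve.recommended_k
            manifest["k_selection"] = {
                "method": curve.method.value,
                "k_values": list(curve.k_values),
                "criterion_values": list(curve.criterion_values),
                "recommended_k": k,
            }
        elif config.k is not None:
            k = config.k
        else:
            raise ValueError("configure either k or optimal_k_method")
        manifest["k"] = k

    with _stage("cluster"):
        clustering = cluster_gene_sets(
            feature_matrix, k, config.cluster_method, seed=config.seed
        )

    with _stage("highlight"):
        if config.highlight_path:
            subset = read_gene_list(config.highlight_path)
            clustering = highlight_score(coll, clustering, subset)

    with _stage("genes-per-cluster"):
        clustering = genes_per_cluster(coll, clustering)

    with _stage("ora"):
        if config.annotation_path:
            ann, _ = gio.read_gmt(config.annotation_path, experiment="annotations")
            results = ora_per_cluster(coll, clustering, ann, config.ora_gene_mode)
            p = write_ora_results(results, out_dir / "ora_results.tsv")
            manifest["artifacts"].append(str(p))

    with _stage("plots"):
        viz_matrix = cap_matrix(matrix, config.cap) if config.cap is not None else matrix
        spec = build_network(matrix, clustering, config.network_threshold)
        for p in (
            write_edge_list(spec, out_dir / "network_edges.tsv"),
            write_graphml(spec, out_dir / "network.graphml"),
            render_network(spec, out_dir / "network.png", seed=config.seed),
            render_heatmap(viz_matrix, clustering, out_dir / "heatmap.png", cap=config.cap),
            render_dendrogram(
                matrix, out_dir / "dendrogram.png",
                newick_path=out_dir / "dendrogram.nwk",
            ),
        ):
            manifest["artifacts"].append(str(p))

    with _stage("export"):
        for p in gio.write_outputs(coll, matrix, clustering, out_dir):
            manifest["artifacts"].append(str(p))
        mpath = out_dir / "manifest.tsv"
        lines = ["artifact"]  # paths relative to out_dir so reruns compare cleanly
        lines += sorted(str(Path(a).relative_to(out_dir)) for a in manifest["artifacts"])
        mpath.write_text("\n".join(lines) + "\n", encoding="utf-8")
        manifest["manifest_path"] = str(mpath)

    return manifest
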