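"""Readers and writers for gene-set analysis files.

Readers cover four dialects: GMT (tab-separated: name, description, genes...),
IPA canonical-pathway exports, GREAT region-enrichment exports, and a generic
"name + gene list" table.  Exact column names in IPA/GREAT exports vary by
tool version, so columns are matched case-insensitively on normalised header
tokens, with an explicit column-mapping override as the escape hatch.

Every reader returns a :class:`ParseReport` that reconciles exactly:
``rows_read = sets_created + rows_skipped``.

Writers emit the pipeline artifacts: gene-set table, square similarity
matrix, per-cluster summary (all UTF-8 TSV, '.' decimal, no index column) and
a GMT of harmonized sets.  Floats are printed with ``repr`` so a read-back
reproduces the in-memory value bit-for-bit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .cluster import ClusteringResult
from .distance import Metric, SimilarityMatrix
from .model import (
    GeneSetCollection,
    SourceTool,
    clean_gene_tokens,
    create_collection,
    manage_gene_sets,
)

logger = logging.getLogger("gsclust")


@dataclass(frozen=True)
class ParseReport:
    file_path: str
    dialect: str
    rows_read: int
    sets_created: int
    rows_skipped: int
    skip_reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.rows_read != self.sets_created + self.rows_skipped:
            raise ValueError(
                f"parse report does not reconcile: {self.rows_read} rows != "
                f"{self.sets_created} sets + {self.rows_skipped} skipped"
            )


def _norm_header(tok: str) -> str:
    """Lowercase and strip everything but alphanumerics, for tolerant header
    matching across export versions."""
    return re.sub(r"[^a-z0-9]+", "", tok.lower())


def _find_column(
    header: Sequence[str],
    candidates: Sequence[str],
    override: Optional[str],
) -> Optional[int]:
    normed = [_norm_header(h) for h in header]
    if override is not None:
        key = _norm_header(override)
        return normed.index(key) if key in normed else None
    for cand in candidates:
        key = _norm_header(cand)
        for i, h in enumerate(normed):
            if key == h or key in h:
                return i
    return None


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(
    path: "str | Path",
    experiment: str = "",
    *,
    species: str = "",
) -> tuple[GeneSetCollection, ParseReport]:
    """One gene-set per line: name, description (stored as category when
    non-empty), then gene tokens.  Lines with fewer than three fields are
    skipped with a reason; a file with no parsable line is an error."""
    path = Path(path)
    records = []
    rows_read = 0
    skipped: list[str] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        rows_read += 1
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            skipped.append(f"line {lineno}: fewer than 3 tab-separated fields")
            continue
        name, desc, genes = fields[0], fields[1], fields[2:]
        cleaned = clean_gene_tokens(genes)
        if len(cleaned) < len([g for g in genes if g.strip()]):
            logger.warning("%s line %d: duplicate gene tokens collapsed", path, lineno)
        records.append(
            dict(
                name=name,
                genes=genes,
                experiment=experiment,
                source_tool=SourceTool.GMT,
                species=species,
                category=desc.strip() or None,
            )
        )
    if not records:
        raise ValueError(f"{path}: no parsable GMT lines")
    coll = create_collection(records)
    report = ParseReport(
        file_path=str(path),
        dialect="GMT",
        rows_read=rows_read,
        sets_created=len(coll),
        rows_skipped=rows_read - len(coll),
        skip_reasons=tuple(skipped),
    )
    return coll, report


def write_gmt(collection: GeneSetCollection, path: "str | Path") -> Path:
    path = Path(path)
    lines = []
    for gs in collection.gene_sets:
        desc = gs.category or ""
        lines.append("\t".join([gs.name, desc, *gs.genes]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# IPA canonical-pathway exports
# ---------------------------------------------------------------------------

IPA_NAME_CANDIDATES = ("Ingenuity Canonical Pathways",)
IPA_LOGP_CANDIDATES = ("-log(p-value)",)
IPA_MOLECULES_CANDIDATES = ("Molecules",)


def _split_molecules(cell: str) -> tuple[list[str], int]:
    """Split an IPA Molecules cell on commas, then split complex notation
    ('A/B') into member genes.  Returns (tokens, n_complexes_split)."""
    toks: list[str] = []
    n_split = 0
    for part in cell.split(","):
        part = part.strip()
        if not part:
            continue
        if "/" in part:
            n_split += 1
            toks.extend(p for p in part.split("/") if p.strip())
        else:
            toks.append(part)
    return toks, n_split


def read_ipa(
    path: "str | Path",
    experiment: str = "",
    *,
    species: str = "",
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple[GeneSetCollection, ParseReport]:
    """Parse a tab-delimited IPA canonical-pathways export.

    Leading banner lines before the header are tolerated (counted as skipped
    rows); the pathway-name, -log(p-value) and Molecules columns are located
    case-insensitively, overridable via ``column_map`` with keys
    ``name``/``logp``/``molecules``.  p-values are recovered as
    ``10**(-logp)``; an unparsable -log(p) cell leaves the p-value absent but
    keeps the row.  Complex notation in Molecules ("A/B") is split into
    member genes.
    """
    path = Path(path)
    column_map = column_map or {}
    lines = [l for l in path.read_text(encoding="utf-8").splitlines() if l.strip()]
    header_idx = None
    cols: dict[str, int] = {}
    for i, line in enumerate(lines):
        fields = line.split("\t")
        ci_name = _find_column(fields, IPA_NAME_CANDIDATES, column_map.get("name"))
        ci_logp = _find_column(fields, IPA_LOGP_CANDIDATES, column_map.get("logp"))
        ci_mol = _find_column(fields, IPA_MOLECULES_CANDIDATES, column_map.get("molecules"))
        if ci_name is not None and ci_mol is not None:
            if ci_logp is None:
                raise ValueError(f"{path}: header found but missing '-log(p-value)' column")
            header_idx, cols = i, {"name": ci_name, "logp": ci_logp, "mol": ci_mol}
            break
    if header_idx is None:
        raise ValueError(
            f"{path}: no header row with the mandatory columns "
            f"'Ingenuity Canonical Pathways' and 'Molecules'"
        )

    records = []
    skipped = [f"line {i + 1}: banner line before header" for i in range(header_idx)]
    n_complex = 0
    for lineno, line in enumerate(lines[header_idx + 1 :], header_idx + 2):
        fields = line.split("\t")
        if len(fields) <= max(cols.values()):
            skipped.append(f"line {lineno}: too few columns")
            continue
        name = fields[cols["name"]].strip()
        genes, ns = _split_molecules(fields[cols["mol"]])
        n_complex += ns
        if not name or not genes:
            skipped.append(f"line {lineno}: empty pathway name or molecule list")
            continue
        pvalue: Optional[float] = None
        try:
            pvalue = float(10.0 ** -float(fields[cols["logp"]]))
        except ValueError:
            logger.warning("%s line %d: unparsable -log(p-value) cell; p-value absent", path, lineno)
        records.append(
            dict(
                name=name,
                genes=genes,
                experiment=experiment,
                source_tool=SourceTool.IPA,
                species=species,
                category="Canonical Pathways",
                pvalue=pvalue,
            )
        )
    if n_complex:
        logger.info("%s: split %d complex tokens ('A/B') into member genes", path, n_complex)
    if not records:
        raise ValueError(f"{path}: no parsable data rows")
    coll = create_collection(records)
    rows_read = header_idx + len(lines) - header_idx - 1  # banners + data rows
    report = ParseReport(
        file_path=str(path),
        dialect="IPA",
        rows_read=rows_read,
        sets_created=len(coll),
        rows_skipped=rows_read - len(coll),
        skip_reasons=tuple(skipped),
    )
    return coll, report


# ---------------------------------------------------------------------------
# GREAT region-enrichment exports
# ---------------------------------------------------------------------------

GREAT_ONTOLOGY_CANDIDATES = ("Ontology",)
GREAT_TERM_CANDIDATES = ("Term Name", "Desc")
GREAT_FDR_CANDIDATES = ("Hyper FDR Q-Val", "HyperFdrQ")
GREAT_GENES_CANDIDATES = ("Genes", "Hyper Foreground Gene Names")


def read_great(
    path: "str | Path",
    experiment: str = "",
    *,
    species: str = "",
    categories: Optional[Sequence[str]] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple[GeneSetCollection, ParseReport]:
    """Parse a tab-delimited GREAT "all ontologies" export.

    '#'-prefixed comment lines are skipped entirely (excluded from the row
    reconciliation); the ontology column becomes the set category, and an
    optional ``categories`` filter keeps only those ontologies.
    """
    path = Path(path)
    column_map = column_map or {}
    lines = [
        l
        for l in path.read_text(encoding="utf-8").splitlines()
        if l.strip() and not l.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: no non-comment lines")
    header = lines[0].split("\t")
    cols = {}
    for key, cands in (
        ("ontology", GREAT_ONTOLOGY_CANDIDATES),
        ("term", GREAT_TERM_CANDIDATES),
        ("fdr", GREAT_FDR_CANDIDATES),
        ("genes", GREAT_GENES_CANDIDATES),
    ):
        ci = _find_column(header, cands, column_map.get(key))
        if ci is None:
            raise ValueError(f"{path}: missing mandatory GREAT column for {key!r}")
        cols[key] = ci

    records = []
    skipped: list[str] = []
    rows_read = 0
    for lineno, line in enumerate(lines[1:], 2):
        rows_read += 1
        fields = line.split("\t")
        if len(fields) <= max(cols.values()):
            skipped.append(f"row {lineno}: too few columns")
            continue
        name = fields[cols["term"]].strip()
        genes = [g for g in fields[cols["genes"]].split(",") if g.strip()]
        if not name or not genes:
            skipped.append(f"row {lineno}: empty term name or gene list")
            continue
        pvalue: Optional[float] = None
        try:
            pvalue = float(fields[cols["fdr"]])
        except ValueError:
            logger.warning("%s row %d: unparsable FDR cell; p-value absent", path, lineno)
        records.append(
            dict(
                name=name,
                genes=genes,
                experiment=experiment,
                source_tool=SourceTool.GREAT,
                species=species,
                category=fields[cols["ontology"]].strip() or None,
                pvalue=pvalue,
            )
        )
    if not records:
        raise ValueError(f"{path}: no parsable data rows")
    coll = create_collection(records)
    report = ParseReport(
        file_path=str(path),
        dialect="GREAT",
        rows_read=rows_read,
        sets_created=len(coll),
        rows_skipped=rows_read - len(coll),
        skip_reasons=tuple(skipped),
    )
    if categories is not None:
        coll = manage_gene_sets(coll, keep_categories=categories)
    return coll, report


# ---------------------------------------------------------------------------
# Pipeline output writers / round-trip readers
# ---------------------------------------------------------------------------

def _fmt(x: object) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_similarity_matrix(matrix: SimilarityMatrix, path: "str | Path") -> Path:
    """Square TSV with set_id row/column headers; float cells printed with
    full (repr) precision, preceded by '#'-metadata lines."""
    path = Path(path)
    lines = [f"# metric={matrix.metric.value}"]
    if matrix.cap_applied is not None:
        lines.append(f"# cap_applied={_fmt(matrix.cap_applied)}")
    lines.append(f"# infinite_replaced={matrix.infinite_replaced}")
    lines.append("\t".join(["set_id", *matrix.set_ids]))
    for sid, row in zip(matrix.set_ids, matrix.scores):
        lines.append("\t".join([sid, *(repr(float(v)) for v in row)]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_similarity_matrix(path: "str | Path") -> SimilarityMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        elif line.strip():
            rows.append(line.split("\t"))
    ids = tuple(rows[0][1:])
    scores = np.array([[float(c) for c in r[1:]] for r in rows[1:]])
    cap = meta.get("cap_applied")
    return SimilarityMatrix(
        set_ids=ids,
        scores=scores,
        metric=Metric(meta.get("metric", "CUSTOM")),
        cap_applied=float(cap) if cap else None,
        infinite_replaced=int(meta.get("infinite_replaced", 0)),
    )


def write_clustering(clustering: ClusteringResult, path: "str | Path") -> Path:
    path = Path(path)
    lines = [
        f"# method={clustering.method.value}",
        f"# k={clustering.k}",
        f"# seed={clustering.seed}",
        "set_id\tcluster\thighlight_score",
    ]
    hs = clustering.highlight_scores or (None,) * len(clustering.set_ids)
    for sid, lab, h in zip(clustering.set_ids, clustering.labels, hs):
        lines.append(f"{sid}\t{lab}\t{_fmt(h)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_clustering(path: "str | Path") -> ClusteringResult:
    from .cluster import ClusterMethod

    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        elif line.strip():
            rows.append(line.split("\t"))
    body = rows[1:]
    hs = [r[2] if len(r) > 2 else "" for r in body]
    return ClusteringResult(
        set_ids=tuple(r[0] for r in body),
        labels=tuple(int(r[1]) for r in body),
        method=ClusterMethod(meta.get("method", "CUSTOM")),
        k=int(meta["k"]),
        seed=int(meta.get("seed", 0)),
        highlight_scores=tuple(float(h) for h in hs) if all(hs) else None,
    )


def write_outputs(
    collection: GeneSetCollection,
    similarity: Optional[SimilarityMatrix],
    clustering: Optional[ClusteringResult],
    out_dir: "str | Path",
) -> list[Path]:
    """Export the pipeline state: gene-set table, similarity matrix,
    per-cluster summary and harmonized GMT.

    All provided inputs must refer to the same set_ids in the same order
    (mismatch is a hard error, never a silent realignment).  With no
    clustering yet, the gene-set table is written with a blank cluster column
    and the cluster summary is skipped with a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = collection.set_ids
    if similarity is not None and similarity.set_ids != ids:
        raise ValueError("similarity matrix set_ids do not match the collection (order matters)")
    if clustering is not None and clustering.set_ids != ids:
        raise ValueError("clustering set_ids do not match the collection (order matters)")

    paths: list[Path] = []

    gs_path = out_dir / "gene_sets.tsv"
    header = "set_id\tname\texperiment\ttool\tcategory\tpvalue\tcluster\thighlight_score\tgenes"
    lines = [header]
    labels = clustering.labels if clustering is not None else (None,) * len(ids)
    hs = (
        clustering.highlight_scores
        if clustering is not None and clustering.highlight_scores is not None
        else (None,) * len(ids)
    )
    for gs, lab, h in zip(collection.gene_sets, labels, hs):
        lines.append(
            "\t".join(
                [
                    gs.set_id, gs.name, gs.experiment, gs.source_tool.value,
                    gs.category or "", _fmt(gs.pvalue), _fmt(lab), _fmt(h),
                    ";".join(gs.genes),
                ]
            )
        )
    gs_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths.append(gs_path)

    if similarity is not None:
        paths.append(write_similarity_matrix(similarity, out_dir / "similarity_matrix.tsv"))
    else:
        logger.warning("no similarity matrix; matrix TSV skipped")

    if clustering is not None:
        cl_path = out_dir / "cluster_summary.tsv"
        lines = ["cluster\tn_sets\tshared_genes\tunique_genes\tmean_highlight"]
        for lab in range(1, clustering.k + 1):
            summ = clustering.cluster_summaries.get(lab)
            if summ is None:
                members = clustering.members(lab)
                lines.append(f"{lab}\t{len(members)}\t\t\t")
            else:
                lines.append(
                    "\t".join(
                        [
                            str(lab), str(summ.n_sets), ";".join(summ.shared_genes),
                            ";".join(summ.unique_genes), _fmt(summ.mean_highlight),
                        ]
                    )
                )
        cl_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths.append(cl_path)
    else:
        logger.warning("no clustering yet; cluster summary TSV skipped")

    paths.append(write_gmt(collection, out_dir / "gene_sets.gmt"))
    return paths
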