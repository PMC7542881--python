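"""In-memory model for gene-set collections.

A :class:`GeneSet` is one named set of harmonized gene identifiers together
with its provenance (tool, experiment, species, p-value).  A
:class:`GeneSetCollection` is an ordered list of gene-sets plus the gene
*universe* — the pool of unique genes across all member sets (or an explicit
user-supplied background) that serves as the denominator population ``N`` for
the overlap statistics.

Collections are treated as immutable values: every operation returns a new
collection and appends exactly one record to its processing log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger("gsclust")


class SourceTool(str, Enum):
    """Origin of a gene-set: which analysis tool produced it."""

    IPA = "IPA"
    GREAT = "GREAT"
    GMT = "GMT"
    GENERIC = "GENERIC"


def _coerce_tool(tool: "SourceTool | str") -> SourceTool:
    if isinstance(tool, SourceTool):
        return tool
    return SourceTool(str(tool).upper())


def clean_gene_tokens(tokens: Iterable[str]) -> tuple[str, ...]:
    """Strip, uppercase and de-duplicate gene tokens, preserving order.

    Case is the most common symbol inconsistency between tools, so all gene
    identifiers are uppercased at ingest; empty tokens are dropped.
    """
    seen: dict[str, None] = {}
    for tok in tokens:
        t = str(tok).strip().upper()
        if t:
            seen.setdefault(t, None)
    return tuple(seen)


@dataclass(frozen=True)
class GeneSet:
    """One named gene-set with provenance.

    ``genes`` holds the harmonized identifiers (unique, uppercase, ordered);
    ``raw_genes`` the original tokens as read from the source file.  ``|genes|``
    is the quantity P_i used by the similarity metrics.
    """

    set_id: str
    name: str
    genes: tuple[str, ...]
    source_tool: SourceTool = SourceTool.GENERIC
    experiment: str = ""
    species: str = ""
    category: Optional[str] = None
    pvalue: Optional[float] = None
    raw_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in set {self.set_id!r}")
        if any(not g for g in self.genes):
            raise ValueError(f"empty gene token in set {self.set_id!r}")
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(
                f"pvalue {self.pvalue!r} of set {self.set_id!r} outside [0, 1]"
            )

    @property
    def size(self) -> int:
        return len(self.genes)

    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class LogRecord:
    """One processing step: operation name, parameters, and counts."""

    operation: str
    params: Mapping[str, object] = field(default_factory=dict)
    counts: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered gene-sets plus gene universe and an append-only processing log."""

    gene_sets: tuple[GeneSet, ...]
    universe_override: Optional[frozenset[str]] = None
    log: tuple[LogRecord, ...] = ()

    def __post_init__(self) -> None:
        ids = [gs.set_id for gs in self.gene_sets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set_ids in collection: {dupes}")

    @property
    def universe(self) -> frozenset[str]:
        """All unique gene IDs across member sets, or the explicit override."""
        if self.universe_override is not None:
            return self.universe_override
        u: set[str] = set()
        for gs in self.gene_sets:
            u.update(gs.genes)
        return frozenset(u)

    @property
    def set_ids(self) -> tuple[str, ...]:
        return tuple(gs.set_id for gs in self.gene_sets)

    def __len__(self) -> int:
        return len(self.gene_sets)

    def __iter__(self):
        return iter(self.gene_sets)

    def __getitem__(self, key: "int | str") -> GeneSet:
        if isinstance(key, str):
            for gs in self.gene_sets:
                if gs.set_id == key:
                    return gs
            raise KeyError(key)
        return self.gene_sets[key]

    def with_log(self, record: LogRecord) -> "GeneSetCollection":
        return replace(self, log=self.log + (record,))


def _assign_set_ids(
    keys: Sequence[tuple[str, str, str]],
) -> list[str]:
    """Deterministic ``<experiment>::<tool>::<name>`` ids with numeric
    suffixes (``::1``, ``::2``, ...) on every member of a colliding group."""
    bases = [f"{exp}::{tool}::{name}" for exp, tool, name in keys]
    total = {b: bases.count(b) for b in bases}
    counter: dict[str, int] = {}
    out = []
    for b in bases:
        if total[b] > 1:
            counter[b] = counter.get(b, 0) + 1
            out.append(f"{b}::{counter[b]}")
        else:
            out.append(b)
    return out


def create_collection(
    records: Sequence[Mapping[str, object]],
    *,
    universe_override: Optional[Iterable[str]] = None,
) -> GeneSetCollection:
    """Build a collection from generic per-set records (the object-creator path
    for results of any gene-set analysis tool).

    Each record is a mapping with keys ``name`` and ``genes`` (required) and
    optionally ``experiment``, ``source_tool``, ``species``, ``category``,
    ``pvalue``.  Records whose gene list is empty after token cleaning are
    warned about and dropped; an entirely empty input is an error.
    """
    if not records:
        raise ValueError("empty input: no gene-set records supplied")

    kept: list[dict] = []
    for i, rec in enumerate(records):
        name = str(rec.get("name", "")).strip()
        if not name:
            raise ValueError(f"record {i} has an empty name")
        genes = clean_gene_tokens(rec.get("genes", ()))
        if not genes:
            logger.warning("record %d (%r): no genes after cleaning; dropped", i, name)
            continue
        kept.append(
            dict(
                name=name,
                genes=genes,
                raw_genes=tuple(str(g) for g in rec.get("genes", ())),
                experiment=str(rec.get("experiment", "")),
                source_tool=_coerce_tool(rec.get("source_tool", SourceTool.GENERIC)),
                species=str(rec.get("species", "")),
                category=rec.get("category"),
                pvalue=rec.get("pvalue"),
            )
        )
    if not kept:
        raise ValueError("empty input: all records had zero genes")

    ids = _assign_set_ids(
        [(r["experiment"], r["source_tool"].value, r["name"]) for r in kept]
    )
    gene_sets = tuple(GeneSet(set_id=sid, **r) for sid, r in zip(ids, kept))
    rec = LogRecord(
        "create_collection",
        counts={
            "records_in": len(records),
            "sets_created": len(gene_sets),
            "records_dropped": len(records) - len(kept),
        },
    )
    coll = GeneSetCollection(
        gene_sets,
        universe_override=(
            frozenset(clean_gene_tokens(universe_override))
            if universe_override is not None
            else None
        ),
    )
    return coll.with_log(rec)


def merge_collections(
    collections: Sequence[GeneSetCollection],
) -> GeneSetCollection:
    """Concatenate several collections into one, preserving order and
    provenance.  set_id collisions across collections are resolved by
    prefixing the colliding set's collection index (never silently
    overwritten); the universe is recomputed as the union of member universes.
    """
    if len(collections) < 2:
        raise ValueError("merge requires at least two collections")
    seen: set[str] = set()
    merged: list[GeneSet] = []
    n_prefixed = 0
    for idx, coll in enumerate(collections):
        for gs in coll.gene_sets:
            sid = gs.set_id
            if sid in seen:
                sid = f"{idx}::{sid}"
                n_prefixed += 1
                while sid in seen:  # pathological repeat collisions
                    sid = f"{idx}::{sid}"
            seen.add(sid)
            merged.append(replace(gs, set_id=sid))
    override: Optional[frozenset[str]] = None
    if any(c.universe_override is not None for c in collections):
        u: set[str] = set()
        for c in collections:
            u.update(c.universe)
        override = frozenset(u)
    logs: tuple[LogRecord, ...] = ()
    for c in collections:
        logs = logs + c.log
    rec = LogRecord(
        "merge_collections",
        params={"n_collections": len(collections)},
        counts={"sets_total": len(merged), "ids_prefixed": n_prefixed},
    )
    return GeneSetCollection(tuple(merged), universe_override=override, log=logs).with_log(rec)


def manage_gene_sets(
    collection: GeneSetCollection,
    *,
    keep_categories: Optional[Sequence[str]] = None,
    drop_categories: Optional[Sequence[str]] = None,
    min_size: int = 1,
    max_size: int = int(1e9),
) -> GeneSetCollection:
    """Filter a collection by category and set size.

    At most one of ``keep_categories`` / ``drop_categories`` may be given.
    Returns a new collection (the input is never mutated); the universe is
    recomputed from the surviving sets.  A filter that removes every set is an
    error naming the responsible rule, not an empty result.
    """
    if keep_categories is not None and drop_categories is not None:
        raise ValueError("supply at most one of keep_categories/drop_categories")
    if not (1 <= min_size <= max_size):
        raise ValueError(f"require 1 <= min_size <= max_size, got [{min_size}, {max_size}]")

    removed_by_category = 0
    removed_by_size = 0
    kept: list[GeneSet] = []
    for gs in collection.gene_sets:
        if keep_categories is not None and gs.category not in set(keep_categories):
            removed_by_category += 1
            continue
        if drop_categories is not None and gs.category in set(drop_categories):
            removed_by_category += 1
            continue
        if not (min_size <= gs.size <= max_size):
            removed_by_size += 1
            continue
        kept.append(gs)
    if not kept:
        if removed_by_category and keep_categories is not None:
            rule = f"keep_categories={list(keep_categories)!r}"
        elif removed_by_category:
            rule = f"drop_categories={list(drop_categories)!r}"
        else:
            rule = f"size filter [{min_size}, {max_size}]"
        raise ValueError(f"empty collection after filtering (rule: {rule})")
    rec = LogRecord(
        "manage_gene_sets",
        params={
            "keep_categories": list(keep_categories) if keep_categories is not None else None,
            "drop_categories": list(drop_categories) if drop_categories is not None else None,
            "min_size": min_size,
            "max_size": max_size if max_size < int(1e9) else math.inf,
        },
        counts={
            "removed_by_category": removed_by_category,
            "removed_by_size": removed_by_size,
            "sets_kept": len(kept),
        },
    )
    return GeneSetCollection(
        tuple(kept), universe_override=collection.universe_override, log=collection.log
    ).with_log(rec)
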