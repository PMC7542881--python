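"""Gene-identifier harmonization.

Gene-set results from different tools, annotations or species use different
identifier vocabularies (mouse symbols, Ensembl IDs, human symbols...).
Before overlap statistics are meaningful, all collections must speak one
vocabulary.  Translation is driven by a user-supplied :class:`MappingTable`
of (source_id, source_namespace, species) -> target_symbol records — a
deterministic, offline equivalent of an ID-conversion service.

Because gene tokens are uppercased at ingest, mapping lookups are
case-insensitive on the source side.  A token that already equals a known
target symbol for its species is considered harmonized (mapped to itself);
this makes :func:`harmonize` idempotent under either unmapped policy.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .model import GeneSet, GeneSetCollection, LogRecord

logger = logging.getLogger("gsclust")


@dataclass(frozen=True)
class MappingTable:
    """Identifier translation records.

    ``records`` maps (SOURCE_ID, NAMESPACE, SPECIES) — all uppercased — to a
    tuple of target symbols (one-to-many mappings keep all targets).
    Duplicate keys with conflicting targets are a load-time error.
    """

    records: Mapping[tuple[str, str, str], tuple[str, ...]]
    provenance: str = ""

    @property
    def namespaces(self) -> frozenset[str]:
        return frozenset(ns for (_, ns, _) in self.records)

    @property
    def target_symbols_by_species(self) -> Mapping[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for (_, _, sp), targets in self.records.items():
            out.setdefault(sp, set()).update(targets)
        return {sp: frozenset(v) for sp, v in out.items()}

    @classmethod
    def from_records(
        cls,
        rows: Sequence[tuple[str, str, str, str]],
        provenance: str = "",
    ) -> "MappingTable":
        recs: dict[tuple[str, str, str], tuple[str, ...]] = {}
        for src, ns, sp, tgt in rows:
            tgt = tgt.strip().upper()
            if not tgt:
                raise ValueError(f"empty target symbol for source {src!r}")
            key = (src.strip().upper(), ns.strip().upper(), sp.strip().upper())
            if key in recs:
                if tgt not in recs[key]:
                    recs[key] = recs[key] + (tgt,)  # one-to-many: keep all targets
            else:
                recs[key] = (tgt,)
        return cls(records=recs, provenance=provenance)

    @classmethod
    def from_tsv(cls, path: "str | Path") -> "MappingTable":
        """Read a 4-column TSV: source_id, source_namespace, species,
        target_symbol (header optional, detected by column names)."""
        path = Path(path)
        rows: list[tuple[str, str, str, str]] = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for i, row in enumerate(reader):
                if not row or all(not c.strip() for c in row):
                    continue
                if i == 0 and row[0].strip().lower() in {"source_id", "source"}:
                    continue
                if len(row) < 4:
                    raise ValueError(f"{path}: line {i + 1} has {len(row)} columns, need 4")
                rows.append((row[0], row[1], row[2], row[3]))
        return cls.from_records(rows, provenance=str(path))


@dataclass(frozen=True)
class SetHarmonization:
    set_id: str
    mapped: int
    unmapped: int
    collapsed: int  # tokens lost to many-to-one duplicate collapse
    expanded: int  # extra tokens gained from one-to-many mappings


@dataclass(frozen=True)
class HarmonizationReport:
    per_set: tuple[SetHarmonization, ...]
    sets_removed: tuple[str, ...] = ()
    high_unmapped_flag: bool = False

    @property
    def total_mapped(self) -> int:
        return sum(s.mapped for s in self.per_set)

    @property
    def total_unmapped(self) -> int:
        return sum(s.unmapped for s in self.per_set)


def harmonize(
    collection: GeneSetCollection,
    mapping: MappingTable,
    source_namespace: str,
    unmapped_policy: str = "keep",
) -> tuple[GeneSetCollection, HarmonizationReport]:
    """Translate every gene token through the mapping table.

    Unmapped tokens are kept verbatim (default) or dropped, per
    ``unmapped_policy``; duplicates arising from many-to-one mappings are
    collapsed; one-to-many mappings expand to all targets.  Sets emptied by
    the translation are removed with a warning.  If more than half of all
    tokens are unmapped the report carries a prominent flag.
    """
    ns = source_namespace.strip().upper()
    if ns not in mapping.namespaces:
        raise ValueError(
            f"namespace {source_namespace!r} absent from mapping table "
            f"(available: {sorted(mapping.namespaces)})"
        )
    if unmapped_policy not in ("drop", "keep"):
        raise ValueError(f"unmapped_policy must be 'drop' or 'keep', got {unmapped_policy!r}")

    targets_by_sp = mapping.target_symbols_by_species
    new_sets: list[GeneSet] = []
    per_set: list[SetHarmonization] = []
    removed: list[str] = []
    for gs in collection.gene_sets:
        sp = gs.species.strip().upper()
        out: dict[str, None] = {}
        mapped = unmapped = expanded = 0
        for tok in gs.genes:
            key = (tok, ns, sp)
            if key in mapping.records:
                tgts = mapping.records[key]
                mapped += 1
                expanded += len(tgts) - 1
                for t in tgts:
                    out.setdefault(t, None)
            elif tok in targets_by_sp.get(sp, frozenset()):
                mapped += 1  # already in target vocabulary: idempotent pass-through
                out.setdefault(tok, None)
            else:
                unmapped += 1
                if unmapped_policy == "keep":
                    out.setdefault(tok, None)
        collapsed = mapped + expanded + (unmapped if unmapped_policy == "keep" else 0) - len(out)
        per_set.append(
            SetHarmonization(gs.set_id, mapped=mapped, unmapped=unmapped,
                             collapsed=collapsed, expanded=expanded)
        )
        if out:
            new_sets.append(replace(gs, genes=tuple(out)))
        else:
            removed.append(gs.set_id)
            logger.warning("gene-set %s emptied by harmonization; removed", gs.set_id)

    total = sum(s.mapped + s.unmapped for s in per_set)
    flag = total > 0 and sum(s.unmapped for s in per_set) / total > 0.5
    if flag:
        logger.warning(
            "more than 50%% of gene tokens were unmapped (%d of %d)",
            sum(s.unmapped for s in per_set), total,
        )
    report = HarmonizationReport(
        per_set=tuple(per_set), sets_removed=tuple(removed), high_unmapped_flag=flag
    )
    rec = LogRecord(
        "harmonize",
        params={"namespace": ns, "unmapped_policy": unmapped_policy},
        counts={
            "mapped": report.total_mapped,
            "unmapped": report.total_unmapped,
            "sets_removed": len(removed),
        },
    )
    out_coll = GeneSetCollection(
        tuple(new_sets),
        universe_override=collection.universe_override,
        log=collection.log,
    ).with_log(rec)
    return out_coll, report


@dataclass(frozen=True)
class MergedDuplicate:
    kept_set_id: str
    kept_name: str
    alias_names: tuple[str, ...]
    alias_set_ids: tuple[str, ...]


def reduce_redundancy(
    collection: GeneSetCollection,
) -> tuple[GeneSetCollection, tuple[MergedDuplicate, ...]]:
    """Collapse gene-sets with identical gene content *within* one
    (experiment, tool) pair, keeping the lexicographically smallest name and
    recording the aliases.  Identical content across experiments is kept —
    cross-experiment comparison is the point of merging.
    """
    groups: dict[tuple[str, str, frozenset[str]], list[GeneSet]] = {}
    order: list[tuple[str, str, frozenset[str]]] = []
    for gs in collection.gene_sets:
        key = (gs.experiment, gs.source_tool.value, gs.gene_set())
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(gs)

    kept_sets: list[GeneSet] = []
    merged: list[MergedDuplicate] = []
    for key in order:
        members = groups[key]
        if len(members) == 1:
            kept_sets.append(members[0])
            continue
        best = min(members, key=lambda g: g.name)
        aliases = [g for g in members if g is not best]
        kept_sets.append(best)
        merged.append(
            MergedDuplicate(
                kept_set_id=best.set_id,
                kept_name=best.name,
                alias_names=tuple(g.name for g in aliases),
                alias_set_ids=tuple(g.set_id for g in aliases),
            )
        )
    rec = LogRecord(
        "reduce_redundancy",
        counts={"sets_in": len(collection), "sets_out": len(kept_sets),
                "duplicates_merged": len(collection) - len(kept_sets)},
    )
    out = GeneSetCollection(
        tuple(kept_sets),
        universe_override=collection.universe_override,
        log=collection.log,
    ).with_log(rec)
    return out, tuple(merged)
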