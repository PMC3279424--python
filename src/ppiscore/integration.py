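"""Identifier mapping and cross-source merging.

Source records arrive in heterogeneous namespaces; every endpoint is mapped
to its canonical protein representative (splice forms are not considered)
plus at least one gene identifier. Records whose endpoints cannot be mapped
are dropped, genetic-interaction records are excluded, and the remaining
records are collapsed so that each unordered canonical pair appears once,
with evidence (studies, techniques, sources, interaction types) unioned
across everything reported for it.

Ortholog evidence — a human pair whose orthologs were observed to interact
in a non-human species — only ever boosts an interaction that already has
human experimental support; ortholog-only pairs are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .io_formats import normalize_technique
from .model import (
    DEFAULT_ORTHOLOG_SPECIES,
    EvidenceBundle,
    Interaction,
    SourceRecord,
    canonical_pair,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DropNotice:
    """Why a record was excluded; drops are data, not errors."""

    record: SourceRecord
    reason: str


@dataclass(frozen=True)
class OrthologRecord:
    """Interaction between orthologs of a canonical human pair in one species."""

    protein_a: str
    protein_b: str
    species: str

    @property
    def key(self) -> tuple[str, str]:
        return canonical_pair(self.protein_a, self.protein_b)


class IdMappingTable:
    """(namespace, source id) -> (canonical protein id, gene ids).

    Every canonical protein maps to at least one gene; a protein encoded by
    duplicated genomic loci maps to several. Lookups fall back to the empty
    namespace so bare identifiers resolve too.
    """

    def __init__(
        self,
        entries: dict[tuple[str, str], tuple[str, frozenset[str]]],
    ):
        if not entries:
            raise ConfigurationError("empty identifier mapping table")
        for (ns, sid), (prot, genes) in entries.items():
            if not genes:
                raise ConfigurationError(
                    f"canonical protein {prot} ({ns}:{sid}) has no gene identifier"
                )
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, raw_id: str) -> Optional[tuple[str, frozenset[str]]]:
        ns, _, sid = raw_id.rpartition(":")
        for key in ((ns, sid), ("", raw_id)):
            if key in self.entries:
                return self.entries[key]
        return None


def load_id_mapping(path: PathLike) -> IdMappingTable:
    """Read a mapping table: namespace <TAB> source_id <TAB> canonical protein
    <TAB> comma-separated gene ids. Namespace may be empty."""
    entries: dict[tuple[str, str], tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ConfigurationError(
                    f"line {lineno}: expected 4 columns, got {len(cols)}"
                )
            ns, sid, prot, genes = (c.strip() for c in cols)
            entries[(ns, sid)] = (
                prot,
                frozenset(g.strip() for g in genes.split(",") if g.strip()),
            )
    return IdMappingTable(entries)


def load_ortholog_records(path: PathLike) -> list[OrthologRecord]:
    """Read ortholog evidence: protein_a <TAB> protein_b <TAB> species."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ConfigurationError(
                    f"line {lineno}: expected 3 columns, got {len(cols)}"
                )
            out.append(OrthologRecord(cols[0].strip(), cols[1].strip(), cols[2].strip()))
    return out


def map_record(
    rec: SourceRecord, table: IdMappingTable
) -> Union[Interaction, DropNotice]:
    """Map one record's endpoints to canonical identifiers.

    Gene combinations are the full cross-product of the two endpoints' gene
    sets, aligned to the canonical (sorted) pair order. An unmappable
    endpoint yields a :class:`DropNotice` instead of an interaction.
    """
    hit_a = table.lookup(rec.raw_id_a)
    hit_b = table.lookup(rec.raw_id_b)
    if hit_a is None or hit_b is None:
        missing = [
            raw
            for raw, hit in ((rec.raw_id_a, hit_a), (rec.raw_id_b, hit_b))
            if hit is None
        ]
        return DropNotice(rec, f"unmappable endpoint(s): {', '.join(missing)}")
    (prot_a, genes_a), (prot_b, genes_b) = hit_a, hit_b
    key = canonical_pair(prot_a, prot_b)
    if key == (prot_a, prot_b):
        first, second = genes_a, genes_b
    else:
        first, second = genes_b, genes_a
    if key[0] == key[1]:  # self-interaction: combinations are unordered
        combos = {tuple(sorted((ga, gb))) for ga in first for gb in second}
    else:
        combos = {(ga, gb) for ga in first for gb in second}
    ev = EvidenceBundle()
    ev.add_record(
        rec.pubmed_ids,
        (normalize_technique(name) for name, _ in rec.techniques),
        rec.source_name,
        rec.interaction_types,
    )
    return Interaction(key=key, gene_combinations=set(combos), evidence=ev)


@dataclass
class MergeResult:
    """Outcome of :func:`merge_sources`.

    ``interactions`` is the merged, deterministically ordered network;
    ``drops`` the per-record exclusions; the counters summarize why input
    records did not surface as distinct interactions.
    """

    interactions: list[Interaction] = field(default_factory=list)
    drops: list[DropNotice] = field(default_factory=list)
    n_genetic_excluded: int = 0
    n_records_in: int = 0
    n_ortholog_only_discarded: int = 0


def merge_sources(
    datasets: Sequence[Sequence[SourceRecord]],
    ortholog_records: Iterable[OrthologRecord] = (),
    table: Optional[IdMappingTable] = None,
    species: Sequence[str] = DEFAULT_ORTHOLOG_SPECIES,
) -> MergeResult:
    """Integrate source datasets into one non-redundant interaction list.

    Genetic records are excluded before merging; identical canonical pairs
    collapse into one interaction with unioned evidence; ortholog evidence
    attaches only to pairs that already exist from human experimental
    records. Output order is deterministic (sorted canonical keys), and the
    operation is idempotent and independent of dataset order.
    """
    if table is None:
        raise ConfigurationError("an identifier mapping table is required")
    species_set = set(species)
    result = MergeResult()
    by_key: dict[tuple[str, str], Interaction] = {}
    for dataset in datasets:
        for rec in dataset:
            result.n_records_in += 1
            if rec.is_genetic:
                result.n_genetic_excluded += 1
                continue
            mapped = map_record(rec, table)
            if isinstance(mapped, DropNotice):
                result.drops.append(mapped)
                continue
            existing = by_key.get(mapped.key)
            if existing is None:
                by_key[mapped.key] = mapped
            else:
                existing.gene_combinations |= mapped.gene_combinations
                ev, new = existing.evidence, mapped.evidence
                ev.studies |= new.studies
                ev.techniques |= new.techniques
                ev.sources |= new.sources
                ev.interaction_types |= new.interaction_types
                for study, techs in new.techniques_by_study.items():
                    ev.techniques_by_study.setdefault(study, set()).update(techs)
    ortho_seen: set[tuple[tuple[str, str], str]] = set()
    for orec in ortholog_records:
        if orec.species not in species_set:
            raise ValueError(
                f"ortholog species {orec.species!r} not in the configured list"
            )
        if (orec.key, orec.species) in ortho_seen:
            continue
        ortho_seen.add((orec.key, orec.species))
        target = by_key.get(orec.key)
        if target is None:
            # non-human evidence never creates an interaction on its own
            result.n_ortholog_only_discarded += 1
            continue
        target.evidence.organisms.add(orec.species)
    result.interactions = [by_key[k] for k in sorted(by_key)]
    return result
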