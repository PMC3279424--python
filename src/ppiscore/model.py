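"""Core domain types shared across the package.

The unit of analysis is an experimentally observed human protein-protein
interaction (PPI), keyed by a canonical unordered protein pair and carrying
an evidence bundle: the studies (PubMed ids) that reported it, the detection
techniques used, the source datasets it came from, and the non-human species
in which orthologs of the pair were seen to interact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

#: Non-human species whose ortholog interactions may boost (never create) a
#: human PPI's confidence score. User-extensible via the ``species`` argument
#: of :func:`ppiscore.integration.merge_sources`.
DEFAULT_ORTHOLOG_SPECIES: tuple[str, ...] = (
    "Bos taurus",
    "Caenorhabditis elegans",
    "Canis familiaris",
    "Drosophila melanogaster",
    "Gallus gallus",
    "Mus musculus",
    "Rattus norvegicus",
    "Saccharomyces cerevisiae",
    "Sus scrofa",
)

#: PSI-MI interaction-type code conventionally flagging a genetic
#: interaction; carried as the boolean ``is_genetic`` rather than as a type.
GENETIC_INTERACTION_TYPE = "MI:0208"

PairKey = tuple[str, str]


def canonical_pair(a: str, b: str) -> PairKey:
    """Order-independent key for a protein pair: (A,B) == (B,A)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class SourceRecord:
    """One interaction record as reported by a source dataset.

    Identifiers are still in the source namespace; mapping to canonical
    protein/gene identifiers happens in :mod:`ppiscore.integration`.
    """

    raw_id_a: str
    raw_id_b: str
    pubmed_ids: frozenset[int] = frozenset()
    #: (method name, optional PSI-MI code such as "MI:0018")
    techniques: frozenset[tuple[str, Optional[str]]] = frozenset()
    interaction_types: frozenset[str] = frozenset()
    source_name: str = ""
    is_genetic: bool = False

    def __post_init__(self) -> None:
        self.pubmed_ids = frozenset(int(p) for p in self.pubmed_ids)
        self.techniques = frozenset(self.techniques)
        if GENETIC_INTERACTION_TYPE in self.interaction_types:
            self.is_genetic = True
            self.interaction_types = (
                frozenset(self.interaction_types) - {GENETIC_INTERACTION_TYPE}
            )
        else:
            self.interaction_types = frozenset(self.interaction_types)


@dataclass
class EvidenceBundle:
    """All evidence accumulated for one canonical interaction.

    ``techniques_by_study`` keeps per-study technique provenance so that a
    leave-one-study-out evaluation can remove exactly the evidence a study
    contributed; techniques from records without a PubMed id are keyed under
    ``None`` and are never removed by a holdout. The flat ``techniques`` set
    is always the union over the provenance map.
    """

    studies: set[int] = field(default_factory=set)
    techniques: set[str] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)
    organisms: set[str] = field(default_factory=set)
    interaction_types: set[str] = field(default_factory=set)
    techniques_by_study: dict[Optional[int], set[str]] = field(default_factory=dict)

    def add_record(self, pmids: Iterable[int], techniques: Iterable[str],
                   source: str, interaction_types: Iterable[str] = ()) -> None:
        pmids = set(pmids)
        techniques = set(techniques)
        self.studies |= pmids
        self.techniques |= techniques
        if source:
            self.sources.add(source)
        self.interaction_types |= set(interaction_types)
        for key in (pmids or {None}):
            self.techniques_by_study.setdefault(key, set()).update(techniques)

    def without_study(self, study: int) -> Optional["EvidenceBundle"]:
        """Evidence remaining after removing one study's contribution.

        Returns ``None`` when nothing experimental remains (the interaction
        drops out of the reduced dataset entirely).
        """
        if study not in self.studies:
            return self
        studies = self.studies - {study}
        prov = {k: set(v) for k, v in self.techniques_by_study.items() if k != study}
        techniques: set[str] = set()
        for v in prov.values():
            techniques |= v
        if not studies and not techniques:
            return None
        return EvidenceBundle(
            studies=studies,
            techniques=techniques,
            sources=set(self.sources),
            organisms=set(self.organisms),
            interaction_types=set(self.interaction_types),
            techniques_by_study=prov,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceBundle):
            return NotImplemented
        return (
            self.studies == other.studies
            and self.techniques == other.techniques
            and self.sources == other.sources
            and self.organisms == other.organisms
            and self.interaction_types == other.interaction_types
        )


@dataclass
class Interaction:
    """A canonical, merged interaction: unordered protein pair + evidence.

    ``gene_combinations`` holds (gene of key[0], gene of key[1]) tuples, one
    per cross-combination of the endpoints' gene sets; duplicated genomic
    loci make this set larger than one.
    """

    key: PairKey
    gene_combinations: set[tuple[str, str]] = field(default_factory=set)
    evidence: EvidenceBundle = field(default_factory=EvidenceBundle)

    def __post_init__(self) -> None:
        if self.key != canonical_pair(*self.key):
            raise ValueError(f"interaction key not canonical: {self.key}")

    @property
    def is_self(self) -> bool:
        return self.key[0] == self.key[1]


@dataclass
class ScoredInteraction:
    interaction: Interaction
    score: float

    @property
    def key(self) -> PairKey:
        return self.interaction.key

    @property
    def evidence(self) -> EvidenceBundle:
        return self.interaction.evidence


@dataclass
class ScoredNetwork:
    """A set of scored interactions, each with full precision score in [0, 1)."""

    interactions: list[ScoredInteraction] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self) -> Iterator[ScoredInteraction]:
        return iter(self.interactions)

    def scores(self) -> list[float]:
        return [si.score for si in self.interactions]

    def by_pair(self) -> dict[PairKey, ScoredInteraction]:
        return {si.key: si for si in self.interactions}

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for si in self.interactions:
            out.update(si.key)
        return out

    def sorted(self) -> "ScoredNetwork":
        return ScoredNetwork(sorted(self.interactions, key=lambda si: si.key))


@dataclass(frozen=True, slots=True)
class ScoringParams:
    """The six free parameters of the confidence score.

    a_s, a_o, a_t control how fast the study / ortholog-organism / technique
    subscores saturate toward 1; w_s, w_o, w_t weight the three subscores and
    must sum to 1.
    """

    a_s: float
    a_o: float
    a_t: float
    w_s: float
    w_o: float
    w_t: float

    def __post_init__(self) -> None:
        if min(self.a_s, self.a_o, self.a_t) < 0:
            raise ValueError("saturation constants must be >= 0")
        if not all(0.0 <= w <= 1.0 for w in (self.w_s, self.w_o, self.w_t)):
            raise ValueError("weights must lie in [0, 1]")
        if not math.isclose(self.w_s + self.w_o + self.w_t, 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a_s, self.a_o, self.a_t, self.w_s, self.w_o, self.w_t)


#: Parameter set selected by the grid search on the original reference data;
#: shipped as the package default.
DEFAULT_PARAMS = ScoringParams(a_s=2.3, a_o=1.6, a_t=0.2, w_s=0.6, w_o=0.1, w_t=0.3)


@dataclass(frozen=True)
class EvidenceCounts:
    """The three evidence quantities the subscores saturate over."""

    n_studies: int
    n_organisms: int
    technique_mass: float

    def __post_init__(self) -> None:
        if self.n_studies < 0 or self.n_organisms < 0 or self.technique_mass < 0:
            raise ValueError("evidence counts must be non-negative")
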