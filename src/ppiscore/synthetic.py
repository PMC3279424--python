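"""Synthetic fixture generation with known ground truth.

Everything the pipeline consumes can be generated here: source datasets
with controlled evidence structure (per-pair study multiplicities, weighted
technique sampling, genetic-record and unmappable-endpoint contamination),
an identifier-mapping table with gene-ambiguous proteins, ortholog evidence
(including ortholog-only pairs that must be discarded), and bait-based
screens with planted score-stratified recall. A ground-truth ledger records
exactly what integration and scoring should recompute from the files.

The generator emulates the statistical structure the scoring model assumes
— most PPIs reported once, a reproducible multi-study minority, technique
diversity growing slowly with study count, sparse cross-species support —
not interactome topology: degree distributions are uniform-random.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .evaluation import ExternalScreen
from .integration import IdMappingTable, OrthologRecord
from .io_formats import normalize_technique
from .model import (
    DEFAULT_ORTHOLOG_SPECIES,
    PairKey,
    ScoredNetwork,
    SourceRecord,
    canonical_pair,
)

PathLike = Union[str, Path]

#: Synthetic study ids start here — far above any real PubMed id, so fixture
#: studies can never be conflated with real literature.
STUDY_ID_BASE = 900_000_000

#: (method name, PSI-MI code, sampling weight). Mostly mid-reliability
#: affinity/complementation methods with a thin tail of structure-grade
#: evidence, echoing how often each technique class occurs in curated PPI
#: databases.
DEFAULT_TECHNIQUE_POOL: tuple[tuple[str, Optional[str], float], ...] = (
    ("two hybrid", "MI:0018", 30.0),
    ("anti bait coimmunoprecipitation", "MI:0006", 15.0),
    ("tandem affinity purification", "MI:0676", 15.0),
    ("in vivo", "MI:0493", 12.0),
    ("gst pull down", "MI:0059", 10.0),
    ("pull down", "MI:0096", 10.0),
    ("fluorescent resonance energy transfer", "MI:0055", 5.0),
    ("x-ray crystallography", "MI:0114", 3.0),
)

#: Most PPIs are seen once; a minority reoccur across studies. The tail
#: drives everything the study subscore rewards.
DEFAULT_STUDY_MULTIPLICITY: dict[int, float] = {1: 0.65, 2: 0.18, 3: 0.10, 4: 0.05, 5: 0.02}

#: Heavier multi-study tail used when a fixture must carry a strong
#: study-reproducibility signal (e.g. parameter-recovery properties).
STRONG_REPRODUCIBILITY_MULTIPLICITY: dict[int, float] = {
    1: 0.40, 2: 0.25, 3: 0.20, 4: 0.10, 5: 0.05,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the generator; defaults are the standard fixture conditions."""

    n_proteins: int = 300
    n_interactions: int = 800
    study_multiplicity: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_STUDY_MULTIPLICITY)
    )
    n_studies: int = 24
    dataset_labels: tuple[str, ...] = ("synthA", "synthB", "synthC")
    technique_pool: tuple[tuple[str, Optional[str], float], ...] = DEFAULT_TECHNIQUE_POOL
    two_technique_rate: float = 0.15
    no_technique_rate: float = 0.01
    organism_evidence_rate: float = 0.02
    species: tuple[str, ...] = DEFAULT_ORTHOLOG_SPECIES
    gene_ambiguity_rate: float = 0.10
    genetic_interaction_rate: float = 0.05
    unmappable_rate: float = 0.02
    ortholog_only_rate: float = 0.02
    self_interaction_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "two_technique_rate": self.two_technique_rate,
            "no_technique_rate": self.no_technique_rate,
            "organism_evidence_rate": self.organism_evidence_rate,
            "gene_ambiguity_rate": self.gene_ambiguity_rate,
            "genetic_interaction_rate": self.genetic_interaction_rate,
            "unmappable_rate": self.unmappable_rate,
            "ortholog_only_rate": self.ortholog_only_rate,
            "self_interaction_rate": self.self_interaction_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        max_pairs = self.n_proteins * (self.n_proteins - 1) // 2 + self.n_proteins
        if self.n_interactions > max_pairs:
            raise ValueError(
                f"{self.n_interactions} interactions infeasible with "
                f"{self.n_proteins} proteins"
            )
        if max(self.study_multiplicity) > self.n_studies:
            raise ValueError("study multiplicity exceeds the number of studies")
        total = sum(self.study_multiplicity.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"multiplicity distribution sums to {total}, not 1")


@dataclass
class TruthEvidence:
    """What the merged evidence for one pair must be."""

    studies: set[int] = field(default_factory=set)
    techniques: set[str] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)
    organisms: set[str] = field(default_factory=set)


@dataclass
class GroundTruth:
    """Exact planted structure, for conservation tests.

    ``pairs`` maps each surviving canonical pair to its expected merged
    evidence (after genetic and unmappable exclusions); the counters record
    exactly how many records each exclusion rule consumed.
    """

    pairs: dict[PairKey, TruthEvidence] = field(default_factory=dict)
    n_records: int = 0
    n_genetic_records: int = 0
    n_unmappable_records: int = 0
    n_ortholog_only: int = 0
    study_to_dataset: dict[int, str] = field(default_factory=dict)


@dataclass
class SyntheticData:
    datasets: list[list[SourceRecord]]
    mapping: IdMappingTable
    ortholog_records: list[OrthologRecord]
    truth: GroundTruth
    spec: SyntheticSpec


def _weighted_choice(rng: random.Random, pool, weights) -> int:
    return rng.choices(range(len(pool)), weights=weights, k=1)[0]


def generate_sources(spec: SyntheticSpec) -> SyntheticData:
    """Generate source datasets + mapping + ortholog evidence + ground truth.

    Bit-reproducible under ``spec.seed``: the same spec always yields the
    same files and ledger.
    """
    rng = random.Random(spec.seed)
    # identifier universe: raw "syn:Xn" -> canonical "Pn" + gene(s)
    proteins = [f"P{i:05d}" for i in range(1, spec.n_proteins + 1)]
    raw_of = {p: f"syn:X{i}" for i, p in enumerate(proteins, start=1)}
    entries = {}
    for i, p in enumerate(proteins, start=1):
        genes = [f"{100000 + i}"]
        if rng.random() < spec.gene_ambiguity_rate:
            genes.append(f"{200000 + i}")
        entries[("syn", f"X{i}")] = (p, frozenset(genes))
    mapping = IdMappingTable(entries)

    # studies, each owned by one source dataset
    studies = [STUDY_ID_BASE + i for i in range(1, spec.n_studies + 1)]
    study_to_dataset = {
        s: spec.dataset_labels[i % len(spec.dataset_labels)]
        for i, s in enumerate(studies)
    }

    # distinct unordered pairs (occasional self-interactions)
    pairs: set[PairKey] = set()
    while len(pairs) < spec.n_interactions:
        if rng.random() < spec.self_interaction_rate:
            a = b = rng.choice(proteins)
        else:
            a, b = rng.sample(proteins, 2)
        pairs.add(canonical_pair(a, b))
    pair_list = sorted(pairs)

    mults = sorted(spec.study_multiplicity)
    mult_weights = [spec.study_multiplicity[m] for m in mults]
    pool_names = [(n, c) for n, c, _ in spec.technique_pool]
    pool_weights = [w for _, _, w in spec.technique_pool]

    truth = GroundTruth(study_to_dataset=dict(study_to_dataset))
    datasets: dict[str, list[SourceRecord]] = {lbl: [] for lbl in spec.dataset_labels}
    unmapped_counter = 0
    for key in pair_list:
        m = mults[_weighted_choice(rng, mults, mult_weights)]
        pair_studies = rng.sample(studies, m)
        # the pair's technique repertoire is drawn once and shared by all its
        # studies: how often a pair was probed and with which methods are
        # separate axes of the evidence structure
        k = 2 if rng.random() < spec.two_technique_rate else 1
        idx = {_weighted_choice(rng, pool_names, pool_weights) for _ in range(k)}
        repertoire = {pool_names[i] for i in idx}
        for study in pair_studies:
            if rng.random() < spec.no_technique_rate:
                techs: set[tuple[str, Optional[str]]] = set()
            else:
                techs = set(repertoire)
            is_genetic = rng.random() < spec.genetic_interaction_rate
            raw_a, raw_b = raw_of[key[0]], raw_of[key[1]]
            unmappable = rng.random() < spec.unmappable_rate
            if unmappable:
                unmapped_counter += 1
                raw_a = f"syn:UNMAPPED{unmapped_counter}"
            label = study_to_dataset[study]
            rec = SourceRecord(
                raw_id_a=raw_a,
                raw_id_b=raw_b,
                pubmed_ids=frozenset({study}),
                techniques=frozenset(techs),
                source_name=label,
                is_genetic=is_genetic,
            )
            datasets[label].append(rec)
            truth.n_records += 1
            if is_genetic:
                truth.n_genetic_records += 1
                continue
            if unmappable:
                truth.n_unmappable_records += 1
                continue
            ev = truth.pairs.setdefault(key, TruthEvidence())
            ev.studies.add(study)
            ev.techniques |= {normalize_technique(n) for n, _ in techs}
            ev.sources.add(label)

    # ortholog evidence for surviving pairs, plus ortholog-only distractors
    ortho: list[OrthologRecord] = []
    for key in sorted(truth.pairs):
        for sp in spec.species:
            if rng.random() < spec.organism_evidence_rate:
                ortho.append(OrthologRecord(key[0], key[1], sp))
                truth.pairs[key].organisms.add(sp)
    n_only = round(spec.ortholog_only_rate * spec.n_interactions)
    made = 0
    while made < n_only:
        a, b = rng.sample(proteins, 2)
        key = canonical_pair(a, b)
        if key in pairs:
            continue
        ortho.append(OrthologRecord(key[0], key[1], rng.choice(spec.species)))
        truth.n_ortholog_only += 1
        made += 1

    return SyntheticData(
        datasets=[datasets[lbl] for lbl in spec.dataset_labels],
        mapping=mapping,
        ortholog_records=ortho,
        truth=truth,
        spec=spec,
    )


def generate_screen(
    net: ScoredNetwork,
    high_recall: float,
    low_recall: float,
    threshold: float,
    seed: int,
    bait_fraction: float = 0.6,
) -> ExternalScreen:
    """A bait-based screen with planted per-stratum recall.

    Baits are a random protein sample; each detectable interaction (>= 1
    bait endpoint) is detected independently with probability high_recall
    or low_recall according to its score stratum at ``threshold``.
    """
    if not 0.0 <= low_recall <= high_recall <= 1.0:
        raise ValueError(
            f"need 0 <= low_recall <= high_recall <= 1, got "
            f"({low_recall}, {high_recall})"
        )
    rng = random.Random(seed)
    proteins = sorted(net.proteins())
    if not proteins:
        raise ValueError("cannot build a screen on an empty network")
    baits = frozenset(rng.sample(proteins, max(1, round(bait_fraction * len(proteins)))))
    detected = set()
    n_detectable = {True: 0, False: 0}
    for si in net:
        if not (set(si.key) & baits):
            continue
        is_high = si.score >= threshold
        n_detectable[is_high] += 1
        rate = high_recall if is_high else low_recall
        if rng.random() < rate:
            detected.add(si.key)
    for is_high, rate in ((True, high_recall), (False, low_recall)):
        if rate > 0 and n_detectable[is_high] == 0:
            stratum = "high" if is_high else "low"
            raise ValueError(
                f"planted {stratum}-stratum recall {rate} infeasible: no "
                f"detectable interactions in that stratum"
            )
    return ExternalScreen(baits=baits, detected_pairs=frozenset(detected))


def write_fixture_dir(data: SyntheticData, outdir: PathLike) -> dict[str, Path]:
    """Write a complete fixture directory in the plain-text input formats.

    Returns the paths written: one source-dialect file per dataset, the
    mapping table, the ortholog-evidence file, and a spec echo.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for label, records in zip(data.spec.dataset_labels, data.datasets):
        p = outdir / f"source_{label}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            for rec in records:
                techs = ",".join(
                    f"{n}={c}" if c else n
                    for n, c in sorted(rec.techniques, key=lambda t: (t[0], t[1] or ""))
                )
                pmids = ",".join(str(x) for x in sorted(rec.pubmed_ids))
                genetic = "genetic" if rec.is_genetic else ""
                fh.write(
                    f"{rec.raw_id_a}\t{rec.raw_id_b}\t{pmids}\t{techs}\t"
                    f"{rec.source_name}\t{genetic}\n"
                )
        written[label] = p
    p = outdir / "id_mapping.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        for (ns, sid), (prot, genes) in sorted(data.mapping.entries.items()):
            fh.write(f"{ns}\t{sid}\t{prot}\t{','.join(sorted(genes))}\n")
    written["mapping"] = p
    p = outdir / "orthologs.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        for rec in data.ortholog_records:
            fh.write(f"{rec.protein_a}\t{rec.protein_b}\t{rec.species}\n")
    written["orthologs"] = p
    p = outdir / "spec.txt"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write(repr(data.spec) + "\n")
    written["spec"] = p
    return written


def write_screen(screen: ExternalScreen, outdir: PathLike) -> tuple[Path, Path]:
    """Write a screen as a bait list and a detected-pairs file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    baits_path = outdir / "screen_baits.txt"
    pairs_path = outdir / "screen_pairs.tsv"
    with open(baits_path, "w", encoding="utf-8") as fh:
        for b in sorted(screen.baits):
            fh.write(b + "\n")
    with open(pairs_path, "w", encoding="utf-8") as fh:
        for a, b in sorted(screen.detected_pairs):
            fh.write(f"{a}\t{b}\n")
    return baits_path, pairs_path
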