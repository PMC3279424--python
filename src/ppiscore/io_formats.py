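"""File formats: PSI-MI TAB 2.5, the scored flat file, and score tables.

Two interaction formats are supported. PSI-MI TAB 2.5 is the Proteomics
Standards Initiative's 15-column tab-delimited exchange format, used by the
public PPI databases this package integrates. The scored flat file is this
package's own 6-column dialect (UniProt id and Entrez Gene id per partner,
score, evidence comment); the evidence comment packs the per-interaction
evidence into labelled classes:

    experiments:<t1,t2,...>;pmids:<p1,...>;sources:<s1,...>[;organisms:<o1,...>]

Multiple evidences of one class are comma-separated and classes are
semicolon-separated. An interaction whose protein maps to several genes is
expanded to one line per gene combination. PSI-MI interaction-type codes are
not representable in the flat dialect; they round-trip through MITAB.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .model import (
    GENETIC_INTERACTION_TYPE,
    EvidenceBundle,
    Interaction,
    ScoredInteraction,
    ScoredNetwork,
    SourceRecord,
    canonical_pair,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Sentinel emitted when a method/source has no PSI-MI code (the MITAB cv
#: cell grammar requires one); mapped back to "no code" on read.
_NO_CODE = "MI:0000"

MITAB_COLUMNS = 15

# psi-mi:"MI:0018"(two hybrid)  /  pubmed:12345  /  taxid:9606(human)
_CV_RE = re.compile(r'([^:|]+):"?([^"|(]*)"?(?:\(([^)]*)\))?')


class FormatError(ValueError):
    """Hard, file-level format violation (e.g. wrong MITAB column count)."""


@dataclass
class ParseIssue:
    """Record-level problem; parsing continues past these."""

    line_number: int
    message: str


def normalize_technique(name: str) -> str:
    """Normalization applied before any name-based technique lookup.

    Case-folds, replaces hyphens/slashes with spaces and collapses runs of
    whitespace, because source datasets mix spellings ("Two-hybrid" vs
    "two hybrid").
    """
    out = name.casefold().replace("-", " ").replace("/", " ")
    return " ".join(out.split())


class TechniqueScoreTable:
    """Reliability scores in [0, 10] for PPI detection methods.

    Lookup resolves by PSI-MI code first and by normalized method name
    second; unknown techniques score 0 with a logged warning.
    """

    def __init__(self, entries: Sequence[tuple[str, Optional[str], float]]):
        self.entries = [(n, c if c else None, float(s)) for n, c, s in entries]
        self.by_code: dict[str, float] = {}
        self.by_name: dict[str, float] = {}
        for name, code, score in self.entries:
            if not 0.0 <= score <= 10.0:
                raise ValueError(f"technique score outside [0, 10]: {name} -> {score}")
            key = normalize_technique(name)
            if code is not None:
                if code in self.by_code and self.by_code[code] != score:
                    raise ValueError(f"conflicting scores for code {code}")
                self.by_code[code] = score
            if key in self.by_name and self.by_name[key] != score:
                raise ValueError(f"conflicting scores for method '{name}'")
            self.by_name[key] = score

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, name: str, code: Optional[str] = None) -> float:
        """Score for a technique; PSI-MI code wins over name on conflict."""
        if code is not None and code in self.by_code:
            return self.by_code[code]
        key = normalize_technique(name)
        if key in self.by_name:
            return self.by_name[key]
        logger.warning("unknown detection technique %r (code %r) scored 0", name, code)
        return 0.0

    def __contains__(self, name: str) -> bool:
        return normalize_technique(name) in self.by_name


def load_technique_scores(path: PathLike) -> TechniqueScoreTable:
    """Read a technique-score table: name <TAB> [PSI-MI code] <TAB> score."""
    entries: list[tuple[str, Optional[str], float]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:  # name, score
                name, code, score = parts[0], "", parts[1]
            elif len(parts) == 3:
                name, code, score = parts
            else:
                raise FormatError(f"expected 2 or 3 columns, got {len(parts)}: {line!r}")
            entries.append((name.strip(), code.strip() or None, float(score)))
    return TechniqueScoreTable(entries)


def default_technique_scores() -> TechniqueScoreTable:
    """The packaged curated score table (125 detection methods)."""
    ref = resources.files("ppiscore").joinpath("data/technique_scores.tsv")
    with resources.as_file(ref) as path:
        return load_technique_scores(path)


# ---------------------------------------------------------------------------
# PSI-MI TAB 2.5


def _parse_cv_cell(cell: str) -> list[tuple[str, str, str]]:
    """Split a pipe-multivalued controlled-vocabulary cell.

    Returns (namespace, accession, label) triples; '-' yields [].
    """
    if cell.strip() in ("", "-"):
        return []
    out = []
    for item in cell.split("|"):
        m = _CV_RE.match(item.strip())
        if m:
            ns, acc, label = m.group(1), m.group(2), m.group(3) or ""
            out.append((ns.strip(), acc.strip(), label.strip()))
        else:
            out.append(("", item.strip(), ""))
    return out


def _strip_namespace(raw: str) -> str:
    items = _parse_cv_cell(raw)
    if not items:
        raise ValueError(f"missing interactor identifier: {raw!r}")
    ns, acc, _ = items[0]
    return f"{ns}:{acc}" if ns else acc


def read_psimitab25(path: PathLike) -> tuple[list[SourceRecord], list[ParseIssue]]:
    """Parse a PSI-MI TAB 2.5 file into source records.

    Extra columns from later MITAB versions are ignored; fewer than 15
    columns is a hard :class:`FormatError`. Cell-level problems are collected
    as :class:`ParseIssue` and parsing continues.
    """
    records: list[SourceRecord] = []
    issues: list[ParseIssue] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):  # optional comment/header line
                continue
            cols = line.split("\t")
            if len(cols) < MITAB_COLUMNS:
                raise FormatError(
                    f"line {lineno}: expected {MITAB_COLUMNS} tab-separated "
                    f"columns, got {len(cols)}"
                )
            try:
                id_a = _strip_namespace(cols[0])
                id_b = _strip_namespace(cols[1])
            except ValueError as exc:
                issues.append(ParseIssue(lineno, str(exc)))
                continue
            pubmed_ids: set[int] = set()
            for ns, acc, _ in _parse_cv_cell(cols[8]):
                if ns != "pubmed":
                    continue
                try:
                    pubmed_ids.add(int(acc))
                except ValueError:
                    issues.append(ParseIssue(lineno, f"non-numeric pubmed id {acc!r}"))
            techniques: set[tuple[str, Optional[str]]] = set()
            for ns, acc, label in _parse_cv_cell(cols[6]):
                code = acc if ns == "psi-mi" and acc and acc != _NO_CODE else None
                name = label or acc
                if name:
                    techniques.add((name, code))
            itypes: set[str] = set()
            for ns, acc, _ in _parse_cv_cell(cols[11]):
                if acc and acc != _NO_CODE:
                    itypes.add(acc)
            sources = [label or acc for _, acc, label in _parse_cv_cell(cols[12])]
            records.append(
                SourceRecord(
                    raw_id_a=id_a,
                    raw_id_b=id_b,
                    pubmed_ids=frozenset(pubmed_ids),
                    techniques=frozenset(techniques),
                    interaction_types=frozenset(itypes),
                    source_name=sources[0] if sources else "",
                )
            )
    return records, issues


def _cv(code: Optional[str], label: str, ns: str = "psi-mi") -> str:
    return f'{ns}:"{code or _NO_CODE}"({label})'


def write_psimitab25(records: Sequence[SourceRecord], path: PathLike) -> None:
    """Write records as PSI-MI TAB 2.5, sorted by canonical identifier pair."""
    def sort_key(rec: SourceRecord):
        return canonical_pair(rec.raw_id_a, rec.raw_id_b) + (rec.source_name,)

    with open(path, "w", encoding="utf-8") as fh:
        for rec in sorted(records, key=sort_key):
            det = "|".join(
                _cv(code, name)
                for name, code in sorted(rec.techniques, key=lambda t: (t[1] or "", t[0]))
            ) or "-"
            pubs = "|".join(f"pubmed:{p}" for p in sorted(rec.pubmed_ids)) or "-"
            itypes = set(rec.interaction_types)
            if rec.is_genetic:
                itypes.add(GENETIC_INTERACTION_TYPE)
            ity = "|".join(_cv(code, "") for code in sorted(itypes)) or "-"
            src = _cv(None, rec.source_name) if rec.source_name else "-"
            cols = [
                rec.raw_id_a,
                rec.raw_id_b,
                "-", "-", "-", "-",
                det,
                "-",
                pubs,
                "taxid:9606(Homo sapiens)",
                "taxid:9606(Homo sapiens)",
                ity,
                src,
                "-",
                "-",
            ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Simple tab-delimited source dialect


def read_source_table(path: PathLike, source_name: Optional[str] = None) -> list[SourceRecord]:
    """Read the simple source dialect.

    Columns: protein_a, protein_b, comma-separated PubMed ids (may be empty),
    comma-separated method names or ``name=MI:nnnn`` items, source name, and
    an optional ``genetic`` flag column. ``source_name`` overrides column 5.
    """
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise FormatError(f"line {lineno}: expected >=5 columns, got {len(cols)}")
            pmids = frozenset(int(p) for p in cols[2].split(",") if p.strip())
            techniques = set()
            for item in cols[3].split(","):
                item = item.strip()
                if not item:
                    continue
                name, _, code = item.partition("=")
                techniques.add((name.strip(), code.strip() or None))
            records.append(
                SourceRecord(
                    raw_id_a=cols[0].strip(),
                    raw_id_b=cols[1].strip(),
                    pubmed_ids=pmids,
                    techniques=frozenset(techniques),
                    source_name=source_name or cols[4].strip(),
                    is_genetic=len(cols) > 5 and cols[5].strip().lower() in ("1", "true", "genetic"),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Scored flat file

_KNOWN_CLASSES = ("experiments", "pmids", "sources", "organisms")


def _format_comment(ev: EvidenceBundle) -> str:
    parts = [
        "experiments:" + ",".join(sorted(ev.techniques)),
        "pmids:" + ",".join(str(p) for p in sorted(ev.studies)),
        "sources:" + ",".join(sorted(ev.sources)),
    ]
    if ev.organisms:
        parts.append("organisms:" + ",".join(sorted(ev.organisms)))
    return ";".join(parts)


def _parse_comment(comment: str) -> EvidenceBundle:
    ev = EvidenceBundle()
    for chunk in comment.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        label, _, body = chunk.partition(":")
        label = label.strip()
        values = [v.strip() for v in body.split(",") if v.strip()]
        if label == "experiments":
            ev.techniques.update(values)
        elif label == "pmids":
            ev.studies.update(int(v) for v in values)
        elif label == "sources":
            ev.sources.update(values)
        elif label == "organisms":
            ev.organisms.update(values)
        else:
            logger.warning("unknown evidence class %r ignored", label)
    if ev.studies:
        ev.techniques_by_study = {min(ev.studies): set(ev.techniques)}
    elif ev.techniques:
        ev.techniques_by_study = {None: set(ev.techniques)}
    return ev


def write_scored_flat(net: ScoredNetwork, path: PathLike) -> None:
    """Write the 6-column scored flat file.

    Scores are printed at 2 decimals (round-half-even); full precision lives
    only in memory. Gene-ambiguous interactions expand to one line per gene
    combination, sorted for determinism.
    """
    lines = []
    for si in net:
        if si.score is None:
            raise ValueError(f"unscored interaction {si.interaction.key}")
        a, b = si.key
        combos = sorted(si.interaction.gene_combinations) or [("", "")]
        comment = _format_comment(si.evidence)
        for ga, gb in combos:
            lines.append((a, ga, b, gb, f"{si.score:.2f}", comment))
    lines.sort()
    with open(path, "w", encoding="utf-8") as fh:
        for row in lines:
            fh.write("\t".join(row) + "\n")


def read_scored_flat(path: PathLike) -> ScoredNetwork:
    """Read a scored flat file back into a network.

    Lines sharing a protein pair (gene-combination expansion) are collapsed
    into one interaction holding every listed gene combination.
    """
    merged: dict[tuple[str, str], ScoredInteraction] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(f"line {lineno}: expected 6 columns, got {len(cols)}")
            ua, ga, ub, gb, score_s, comment = cols
            score = float(score_s)
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"line {lineno}: score {score} outside [0, 1]")
            key = canonical_pair(ua, ub)
            combo = (ga, gb) if (ua, ub) == key else (gb, ga)
            if key in merged:
                si = merged[key]
                if (ga or gb):
                    si.interaction.gene_combinations.add(combo)
            else:
                ev = _parse_comment(comment)
                combos = {combo} if (ga or gb) else set()
                merged[key] = ScoredInteraction(
                    Interaction(key=key, gene_combinations=combos, evidence=ev),
                    score=score,
                )
    return ScoredNetwork(sorted(merged.values(), key=lambda si: si.key))


def network_to_records(net: ScoredNetwork) -> list[SourceRecord]:
    """Flatten a scored network back to source records (one per interaction),
    e.g. for MITAB export. Technique names are the stored normalized keys."""
    out = []
    for si in net:
        ev = si.evidence
        out.append(
            SourceRecord(
                raw_id_a=si.key[0],
                raw_id_b=si.key[1],
                pubmed_ids=frozenset(ev.studies),
                techniques=frozenset((t, None) for t in ev.techniques),
                interaction_types=frozenset(ev.interaction_types),
                source_name=",".join(sorted(ev.sources)),
            )
        )
    return out
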