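"""Evaluating a scored network against an external interaction screen.

A bait-based screen (yeast two-hybrid or affinity-capture MS) can only
report pairs touching one of its baits, so recall is measured on the
"detectable" interactions: those with at least one endpoint in the bait
list. The network is stratified at a confidence threshold (high: score >=
threshold; low: below), recall = overlap / detectable is computed per
stratum, and a one-sided Fisher's exact test asks whether the high stratum
is recalled better than the low one.

The 2x2 table underlying the test pairs each stratum's overlap count with
its detectable-set size:

    [[k_high, n_high],
     [k_low,  n_low ]]

with alternative "greater" (larger recall in the high stratum).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from scipy.stats import fisher_exact

from .model import PairKey, ScoredInteraction, ScoredNetwork, canonical_pair

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ExternalScreen:
    """A bait-based screen: its baits and the pairs it detected."""

    baits: frozenset[str]
    detected_pairs: frozenset[PairKey]

    def __post_init__(self) -> None:
        bad = [p for p in self.detected_pairs if not (set(p) & self.baits)]
        if bad:
            raise ValueError(
                f"{len(bad)} detected pair(s) contain no bait, e.g. {bad[0]}"
            )


def load_screen(baits_path: PathLike, pairs_path: PathLike) -> ExternalScreen:
    """Read a screen from a bait list (one id per line) and a two-column
    detected-pairs file."""
    with open(baits_path, encoding="utf-8") as fh:
        baits = frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )
    pairs = set()
    with open(pairs_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            pairs.add(canonical_pair(a.strip(), b.strip()))
    return ExternalScreen(baits=baits, detected_pairs=frozenset(pairs))


def detectable_subset(
    net: ScoredNetwork, screen: ExternalScreen
) -> list[ScoredInteraction]:
    """Interactions with at least one endpoint among the screen's baits."""
    if not screen.baits:
        raise ValueError("screen has no baits; nothing is detectable")
    return [si for si in net if set(si.key) & screen.baits]


@dataclass(frozen=True)
class StratumStats:
    label: str
    size: int
    detectable: int
    overlap: int

    @property
    def recall(self) -> Optional[float]:
        """overlap / detectable; None when nothing is detectable."""
        if self.detectable == 0:
            return None
        return self.overlap / self.detectable

    @property
    def recall_pct(self) -> Optional[float]:
        """Recall as a percentage at 1 decimal, as reported in tables."""
        r = self.recall
        return None if r is None else round(100.0 * r, 1)


@dataclass(frozen=True)
class RecallReport:
    high: StratumStats
    low: StratumStats
    fisher_p: Optional[float]
    threshold: float

    def to_text(self) -> str:
        lines = ["subset\tsize\tdetectable\toverlap (recall)"]
        for s in (self.high, self.low):
            rec = "NA" if s.recall_pct is None else f"{s.overlap} ({s.recall_pct}%)"
            lines.append(f"{s.label}\t{s.size}\t{s.detectable}\t{rec}")
        p = "NA" if self.fisher_p is None else f"{self.fisher_p:.2e}"
        lines.append(f"one-sided Fisher p = {p}")
        return "\n".join(lines)


def fisher_one_sided(k_high: int, n_high: int, k_low: int, n_low: int) -> float:
    """One-sided Fisher's exact test for greater recall in the high stratum.

    Exact hypergeometric tail probability of observing >= k_high on the
    table [[k_high, n_high], [k_low, n_low]] (overlap vs detectable-set
    size per stratum).
    """
    for k, n in ((k_high, n_high), (k_low, n_low)):
        if not 0 <= k <= n:
            raise ValueError(f"inconsistent counts: overlap {k}, detectable {n}")
    _, p = fisher_exact([[k_high, n_high], [k_low, n_low]], alternative="greater")
    return float(p)


def stratified_recall(
    net: ScoredNetwork, screen: ExternalScreen, threshold: float
) -> RecallReport:
    """Stratify at the threshold, restrict to detectable PPIs, compute recall
    per stratum and the one-sided Fisher p-value for their difference.

    Ties at the threshold land in the high stratum (score >= threshold).
    The p-value is None when either stratum has no detectable PPIs.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    detectable = detectable_subset(net, screen)
    strata = {}
    for label, members, det in (
        (f"score >= {threshold}", [si for si in net if si.score >= threshold],
         [si for si in detectable if si.score >= threshold]),
        (f"score < {threshold}", [si for si in net if si.score < threshold],
         [si for si in detectable if si.score < threshold]),
    ):
        overlap = sum(1 for si in det if si.key in screen.detected_pairs)
        strata[label] = StratumStats(
            label=label, size=len(members), detectable=len(det), overlap=overlap
        )
    high, low = strata.values()
    if high.detectable and low.detectable:
        p = fisher_one_sided(high.overlap, high.detectable, low.overlap, low.detectable)
    else:
        p = None
    return RecallReport(high=high, low=low, fisher_p=p, threshold=threshold)
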