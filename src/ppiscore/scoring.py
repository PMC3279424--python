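"""Confidence score for an interaction's accumulated evidence.

Each interaction gets a score S in [0, 1) built from three evidence
quantities: the number of studies (PubMed ids) reporting it, the number of
non-human species in which orthologs of the pair interact, and the summed
reliability scores of the distinct detection techniques used. Each quantity
n is squashed through a saturating function

    s(n) = 1 - exp(-a * n)

with s(0) = 0 and s(inf) = 1, whose steepness a is a free parameter, and the
total score is the weighted sum

    S = w_s * s(n_studies; a_s) + w_o * s(n_organisms; a_o)
        + w_t * s(technique_mass; a_t),      w_s + w_o + w_t = 1.

The saturating form is injectable (``saturation=``) so alternatives such as
n / (n + a) can be swapped in for sensitivity analyses.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

from .io_formats import TechniqueScoreTable
from .model import (
    EvidenceBundle,
    EvidenceCounts,
    Interaction,
    ScoredInteraction,
    ScoredNetwork,
    ScoringParams,
)

SaturationFn = Callable[[float, float], float]


def exp_saturation(n: float, a: float) -> float:
    """Default saturating subscore: 1 - exp(-a*n), in [0, 1)."""
    return 1.0 - math.exp(-a * n)


def subscore(n: float, a: float, saturation: SaturationFn = exp_saturation) -> float:
    """Saturating subscore of one evidence quantity.

    Strictly increasing in n for a > 0, 0 at n = 0, approaching 1 as n grows.
    """
    if n < 0:
        raise ValueError(f"evidence quantity must be >= 0, got {n}")
    if a < 0:
        raise ValueError(f"steepness constant must be >= 0, got {a}")
    return saturation(n, a)


def evidence_counts(ev: EvidenceBundle, table: TechniqueScoreTable) -> EvidenceCounts:
    """Reduce an evidence bundle to the three scored quantities.

    Distinct techniques each count once, however many studies used them; the
    study count separately rewards repetition. Unknown techniques contribute
    0 (with a warning from the table lookup).
    """
    mass = sum(table.lookup(t) for t in sorted(ev.techniques))
    return EvidenceCounts(
        n_studies=len(ev.studies),
        n_organisms=len(ev.organisms),
        technique_mass=float(mass),
    )


def score_counts(
    counts: EvidenceCounts,
    params: ScoringParams,
    saturation: SaturationFn = exp_saturation,
) -> float:
    """Weighted sum of the three subscores; 0 iff all three quantities are 0."""
    return (
        params.w_s * subscore(counts.n_studies, params.a_s, saturation)
        + params.w_o * subscore(counts.n_organisms, params.a_o, saturation)
        + params.w_t * subscore(counts.technique_mass, params.a_t, saturation)
    )


# spec-facing alias
score_interaction = score_counts


def score_network(
    interactions: Iterable[Interaction],
    params: ScoringParams,
    table: TechniqueScoreTable,
    saturation: SaturationFn = exp_saturation,
) -> ScoredNetwork:
    """Score every interaction; a pure, deterministic function of its inputs."""
    scored = [
        ScoredInteraction(ia, score_counts(evidence_counts(ia.evidence, table), params, saturation))
        for ia in interactions
    ]
    return ScoredNetwork(scored)


def counts_matrix(
    interactions: Sequence[Interaction], table: TechniqueScoreTable
) -> np.ndarray:
    """(n, 3) array of (n_studies, n_organisms, technique_mass) rows.

    Vectorized backing store for the grid search, where the same evidence is
    rescored under millions of parameter settings.
    """
    rows = np.empty((len(interactions), 3), dtype=float)
    for i, ia in enumerate(interactions):
        c = evidence_counts(ia.evidence, table)
        rows[i] = (c.n_studies, c.n_organisms, c.technique_mass)
    return rows


def score_counts_array(counts: np.ndarray, params: ScoringParams) -> np.ndarray:
    """Vectorized scores for a (n, 3) counts array under one parameter set."""
    a = np.array([params.a_s, params.a_o, params.a_t])
    w = np.array([params.w_s, params.w_o, params.w_t])
    return (w * (1.0 - np.exp(-a * counts))).sum(axis=1)


def upper_quartile(scores_or_net: "ScoredNetwork | Sequence[float]") -> float:
    """75th-percentile score by the nearest-rank convention.

    The high-confidence stratum is defined by score >= this threshold.
    Nearest-rank (the ceil(0.75*n)-th order statistic) is used for exact
    determinism across platforms: no interpolation between observed scores.
    """
    scores = (
        scores_or_net.scores()
        if isinstance(scores_or_net, ScoredNetwork)
        else list(scores_or_net)
    )
    if len(scores) < 4:
        raise ValueError(f"need >= 4 scores for a quartile, got {len(scores)}")
    ranked = sorted(scores)
    rank = math.ceil(0.75 * len(ranked))  # 1-based
    return ranked[rank - 1]


def interquartile_range(scores: Sequence[float]) -> float:
    """Q3 - Q1 under the same nearest-rank convention as upper_quartile."""
    if len(scores) < 4:
        raise ValueError(f"need >= 4 scores for quartiles, got {len(scores)}")
    ranked = sorted(scores)
    n = len(ranked)
    q3 = ranked[math.ceil(0.75 * n) - 1]
    q1 = ranked[math.ceil(0.25 * n) - 1]
    return q3 - q1
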