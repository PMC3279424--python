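"""Parameter selection by exhaustive grid search with leave-one-study-out.

The six scoring parameters are chosen by scanning a regular grid — the
steepness constants a_s, a_o, a_t over [0, 3] and the weights over the
simplex w_s + w_o + w_t = 1, both at step 0.1 by default (31^3 x 66 =
1,966,206 combinations) — and ranking each candidate by how well the score
it induces predicts reproducibility across studies.

The reproducibility objective removes one study at a time from a reference
dataset with explicit study-interaction associations, rescores the reduced
dataset, and asks whether the interactions shared between the held-out study
and the reduced dataset are enriched above the reduced dataset's upper
quartile Q3. Per holdout j:

    dev_j = (n_high_j + 0.5) / (0.25 * |overlap_j| + 0.5)

where n_high_j counts overlap interactions rescoring >= Q3 and 0.25 *
|overlap_j| is the random expectation (Q3 puts exactly a quarter of the
reduced dataset in the high stratum); the 0.5 pseudocounts keep the
logarithm finite when nothing scores high. The overall objective is the
overlap-weighted geometric mean

    f = exp( sum_j v_j * log dev_j / sum_j v_j ),     v_j = |overlap_j|,

any strictly increasing outer function leaves the argmax unchanged. Among
f-maximizers the combination spreading scores widest (largest interquartile
range on the full reference) wins; residual ties break to the
lexicographically smallest parameter tuple. Combinations inducing too few
distinct score values (e.g. w_t = 0, which discards the granularity
contributed by technique scores) are excluded as degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import TechniqueScoreTable
from .model import Interaction, PairKey, ScoringParams
from .scoring import (
    counts_matrix,
    interquartile_range,
    score_counts_array,
    score_network,
    upper_quartile,
)

#: Combinations inducing fewer distinct scores than this on the reference
#: are excluded as degenerate.
DEFAULT_DEGENERACY_THRESHOLD = 20


@dataclass(frozen=True)
class ParamGrid:
    """Regular search grid: steepness values per axis x weight triples."""

    a_values: tuple[float, ...]
    w_triples: tuple[tuple[float, float, float], ...]

    @property
    def size(self) -> int:
        return len(self.a_values) ** 3 * len(self.w_triples)


def weight_simplex(step: float = 0.1) -> tuple[tuple[float, float, float], ...]:
    """All (w_s, w_o, w_t) on the given lattice summing to 1."""
    k = round(1.0 / step)
    triples = []
    for i in range(k + 1):
        for j in range(k + 1 - i):
            triples.append((i / k, j / k, (k - i - j) / k))
    return tuple(triples)


def default_grid(a_step: float = 0.1, w_step: float = 0.1, a_max: float = 3.0) -> ParamGrid:
    n = round(a_max / a_step)
    return ParamGrid(
        a_values=tuple(i * a_step for i in range(n + 1)),
        w_triples=weight_simplex(w_step),
    )


def reduced_grid() -> ParamGrid:
    """Coarse grid (a step 1.0, w step 0.2) for tests and small studies."""
    return default_grid(a_step=1.0, w_step=0.2)


def enumerate_grid(grid: Optional[ParamGrid] = None) -> list[ScoringParams]:
    """Full cross product of steepness grids x weight simplex, in
    deterministic lexicographic order, before any degeneracy filtering."""
    grid = grid or default_grid()
    out = []
    for a_s in grid.a_values:
        for a_o in grid.a_values:
            for a_t in grid.a_values:
                for w_s, w_o, w_t in grid.w_triples:
                    out.append(ScoringParams(a_s, a_o, a_t, w_s, w_o, w_t))
    return out


@dataclass
class StudyHoldout:
    """Diagnostics for one left-out study under one parameter setting."""

    study_id: int
    n_overlap: int
    n_high: int
    dev: float
    #: the shared pair keys, when the caller wants them (the vectorized grid
    #: search only tracks the count)
    overlap: Optional[frozenset[PairKey]] = None

    @property
    def v(self) -> int:
        """Objective weight, proportional to the overlap size."""
        return self.n_overlap


def eligible_studies(
    reference: Sequence[Interaction],
    min_interactions: int = 10,
    min_multistudy: int = 2,
) -> list[int]:
    """Studies usable as holdouts: at least ``min_interactions`` interactions
    and more than ``min_multistudy`` PPIs found in multiple studies
    (multi-study membership judged on the full reference)."""
    by_study: dict[int, list[Interaction]] = {}
    for ia in reference:
        for s in ia.evidence.studies:
            by_study.setdefault(s, []).append(ia)
    out = []
    for study in sorted(by_study):
        members = by_study[study]
        if len(members) < min_interactions:
            continue
        n_multi = sum(1 for ia in members if len(ia.evidence.studies) >= 2)
        if n_multi > min_multistudy:
            out.append(study)
    return out


def deviation_statistic(n_high: int, n_overlap: int) -> float:
    """dev = (n_high + 0.5) / (0.25 * n_overlap + 0.5)."""
    return (n_high + 0.5) / (0.25 * n_overlap + 0.5)


def reduced_dataset(
    reference: Sequence[Interaction], study: int
) -> list[Interaction]:
    """The reference with one study's evidence removed.

    Removal acts on evidence, not interactions: an interaction only drops
    out when nothing experimental (no study, no technique provenance)
    remains.
    """
    out = []
    for ia in reference:
        ev = ia.evidence.without_study(study)
        if ev is None:
            continue
        if ev is ia.evidence:
            out.append(ia)
        else:
            out.append(Interaction(ia.key, set(ia.gene_combinations), ev))
    return out


def loso_deviation(
    reference: Sequence[Interaction],
    study: int,
    params: ScoringParams,
    table: TechniqueScoreTable,
) -> StudyHoldout:
    """Hold out one study, rescore the remainder, and measure enrichment of
    the shared PPIs above the reduced dataset's upper quartile."""
    study_keys = {ia.key for ia in reference if study in ia.evidence.studies}
    reduced = reduced_dataset(reference, study)
    scored = score_network(reduced, params, table)
    q3 = upper_quartile(scored)
    by_pair = scored.by_pair()
    overlap = frozenset(k for k in study_keys if k in by_pair)
    n_high = sum(1 for k in overlap if by_pair[k].score >= q3)
    return StudyHoldout(
        study_id=study,
        n_overlap=len(overlap),
        n_high=n_high,
        dev=deviation_statistic(n_high, len(overlap)),
        overlap=overlap,
    )


def objective_f(holdouts: Sequence[StudyHoldout]) -> float:
    """Overlap-weighted geometric mean of the per-study deviations.

    Invariant under uniform scaling of the weights and under permutation of
    the holdouts; equals 1 when every study behaves exactly as expected at
    random.
    """
    if not holdouts:
        raise ValueError("objective_f needs at least one holdout")
    total_v = sum(h.v for h in holdouts)
    if total_v == 0:
        raise ValueError("all holdout overlaps are empty")
    acc = sum(h.v * math.log(h.dev) for h in holdouts)
    return math.exp(acc / total_v)


@dataclass
class CombinationRecord:
    params: ScoringParams
    f: Optional[float]
    iqr: Optional[float]
    n_distinct_scores: int
    degenerate: bool


@dataclass
class OptimizationReport:
    """Every evaluated combination plus the selected winner."""

    records: list[CombinationRecord]
    winner: ScoringParams
    winner_f: float
    winner_iqr: float
    winner_holdouts: list[StudyHoldout]
    studies_used: list[int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "a_s": r.params.a_s,
                "a_o": r.params.a_o,
                "a_t": r.params.a_t,
                "w_s": r.params.w_s,
                "w_o": r.params.w_o,
                "w_t": r.params.w_t,
                "f": r.f,
                "iqr": r.iqr,
                "n_distinct_scores": r.n_distinct_scores,
                "degenerate": r.degenerate,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


class _HoldoutIndex:
    """Parameter-independent per-holdout structures, computed once.

    Rescoring under a new parameter set only changes the score vector, never
    the evidence counts, so the reduced-count matrices and overlap row
    indices can be shared across all grid points.
    """

    def __init__(
        self,
        reference: Sequence[Interaction],
        studies: Sequence[int],
        table: TechniqueScoreTable,
    ):
        self.studies = list(studies)
        self.full_counts = counts_matrix(reference, table)
        self.per_study: list[tuple[np.ndarray, np.ndarray]] = []
        for study in self.studies:
            study_keys = {
                ia.key for ia in reference if study in ia.evidence.studies
            }
            reduced = reduced_dataset(reference, study)
            counts = counts_matrix(reduced, table)
            overlap_idx = np.array(
                [i for i, ia in enumerate(reduced) if ia.key in study_keys],
                dtype=int,
            )
            self.per_study.append((counts, overlap_idx))

    def evaluate(self, params: ScoringParams) -> tuple[float, list[StudyHoldout]]:
        holdouts = []
        for study, (counts, overlap_idx) in zip(self.studies, self.per_study):
            scores = score_counts_array(counts, params)
            rank = math.ceil(0.75 * len(scores))
            q3 = np.partition(scores, rank - 1)[rank - 1]
            n_high = int((scores[overlap_idx] >= q3).sum())
            holdouts.append(
                StudyHoldout(
                    study_id=study,
                    n_overlap=len(overlap_idx),
                    n_high=n_high,
                    dev=deviation_statistic(n_high, len(overlap_idx)),
                )
            )
        return objective_f(holdouts), holdouts


def select_params(
    reference: Sequence[Interaction],
    table: TechniqueScoreTable,
    grid: Optional[ParamGrid] = None,
    degeneracy_threshold: int = DEFAULT_DEGENERACY_THRESHOLD,
    keep_records: bool = True,
) -> OptimizationReport:
    """Run the grid search and pick the winning parameter set.

    Winner = argmax f; ties (grouped at 9 decimals, since exact mathematical
    ties accumulate float noise) break to the largest full-reference IQR,
    then to the lexicographically smallest parameter tuple. Every evaluated
    combination is recorded; degenerate ones carry no f.
    """
    grid = grid or default_grid()
    studies = eligible_studies(reference)
    if not studies:
        raise ValueError(
            "no eligible studies: need >=10 interactions and >2 multi-study "
            "PPIs per holdout study"
        )
    index = _HoldoutIndex(reference, studies, table)
    full_counts = index.full_counts
    records: list[CombinationRecord] = []
    best_key: Optional[tuple[float, float, tuple[float, ...]]] = None
    winner: Optional[ScoringParams] = None
    winner_f = winner_iqr = float("nan")
    any_evaluated = False
    for params in enumerate_grid(grid):
        scores = score_counts_array(full_counts, params)
        n_distinct = int(np.unique(np.round(scores, 10)).size)
        if n_distinct < degeneracy_threshold:
            if keep_records:
                records.append(CombinationRecord(params, None, None, n_distinct, True))
            continue
        any_evaluated = True
        f, _ = index.evaluate(params)
        iqr = interquartile_range(scores.tolist())
        if keep_records:
            records.append(CombinationRecord(params, f, iqr, n_distinct, False))
        # maximize (f, iqr), then minimize the parameter tuple
        key = (
            round(f, 9),
            round(iqr, 9),
            tuple(-p for p in params.as_tuple()),
        )
        if best_key is None or key > best_key:
            best_key = key
            winner, winner_f, winner_iqr = params, f, iqr
    if not any_evaluated or winner is None:
        raise ValueError("every parameter combination was degenerate")
    winner_holdouts = [
        loso_deviation(reference, s, winner, table) for s in studies
    ]
    return OptimizationReport(
        records=records,
        winner=winner,
        winner_f=winner_f,
        winner_iqr=winner_iqr,
        winner_holdouts=winner_holdouts,
        studies_used=studies,
    )
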