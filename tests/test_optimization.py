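"""Grid enumeration, LOSO deviations, the objective f, and the search."""

import math

import pytest

from ppiscore.integration import merge_sources
from ppiscore.model import DEFAULT_PARAMS, EvidenceBundle, Interaction, ScoringParams
from ppiscore.optimization import (
    ParamGrid,
    StudyHoldout,
    _HoldoutIndex,
    default_grid,
    deviation_statistic,
    eligible_studies,
    enumerate_grid,
    loso_deviation,
    objective_f,
    reduced_grid,
    select_params,
    weight_simplex,
)
from ppiscore.synthetic import (
    STRONG_REPRODUCIBILITY_MULTIPLICITY,
    SyntheticSpec,
    generate_sources,
)


def holdout(dev=None, n_overlap=8, n_high=2, study=1):
    if dev is None:
        dev = deviation_statistic(n_high, n_overlap)
    return StudyHoldout(study_id=study, n_overlap=n_overlap, n_high=n_high, dev=dev)


class TestGrid:
    def test_weight_simplex_has_66_triples(self):
        triples = weight_simplex(0.1)
        assert len(triples) == 66
        assert len(set(triples)) == 66
        for t in triples:
            assert sum(t) == pytest.approx(1.0, abs=1e-9)

    def test_default_grid_cardinality(self):
        g = default_grid()
        assert len(g.a_values) == 31
        assert g.size == 31**3 * 66 == 1_966_206

    def test_enumerate_small_grid_is_full_cross_product(self):
        g = ParamGrid(a_values=(0.0, 1.0), w_triples=((0.5, 0.25, 0.25), (1.0, 0.0, 0.0)))
        params = enumerate_grid(g)
        assert len(params) == 2**3 * 2 == g.size
        assert len(set(params)) == len(params)
        assert params == sorted(params, key=lambda p: p.as_tuple())


class TestDeviation:
    def test_observed_equals_random_expectation(self):
        # 8 overlap, 2 high: dev = 2.5/2.5 = 1, log dev = 0
        assert deviation_statistic(2, 8) == 1.0

    def test_full_enrichment(self):
        assert deviation_statistic(8, 8) == pytest.approx(8.5 / 2.5) == pytest.approx(3.4)

    def test_pseudocount_keeps_log_finite_at_zero_observed(self):
        assert deviation_statistic(0, 8) > 0


def _two_study_reference():
    """Pair (A,B) seen in studies 1 and 2; pair (C,D) only in study 1."""
    def ia(a, b, studies):
        ev = EvidenceBundle()
        for s in studies:
            ev.add_record([s], ["two hybrid"], "db")
        return Interaction((a, b), set(), ev)

    return [ia("A", "B", [1, 2]), ia("C", "D", [1]), ia("E", "F", [2]),
            ia("G", "H", [1, 2]), ia("I", "J", [2]),
            ia("K", "L", [3]), ia("M", "N", [3]), ia("O", "P", [3])]


def test_removing_sole_evidence_study_drops_interaction(table):
    ref = _two_study_reference()
    h = loso_deviation(ref, 1, DEFAULT_PARAMS, table)
    # (C,D) existed only through study 1 -> gone from the reduced set
    assert ("C", "D") not in h.overlap
    assert h.overlap == {("A", "B"), ("G", "H")}


def test_holdout_removes_evidence_not_interactions(table):
    ref = _two_study_reference()
    h = loso_deviation(ref, 2, DEFAULT_PARAMS, table)
    # (A,B) retains study 1 and stays in the reduced set
    assert ("A", "B") in h.overlap


class TestObjective:
    def test_all_dev_one_gives_f_one(self):
        hs = [holdout(dev=1.0, n_overlap=k) for k in (3, 8, 20)]
        assert objective_f(hs) == pytest.approx(1.0)

    def test_equal_devs(self):
        hs = [holdout(dev=2.0, n_overlap=5), holdout(dev=2.0, n_overlap=9)]
        assert objective_f(hs) == pytest.approx(2.0)

    def test_weighted_geometric_mean_closed_form(self):
        hs = [holdout(dev=4.0, n_overlap=3), holdout(dev=1.0, n_overlap=1)]
        assert objective_f(hs) == pytest.approx(math.exp(3 * math.log(4) / 4))
        assert objective_f(hs) == pytest.approx(2.828427, abs=5e-7)

    def test_invariant_under_uniform_weight_scaling(self):
        hs = [holdout(dev=1.7, n_overlap=4), holdout(dev=0.6, n_overlap=10)]
        scaled = [holdout(dev=h.dev, n_overlap=h.n_overlap * 3) for h in hs]
        assert objective_f(scaled) == pytest.approx(objective_f(hs))

    def test_invariant_under_permutation(self):
        hs = [holdout(dev=d, n_overlap=n) for d, n in [(1.3, 4), (0.9, 7), (2.0, 3)]]
        assert objective_f(list(reversed(hs))) == pytest.approx(objective_f(hs))

    def test_empty_holdouts_rejected(self):
        with pytest.raises(ValueError):
            objective_f([])


class TestEligibility:
    def test_thresholds(self):
        def ia(i, studies):
            ev = EvidenceBundle()
            for s in studies:
                ev.add_record([s], ["two hybrid"], "db")
            return Interaction((f"A{i:03d}", f"B{i:03d}"), set(), ev)

        # study 1: 12 interactions, 3 of them multi-study -> eligible
        # study 2: 12 interactions, only 2 multi-study -> not eligible
        # study 3: 3 interactions -> too small
        ref = []
        for i in range(12):
            partner = [1, 4] if i < 3 else [1]
            ref.append(ia(i, partner))
        for i in range(12, 24):
            partner = [2, 4] if i < 14 else [2]
            ref.append(ia(i, partner))
        for i in range(24, 27):
            ref.append(ia(i, [3]))
        assert 1 in eligible_studies(ref)
        assert 2 not in eligible_studies(ref)
        assert 3 not in eligible_studies(ref)


def _recovery_reference(seed, **overrides):
    kw = dict(
        n_proteins=150, n_interactions=250, n_studies=16,
        study_multiplicity=dict(STRONG_REPRODUCIBILITY_MULTIPLICITY),
        genetic_interaction_rate=0.0, unmappable_rate=0.0, ortholog_only_rate=0.0,
        seed=seed,
    )
    kw.update(overrides)
    data = generate_sources(SyntheticSpec(**kw))
    return merge_sources(data.datasets, data.ortholog_records, data.mapping).interactions


class TestSelectParams:
    def test_single_combination_grid_returns_it(self, table):
        ref = _recovery_reference(5)
        g = ParamGrid(a_values=(2.3,), w_triples=((0.6, 0.1, 0.3),))
        # a single a-value grid means a_s = a_o = a_t; build accordingly
        report = select_params(ref, table, g)
        assert report.winner == ScoringParams(2.3, 2.3, 2.3, 0.6, 0.1, 0.3)
        assert len(report.records) == 1

    def test_degenerate_combination_excluded(self, table):
        # w_t = 0 discards technique granularity; with organisms rare the
        # score takes only a handful of values and the combination is culled
        ref = _recovery_reference(6, organism_evidence_rate=0.0)
        g = ParamGrid(a_values=(2.3,), w_triples=((0.7, 0.3, 0.0), (0.6, 0.1, 0.3)))
        report = select_params(ref, table, g)
        by_wt = {r.params.w_t: r for r in report.records}
        assert by_wt[0.0].degenerate
        assert not by_wt[0.3].degenerate
        assert report.winner.w_t == 0.3

    def test_all_degenerate_is_error(self, table):
        ref = _recovery_reference(6, organism_evidence_rate=0.0)
        g = ParamGrid(a_values=(2.3,), w_triples=((0.7, 0.3, 0.0),))
        with pytest.raises(ValueError, match="degenerate"):
            select_params(ref, table, g)

    def test_degeneracy_filter_keeps_published_default(self, table):
        ref = _recovery_reference(7)
        g = ParamGrid(
            a_values=(1.6, 2.3, 0.2), w_triples=((0.6, 0.1, 0.3),)
        )
        report = select_params(ref, table, g)
        rec = next(r for r in report.records
                   if r.params == DEFAULT_PARAMS)
        assert not rec.degenerate

    def test_planted_reproducibility_selects_positive_study_weight(self, table):
        ref = _recovery_reference(8)
        report = select_params(ref, table, reduced_grid(), keep_records=False)
        assert report.winner.w_s > 0
        assert report.winner_f > 1.0

    def test_fast_path_matches_object_level_loso(self, table):
        """The vectorized grid-search internals agree with the reference
        implementation built from loso_deviation + objective_f."""
        ref = _recovery_reference(9)
        studies = eligible_studies(ref)
        index = _HoldoutIndex(ref, studies, table)
        for params in [DEFAULT_PARAMS, ScoringParams(1.0, 1.0, 1.0, 0.2, 0.4, 0.4)]:
            f_fast, _ = index.evaluate(params)
            f_slow = objective_f(
                [loso_deviation(ref, s, params, table) for s in studies]
            )
            assert f_fast == pytest.approx(f_slow, abs=1e-12)
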