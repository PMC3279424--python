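"""Detectable subsets, stratified recall, and the one-sided Fisher test."""

import math
import random

import pytest

from ppiscore.evaluation import (
    ExternalScreen,
    detectable_subset,
    fisher_one_sided,
    stratified_recall,
)
from ppiscore.model import (
    EvidenceBundle,
    Interaction,
    ScoredInteraction,
    ScoredNetwork,
    canonical_pair,
)
from ppiscore.synthetic import generate_screen


def net_from(scored_pairs):
    out = []
    for (a, b), score in scored_pairs:
        key = canonical_pair(a, b)
        out.append(ScoredInteraction(Interaction(key, set(), EvidenceBundle()), score))
    return ScoredNetwork(out)


def make_net(n, frac_high, threshold, seed=0):
    """n interactions on a protein universe, frac_high of them >= threshold."""
    rng = random.Random(seed)
    pairs = []
    for i in range(n):
        a, b = f"P{2*i}", f"P{2*i+1}"
        high = rng.random() < frac_high
        score = rng.uniform(threshold, 0.99) if high else rng.uniform(0.0, threshold - 1e-6)
        pairs.append(((a, b), score))
    return net_from(pairs)


class TestDetectable:
    def test_all_proteins_baited_means_all_detectable(self):
        net = net_from([(("A", "B"), 0.5), (("C", "D"), 0.2)])
        screen = ExternalScreen(frozenset("ABCD"), frozenset())
        assert len(detectable_subset(net, screen)) == 2

    def test_pair_without_bait_excluded(self):
        net = net_from([(("A", "B"), 0.5), (("C", "D"), 0.2)])
        screen = ExternalScreen(frozenset("A"), frozenset())
        assert [si.key for si in detectable_subset(net, screen)] == [("A", "B")]

    def test_self_interaction_with_bait_included(self):
        net = net_from([(("A", "A"), 0.5)])
        screen = ExternalScreen(frozenset("A"), frozenset())
        assert len(detectable_subset(net, screen)) == 1

    def test_empty_bait_set_is_error(self):
        net = net_from([(("A", "B"), 0.5)])
        with pytest.raises(ValueError, match="no baits"):
            detectable_subset(net, ExternalScreen(frozenset(), frozenset()))

    def test_detected_pair_must_touch_a_bait(self):
        with pytest.raises(ValueError, match="no bait"):
            ExternalScreen(frozenset("A"), frozenset({("C", "D")}))


class TestFisher:
    def test_no_successes_gives_p_one(self):
        assert fisher_one_sided(0, 100, 0, 250) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            fisher_one_sided(5, 4, 0, 10)

    def test_p_nonincreasing_in_k_high(self):
        last = 1.1
        for k in range(0, 21):
            p = fisher_one_sided(k, 20, 5, 40)
            assert p <= last + 1e-15
            last = p

    def test_brute_force_hypergeometric_oracle(self):
        """Exact agreement with direct enumeration of the 2x2 tail."""

        def oracle(a, b, c, d):
            # P(A >= a) over tables with margins of [[a, b], [c, d]]
            r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

            def lchoose(m, k):
                return math.lgamma(m + 1) - math.lgamma(k + 1) - math.lgamma(m - k + 1)

            total = 0.0
            for x in range(max(0, c1 - r2), min(r1, c1) + 1):
                if x >= a:
                    total += math.exp(
                        lchoose(r1, x) + lchoose(r2, c1 - x) - lchoose(n, c1)
                    )
            return min(total, 1.0)

        rng = random.Random(0)
        cases = [(2, 8, 1, 12), (0, 5, 3, 5), (7, 7, 0, 9), (5, 20, 5, 20)]
        cases += [
            (rng.randint(0, 50), 50, rng.randint(0, 50), 50) for _ in range(30)
        ]
        cases += [
            (rng.randint(0, 15), rng.randint(15, 50), rng.randint(0, 15), rng.randint(15, 50))
            for _ in range(30)
        ]
        for k_h, n_h, k_l, n_l in cases:
            assert fisher_one_sided(k_h, n_h, k_l, n_l) == pytest.approx(
                oracle(k_h, n_h, k_l, n_l), rel=1e-9
            )


class TestStratifiedRecall:
    def test_hand_counted_example(self):
        net = net_from([
            (("A", "B"), 0.9), (("A", "C"), 0.8),   # high, detectable via A
            (("A", "D"), 0.3), (("A", "E"), 0.2),   # low, detectable via A
            (("X", "Y"), 0.95), (("X", "Z"), 0.1),  # not detectable
        ])
        screen = ExternalScreen(
            baits=frozenset("A"),
            detected_pairs=frozenset({("A", "B"), ("A", "D")}),
        )
        rep = stratified_recall(net, screen, 0.73)
        assert (rep.high.size, rep.high.detectable, rep.high.overlap) == (3, 2, 1)
        assert (rep.low.size, rep.low.detectable, rep.low.overlap) == (3, 2, 1)
        assert rep.high.recall == 0.5
        assert rep.fisher_p == pytest.approx(fisher_one_sided(1, 2, 1, 2))

    def test_threshold_ties_counted_in_high_stratum(self):
        net = net_from([(("A", "B"), 0.73), (("A", "C"), 0.7299)])
        screen = ExternalScreen(frozenset("A"), frozenset({("A", "B")}))
        rep = stratified_recall(net, screen, 0.73)
        assert rep.high.size == 1 and rep.high.overlap == 1
        assert rep.low.size == 1 and rep.low.overlap == 0

    def test_no_detected_pairs_gives_zero_recall(self):
        net = make_net(40, 0.25, 0.73, seed=1)
        screen = ExternalScreen(frozenset(net.proteins()), frozenset())
        rep = stratified_recall(net, screen, 0.73)
        assert rep.high.overlap == rep.low.overlap == 0
        assert rep.high.recall == rep.low.recall == 0.0

    def test_empty_stratum_reports_absent_recall(self):
        net = net_from([(("A", "B"), 0.9), (("A", "C"), 0.8),
                        (("D", "E"), 0.1)])
        screen = ExternalScreen(frozenset("A"), frozenset())
        rep = stratified_recall(net, screen, 0.5)
        assert rep.low.detectable == 0
        assert rep.low.recall is None
        assert rep.fisher_p is None

    def test_recall_pct_rounded_to_one_decimal(self):
        from ppiscore.evaluation import StratumStats

        s = StratumStats(label="x", size=100, detectable=2239, overlap=75)
        assert s.recall_pct == 3.3
        s = StratumStats(label="x", size=100, detectable=806, overlap=32)
        assert s.recall_pct == 4.0


class TestPlantedScreens:
    def test_planted_effect_direction_detected(self):
        """Screens planted with higher high-stratum recall at realistic
        stratum sizes yield overwhelmingly significant one-sided tests."""
        # detectable strata sized like the published evaluation (~2240 high,
        # ~5760 low): every protein baited, 28% of 8000 PPIs high-scoring
        net = make_net(8000, 0.28, 0.73, seed=3)
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            screen = generate_screen(net, high_recall=0.03, low_recall=0.008,
                                     threshold=0.73, seed=seed, bait_fraction=1.0)
            rep = stratified_recall(net, screen, 0.73)
            if rep.fisher_p is not None and rep.fisher_p < 0.001:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_null_screens_are_calibrated(self):
        """With equal planted recalls the one-sided p behaves like a
        (conservative, discrete) null p-value: P(p <= a) <= ~a."""
        net = make_net(600, 0.25, 0.73, seed=4)
        pvals = []
        for seed in range(100):
            screen = generate_screen(net, high_recall=0.05, low_recall=0.05,
                                     threshold=0.73, seed=seed, bait_fraction=0.9)
            rep = stratified_recall(net, screen, 0.73)
            if rep.fisher_p is not None:
                pvals.append(rep.fisher_p)
        frac_small = sum(1 for p in pvals if p <= 0.05) / len(pvals)
        assert frac_small <= 0.10
        assert sum(pvals) / len(pvals) > 0.3
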