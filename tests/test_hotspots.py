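"""Support counting, hotspot thresholds, and the Monte-Carlo shared-fraction null."""

import itertools

import numpy as np
import pytest

from breakome.genome_io import BreakPosition, BreakSet
from breakome.hotspots import (
    NullDistribution,
    build_support,
    call_hotspots,
    hotspot_fraction,
    hotspot_significance,
    overlap_odds_ratio,
    overlap_odds_ratio_counts,
    percentage,
    simulate_null,
    summarize_hotspot_gene_counts,
)


def _pos(label: str) -> BreakPosition:
    return BreakPosition("chr1", ord(label), "+")


def _replica(name, labels) -> BreakSet:
    return BreakSet(name, frozenset(_pos(l) for l in labels))


class TestSupport:
    def test_multiset_count(self):
        reps = [_replica("1", "AB"), _replica("2", "BC"), _replica("3", "BD")]
        sup = build_support(reps)
        got = {chr(p.coord): c for p, c in sup.counts.items()}
        assert got == {"A": 1, "B": 3, "C": 1, "D": 1}
        assert sum(sup.counts.values()) == sum(sup.replica_totals)

    def test_identical_replicas_all_max_support(self):
        reps = [_replica(str(i), "XYZ") for i in range(4)]
        assert set(build_support(reps).counts.values()) == {4}

    def test_disjoint_replicas_all_single(self):
        reps = [_replica("1", "AB"), _replica("2", "CD")]
        assert set(build_support(reps).counts.values()) == {1}

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_support([])


class TestCallHotspots:
    def test_threshold(self):
        sup = build_support([_replica("1", "AB"), _replica("2", "BC"), _replica("3", "BD")])
        hs = call_hotspots(sup, 2)
        assert {chr(p.coord) for p in hs} == {"B"}

    def test_k_below_two_rejected(self):
        sup = build_support([_replica("1", "A"), _replica("2", "A")])
        with pytest.raises(ValueError):
            call_hotspots(sup, 1)

    def test_nesting_over_random_replica_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            reps = [
                BreakSet(str(i), frozenset(
                    BreakPosition("chr1", int(c), "+")
                    for c in rng.integers(0, 30, rng.integers(1, 25))))
                for i in range(5)
            ]
            sup = build_support(reps)
            prev = None
            for k in range(2, 6):
                hs = call_hotspots(sup, k)
                if prev is not None:
                    assert hs.positions <= prev
                assert hotspot_fraction(sup, k) <= hotspot_fraction(sup, k - 1)
                prev = hs.positions


class TestHotspotFraction:
    def test_shared_over_union(self):
        sup = build_support([_replica("1", "AB"), _replica("2", "BC"), _replica("3", "BD")])
        assert hotspot_fraction(sup, 2) == 1 / 4

    def test_identical_replicas_fraction_one(self):
        sup = build_support([_replica("1", "AB"), _replica("2", "AB")])
        assert hotspot_fraction(sup, 2) == 1.0

    def test_disjoint_replicas_fraction_zero(self):
        sup = build_support([_replica("1", "A"), _replica("2", "B")])
        assert hotspot_fraction(sup, 2) == 0.0


class TestSimulateNull:
    def test_saturation(self):
        null = simulate_null(2, [4, 4], space_size=4, n_sim=10, seed=0)
        assert np.all(null.fractions == 1.0)

    def test_sparse_limit(self):
        null = simulate_null(3, [1, 1, 1], space_size=10**7, n_sim=50, seed=0)
        assert np.all(null.fractions == 0.0)

    def test_mean_matches_exhaustive_enumeration(self):
        # oracle: all C(4,2)^2 equally likely pairs of 2-subsets of 4 positions
        subsets = list(itertools.combinations(range(4), 2))
        fracs = []
        for a, b in itertools.product(subsets, subsets):
            overlap = len(set(a) & set(b))
            union = len(set(a) | set(b))
            fracs.append(overlap / union)
        oracle_mean = np.mean(fracs)
        null = simulate_null(2, [2, 2], space_size=4, n_sim=4000, seed=1)
        se = null.fractions.std(ddof=1) / np.sqrt(null.n_simulations)
        assert abs(null.fractions.mean() - oracle_mean) < 3 * se

    def test_deterministic_for_seed(self):
        a = simulate_null(2, [10, 10], 100, n_sim=5, seed=3)
        b = simulate_null(2, [10, 10], 100, n_sim=5, seed=3)
        assert np.array_equal(a.fractions, b.fractions)


class TestSignificance:
    def test_observation_at_null_mean_not_significant(self):
        null = NullDistribution(np.array([0.09, 0.10, 0.11, 0.10]), 4, 100, None)
        t, p, deg = hotspot_significance(0.10, null)
        assert not deg
        assert p > 0.95

    def test_far_observation_extremely_significant(self):
        rng = np.random.default_rng(0)
        null = NullDistribution(0.01 + 0.001 * rng.standard_normal(100), 100, 10**6, 0)
        t, p, deg = hotspot_significance(0.5, null)
        # cross-check against the t statistic recomputed from mean/sd
        x = null.fractions
        t_manual = (x.mean() - 0.5) / (x.std(ddof=1) / np.sqrt(len(x)))
        assert t == pytest.approx(t_manual)
        assert p < 1e-10

    def test_degenerate_constant_null(self):
        null = NullDistribution(np.full(10, 0.1), 10, 100, None)
        _, p, deg = hotspot_significance(0.1, null)
        assert deg and p == 1.0
        _, p2, deg2 = hotspot_significance(0.2, null)
        assert deg2 and p2 < 1e-300


class TestOverlapOddsRatio:
    def test_expectation_case(self):
        _, odds, p = overlap_odds_ratio_counts(100, 100, 1, 10_000)
        assert odds == 1.0
        assert p > 0.5

    def test_disjoint_sets(self):
        a = [BreakPosition("chr1", i, "+") for i in range(5)]
        b = [BreakPosition("chr1", i, "+") for i in range(10, 15)]
        observed, odds, _ = overlap_odds_ratio(a, b, 1000)
        assert observed == 0 and odds == 0.0

    def test_set_and_count_paths_agree(self):
        a = [BreakPosition("chr1", i, "+") for i in range(20)]
        b = [BreakPosition("chr1", i, "+") for i in range(10, 40)]
        assert overlap_odds_ratio(a, b, 500) == overlap_odds_ratio_counts(20, 30, 10, 500)


class TestGeneCountSummary:
    def test_reported_percentages(self):
        # 2,147 genes: 1,510 with one hotspot, 399 with two, 195 with 3-5, 43 with >5
        counts = {}
        i = 0
        for n, c in ((1510, 1), (399, 2), (195, 4), (43, 7)):
            for _ in range(n):
                counts[f"g{i}"] = c
                i += 1
        table = summarize_hotspot_gene_counts(counts).set_index("hotspot_count")
        assert table.loc["1", "percentage"] == 70.3
        assert table.loc["2", "percentage"] == 18.6
        assert table.loc[">5", "percentage"] == 2.0
        assert table["n_genes"].sum() == 2147

    def test_all_single_hotspot(self):
        table = summarize_hotspot_gene_counts({"a": 1, "b": 1}).set_index("hotspot_count")
        assert table.loc["1", "percentage"] == 100.0

    def test_rounding_is_half_up(self):
        assert percentage(1, 8) == 12.5
        assert percentage(150052, 11532044) == 1.3
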