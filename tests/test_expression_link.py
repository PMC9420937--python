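"""Expression strata, expected fractions from random breaks, and O/E odds ratios."""

import numpy as np
import pandas as pd
import pytest

from breakome.expression_link import (
    compare_or_series,
    expected_fractions,
    expression_odds_ratios,
    observed_fractions,
    rank_strata,
)
from breakome.genome_io import GenomeModel
from breakome.synthetic_data import (
    SimulationConfig,
    generate_annotation,
    generate_breakome,
    generate_genome,
)
from breakome.tss_model import TssRecord, assign_tss, call_cage_peaks, merge_cage


def _expr(values):
    return pd.DataFrame({"gene_id": [f"g{i:03d}" for i in range(len(values))],
                         "mean_fpkm": values})


class TestRankStrata:
    def test_sizes_and_nesting(self):
        rng = np.random.default_rng(0)
        strata = rank_strata(_expr(rng.lognormal(size=100)))
        assert [len(strata[f]) for f in (0.05, 0.10, 0.25, 0.50)] == [5, 10, 25, 50]
        assert strata[0.05] <= strata[0.10] <= strata[0.25] <= strata[0.50]

    def test_ties_break_deterministically(self):
        a = rank_strata(_expr([1.0] * 40))
        b = rank_strata(_expr([1.0] * 40))
        assert a == b
        assert len(a[0.05]) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_strata(_expr([]))


class TestExpectedFractions:
    def test_matches_window_length_arithmetic(self):
        # one TSS on a repeat-free genome: the within-200 fraction of uniform
        # stranded positions is the closed-window share 401/L
        L = 100_000
        g = GenomeModel([("chr1", L)])
        tss = {0.5: [TssRecord("g0", "chr1", "+", 50_000, 50_000, 5)]}
        df = expected_fractions(200_000, g, tss, seed=1).set_index("stratum")
        expect_inner = 401 / L
        expect_annulus = (10_001 - 401) / L
        got_inner = float(df.loc[0.5, "within_200"])
        got_annulus = float(df.loc[0.5, "annulus_200_5000"])
        assert got_inner == pytest.approx(expect_inner, rel=0.15)
        assert got_annulus == pytest.approx(expect_annulus, rel=0.05)

    def test_same_seed_identical(self):
        g = GenomeModel([("chr1", 50_000)])
        tss = {0.5: [TssRecord("g0", "chr1", "+", 25_000, 25_000, 5)]}
        a = expected_fractions(10_000, g, tss, seed=3)
        b = expected_fractions(10_000, g, tss, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestOddsRatios:
    def test_identity_and_null(self, neutral_run):
        """Positions drawn by the generator's neutral process give ORs near 1."""
        ann, genome, tss = neutral_run["ann"], neutral_run["genome"], neutral_run["tss"]
        strata = rank_strata(ann.expression)
        tss_strata = {f: [t for t in tss if t.gene_id in gs] for f, gs in strata.items()}
        expected = expected_fractions(400_000, genome, tss_strata, seed=9)
        pooled = sorted(frozenset().union(*(r.positions for r in neutral_run["replicas"])))
        df = expression_odds_ratios(pooled, tss_strata, expected)
        for _, row in df.iterrows():
            assert row["odds_ratio"] == pytest.approx(
                row["observed"] / row["expected"])
        wide = df[(df["distance_bin"] == "annulus_200_5000")]
        assert ((wide["odds_ratio"] > 0.85) & (wide["odds_ratio"] < 1.15)).all()

    def test_planted_top_stratum_boost_gives_monotone_ors(self, neutral_run):
        """3x promoter weight on top-5% genes only: OR decreases top5 -> top50."""
        ann, genome = neutral_run["ann"], neutral_run["genome"]
        strata = rank_strata(ann.expression)
        mult = {g.gene_id: (3.0 if g.gene_id in strata[0.05] else 1.0)
                for g in ann.genes}
        cfg = SimulationConfig(seed=404, n_replicas=1, tss_enrichment_factor=1.0,
                               hotspot_gain=1.0, cytosine_bias=0.0,
                               expression_coupling=0.0)
        reps, _ = generate_breakome(cfg, genome, ann.genes, gene_multipliers=mult)
        tss = neutral_run["tss"]
        tss_strata = {f: [t for t in tss if t.gene_id in gs] for f, gs in strata.items()}
        expected = expected_fractions(400_000, genome, tss_strata, seed=10)
        df = expression_odds_ratios(sorted(reps[0].positions), tss_strata, expected)
        inner = df[df["distance_bin"] == "within_200"].sort_values("stratum")
        ors = inner["odds_ratio"].tolist()
        assert ors == sorted(ors, reverse=True)
        assert ors[0] > 1.5

    def test_decoupled_expression_shows_no_systematic_ordering(self):
        """With expression_coupling = 0, strict OR ordering across the 4 strata
        should occur at chance rate (1/24 per simulation)."""
        ordered = 0
        for i in range(6):
            cfg = SimulationConfig(seed=500 + i, n_chromosomes=1,
                                   chromosome_length=2_000_000, n_genes=100,
                                   n_replicas=1, breaks_per_replica=20_000,
                                   tss_enrichment_factor=1.0, hotspot_gain=1.0,
                                   cytosine_bias=0.0, expression_coupling=0.0)
            g = generate_genome(cfg)
            ann = generate_annotation(cfg, g)
            reps, _ = generate_breakome(cfg, g, ann.genes, ann.gene_truth)
            peaks = call_cage_peaks(merge_cage([ann.cage_tags]))
            tss = assign_tss(ann.genes, peaks)
            strata = rank_strata(ann.expression)
            tss_strata = {f: [t for t in tss if t.gene_id in gs]
                          for f, gs in strata.items()}
            expected = expected_fractions(100_000, g, tss_strata, seed=600 + i)
            df = expression_odds_ratios(sorted(reps[0].positions), tss_strata, expected)
            inner = df[df["distance_bin"] == "within_200"].sort_values("stratum")
            ors = inner["odds_ratio"].tolist()
            if ors == sorted(ors, reverse=True) and len(set(ors)) == len(ors):
                ordered += 1
        assert ordered <= 2  # P(>=3 of 6 strictly ordered | null) < 1e-3


class TestCompareSeries:
    def test_identical_series_symmetric_null(self):
        assert compare_or_series([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_large_shift_significant(self):
        a = [10.0, 10.1, 9.9, 10.05]
        b = [1.0, 1.1, 0.9, 1.05]
        assert compare_or_series(a, b) < 0.01

    def test_swapped_arguments_complement(self):
        a = [1.0, 1.2, 1.4, 1.1]
        b = [0.9, 1.0, 1.3, 1.2]
        p = compare_or_series(a, b)
        assert compare_or_series(b, a) == pytest.approx(1.0 - p)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            compare_or_series([1.0], [1.0, 2.0])
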