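"""Distance signing, NR_j normalization, D_ij densities and the R statistic."""

import numpy as np
import pytest

from breakome.genome_io import BreakPosition, GenomeModel
from breakome.tss_enrichment import (
    build_bin_grid,
    compare_ratio_groups,
    density_profile,
    enrichment_from_counts,
    enrichment_ratio,
    nearest_tss_distance,
    nearest_tss_distances,
)
from breakome.tss_model import TssRecord


def _tss(coord, strand="+", gene_id="g", chrom="chr1"):
    return TssRecord(gene_id, chrom, strand, coord, coord, 5)


class TestNearestDistance:
    def test_break_at_tss_is_zero(self):
        d, gene, _ = nearest_tss_distance(BreakPosition("chr1", 500, "+"), [_tss(500)])
        assert d == 0 and gene == "g"

    def test_sign_follows_gene_orientation(self):
        # 100 bp toward the gene's 5' side: genomically left of a + gene,
        # genomically right of a - gene
        d_plus, _, _ = nearest_tss_distance(BreakPosition("chr1", 400, "+"),
                                            [_tss(500, "+")])
        assert d_plus == -100
        d_minus, _, _ = nearest_tss_distance(BreakPosition("chr1", 400, "+"),
                                             [_tss(500, "-")])
        assert d_minus == +100

    def test_absolute_shortest_distance_kept(self):
        tss_set = [_tss(1000, gene_id="far"), _tss(1550, gene_id="near")]
        d, gene, _ = nearest_tss_distance(BreakPosition("chr1", 1300, "+"), tss_set)
        assert (abs(d), gene) == (250, "near")

    def test_chromosome_without_tss_returns_none(self):
        assert nearest_tss_distance(BreakPosition("chr2", 5, "+"), [_tss(10)]) is None


class TestBinGrid:
    def test_no_repeats_gives_unit_ratios(self):
        g = GenomeModel([("chr1", 20_000)])
        grid = build_bin_grid([_tss(10_000)], g, window=5000)
        assert grid.n_bins == 500
        assert np.all(grid.nr == 1.0)

    def test_repeat_covering_half_a_bin(self):
        g = GenomeModel([("chr1", 20_000)], repeats={"chr1": [(10_000, 10_010)]})
        grid = build_bin_grid([_tss(10_000)], g, window=5000)
        j0 = 250  # bin covering offsets [0, 20)
        assert grid.nr[j0] == 0.5
        assert np.all(np.delete(grid.nr, j0) == 1.0)

    def test_average_over_masked_and_clean_gene(self):
        g = GenomeModel([("chr1", 40_000)], repeats={"chr1": [(5_000, 15_001)]})
        grid = build_bin_grid([_tss(10_000, gene_id="masked"),
                               _tss(30_000, gene_id="clean")], g, window=5000)
        assert np.all(grid.nr == 0.5)

    def test_minus_strand_gene_mirrors_bins(self):
        # repeat strictly 3' of a minus-strand TSS: downstream = lower coordinates;
        # genomic [9961, 9981) maps to oriented offsets 20..39, i.e. exactly bin 251
        g = GenomeModel([("chr1", 20_000)], repeats={"chr1": [(9_961, 9_981)]})
        grid = build_bin_grid([_tss(10_000, "-")], g, window=5000)
        masked = np.flatnonzero(grid.nr < 1.0)
        assert masked.tolist() == [251]
        assert grid.nr[251] == 0.0


class TestDensityProfile:
    def test_formula_single_position(self):
        g = GenomeModel([("chr1", 20_000)])
        grid = build_bin_grid([_tss(10_000)], g, window=5000)
        pos = [BreakPosition("chr1", 10_005, "+")]  # non-template for a + gene
        profs = density_profile(pos, [_tss(10_000)], grid, total_positions=10)
        nt = profs["non-template"]
        j = (5 + 5000) // 20
        assert nt.counts[j] == 1
        assert nt.densities[j] == pytest.approx(1e6 / (1.0 * 10))
        assert profs["template"].counts.sum() == 0

    def test_doubling_t_halves_density(self):
        g = GenomeModel([("chr1", 20_000)])
        tss = [_tss(10_000)]
        grid = build_bin_grid(tss, g, window=5000)
        pos = [BreakPosition("chr1", 10_005, "+"), BreakPosition("chr1", 9_800, "+")]
        d1 = density_profile(pos, tss, grid, total_positions=10)["non-template"].densities
        d2 = density_profile(pos, tss, grid, total_positions=20)["non-template"].densities
        assert np.allclose(np.nan_to_num(d2), np.nan_to_num(d1) / 2)

    def test_counts_sum_to_in_window_positions(self, neutral_run):
        tss = neutral_run["tss"]
        grid = build_bin_grid(tss, neutral_run["genome"])
        pos = sorted(neutral_run["replicas"][0].positions)[:20_000]
        profs = density_profile(pos, tss, grid)
        df = nearest_tss_distances(pos, tss)
        in_window = int(((df["distance"] >= -5000) & (df["distance"] < 5000)).sum())
        assert sum(p.counts.sum() for p in profs.values()) == in_window


class TestEnrichmentRatio:
    def test_formula_arithmetic(self):
        r = enrichment_from_counts(20, 100, 4_000, 100_000)
        assert r.ratio == pytest.approx(5.0)

    def test_recomputation_identity(self, neutral_run):
        r = enrichment_ratio(sorted(neutral_run["replicas"][0].positions),
                             neutral_run["tss"], neutral_run["genome"])
        assert r.ratio == pytest.approx(
            (r.m_inner / r.m_outer) / (r.l_inner / r.l_outer))
        assert r.m_inner <= r.m_outer and r.l_inner <= r.l_outer

    def test_adding_inner_breaks_never_decreases_r(self):
        g = GenomeModel([("chr1", 20_000)])
        tss = [_tss(10_000)]
        rng = np.random.default_rng(5)
        pos = [BreakPosition("chr1", int(c), "+")
               for c in rng.integers(5_000, 15_000, 300)]
        r0 = enrichment_ratio(pos, tss, g).ratio
        extra = [BreakPosition("chr1", int(c), "-")
                 for c in rng.integers(9_800, 10_201, 50)]
        r1 = enrichment_ratio(pos + extra, tss, g).ratio
        assert r1 >= r0

    def test_reflection_invariance(self):
        """Mirroring the genome (coordinates and strands) leaves R and D unchanged."""
        L = 20_000
        g = GenomeModel([("chr1", L)], repeats={"chr1": [(8_000, 8_500)]})
        g_ref = GenomeModel([("chr1", L)], repeats={"chr1": [(L - 8_500, L - 8_000)]})
        tss = [_tss(10_000, "+")]
        tss_ref = [_tss(L - 1 - 10_000, "-")]
        rng = np.random.default_rng(8)
        pos = [BreakPosition("chr1", int(c), "+-"[int(s)])
               for c, s in zip(rng.integers(5_000, 15_000, 400), rng.integers(0, 2, 400))]
        pos_ref = [BreakPosition("chr1", L - 1 - p.coord, "+" if p.strand == "-" else "-")
                   for p in pos]
        r = enrichment_ratio(pos, tss, g)
        r_ref = enrichment_ratio(pos_ref, tss_ref, g_ref)
        assert (r.m_inner, r.m_outer, r.l_inner, r.l_outer) == \
               (r_ref.m_inner, r_ref.m_outer, r_ref.l_inner, r_ref.l_outer)
        grid = build_bin_grid(tss, g)
        grid_ref = build_bin_grid(tss_ref, g_ref)
        assert np.allclose(grid.nr, grid_ref.nr)
        for sc in ("template", "non-template"):
            d = density_profile(pos, tss, grid)[sc]
            d_ref = density_profile(pos_ref, tss_ref, grid_ref)[sc]
            assert np.array_equal(d.counts, d_ref.counts)


class TestCompareRatioGroups:
    def test_identical_groups_p_one(self):
        p = compare_ratio_groups({"dmso": [1.0, 1.1, 0.9], "drug": [1.0, 1.1, 0.9]},
                                 reference="dmso")
        assert p["drug"] == pytest.approx(1.0)

    def test_large_shift_detected(self):
        p = compare_ratio_groups({"dmso": [1.0, 1.05, 0.95, 1.02],
                                  "drug": [3.0, 3.05, 2.95, 3.02]}, reference="dmso")
        assert p["drug"] < 0.01

    def test_one_pvalue_per_treatment(self):
        groups = {"dmso": [1.0, 1.1], "a": [1.2, 1.3], "b": [0.8, 0.9], "c": [1.0, 1.2]}
        assert set(compare_ratio_groups(groups, "dmso")) == {"a", "b", "c"}

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_ratio_groups({"dmso": [1.0, 1.1], "drug": [1.0]}, "dmso")
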