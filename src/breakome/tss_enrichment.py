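"""Signed distance to the nearest TSS, normalized metagene profiles, and the
TSS-SSB enrichment ratio.

The +/-5,000 bp region around each operative TSS is split into 500
non-overlapping 20-bp bins in *gene orientation* (negative offsets upstream,
positive downstream).  The average non-repeat ratio of bin j over the n
expressed genes is

    NR_j = (sum_k LNR_kj / 20) / n,

and the normalized break density of sample i in bin j is

    D_ij = N_ij * 1e6 / (NR_j * T_i),

with N_ij the number of break positions whose nearest-TSS signed distance
falls in bin j and T_i the sample's total number of positions.  The
enrichment ratio of the immediate TSS vicinity over the +/-5,000 bp
background is

    R_i = (M_i^200 / M_i^5000) / (L^200 / L^5000),

where M are position counts within +/-200 / +/-5,000 bp (|d| inclusive) and
L are the per-gene summed non-repeat lengths of the matching windows; its
p-value comes from a two-sided binomial test conditioned on M_i^5000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import BreakPosition, GenomeModel
from .tss_model import TEMPLATE, NON_TEMPLATE, TssRecord

__all__ = ["BinGrid", "DensityProfile", "EnrichmentResult",
           "nearest_tss_distance", "nearest_tss_distances", "build_bin_grid",
           "density_profile", "enrichment_ratio", "enrichment_from_counts",
           "compare_ratio_groups"]


@dataclass(frozen=True)
class BinGrid:
    window: int
    bin_width: int
    nr: np.ndarray  # NR_j, length n_bins
    n_genes: int

    @property
    def n_bins(self) -> int:
        return len(self.nr)

    @property
    def offsets(self) -> np.ndarray:
        """Left edge of each bin in gene-oriented coordinates."""
        return -self.window + self.bin_width * np.arange(self.n_bins)


@dataclass(frozen=True)
class DensityProfile:
    sample_id: str
    strand_class: str
    counts: np.ndarray       # N_ij
    densities: np.ndarray    # D_ij (NaN where NR_j = 0)
    total_positions: int     # T_i
    grid: BinGrid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.sample_id,
            "strand_class": self.strand_class,
            "bin": np.arange(1, self.grid.n_bins + 1),
            "offset": self.grid.offsets,
            "N": self.counts,
            "NR": self.grid.nr,
            "T": self.total_positions,
            "D": self.densities,
        })


@dataclass(frozen=True)
class EnrichmentResult:
    sample_id: str
    strand_class: str        # template / non-template / combined
    m_inner: int             # M^200
    m_outer: int             # M^5000
    l_inner: int             # L^200
    l_outer: int             # L^5000
    ratio: float             # R
    pvalue: float


def _tss_index(tss_set: Sequence[TssRecord]):
    by_chrom: dict[str, tuple[np.ndarray, list[TssRecord]]] = {}
    for chrom in {t.chrom for t in tss_set}:
        recs = sorted((t for t in tss_set if t.chrom == chrom),
                      key=lambda t: t.operative_tss)
        coords = np.array([t.operative_tss for t in recs], dtype=np.int64)
        by_chrom[chrom] = (coords, recs)
    return by_chrom


def nearest_tss_distances(positions: Iterable[BreakPosition],
                          tss_set: Sequence[TssRecord]) -> pd.DataFrame:
    """Signed nearest-TSS distance and strand class for every position.

    The absolute shortest distance wins; positions 5' of the TSS in gene
    orientation get negative distances, 3' positive.  Equidistant ties break
    toward the lower genomic coordinate.  Positions on chromosomes without
    any TSS are omitted.
    """
    index = _tss_index(tss_set)
    rows = []
    by_chrom: dict[str, list[BreakPosition]] = {}
    for p in positions:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, plist in by_chrom.items():
        if chrom not in index:
            continue
        coords, recs = index[chrom]
        pos = np.array([p.coord for p in plist], dtype=np.int64)
        i = np.searchsorted(coords, pos)
        left = np.clip(i - 1, 0, len(coords) - 1)
        right = np.clip(i, 0, len(coords) - 1)
        dl = np.where(i > 0, np.abs(pos - coords[left]), np.iinfo(np.int64).max)
        dr = np.where(i < len(coords), np.abs(coords[right] - pos), np.iinfo(np.int64).max)
        pick = np.where(dl <= dr, left, right)
        for p, j in zip(plist, pick.tolist()):
            rec = recs[j]
            d_gen = p.coord - rec.operative_tss
            signed = d_gen if rec.strand == "+" else -d_gen
            strand_class = NON_TEMPLATE if p.strand == rec.strand else TEMPLATE
            rows.append((p.chrom, p.coord, p.strand, signed, rec.gene_id, strand_class))
    return pd.DataFrame(rows, columns=["chrom", "coord", "strand", "distance",
                                       "gene_id", "strand_class"])


def nearest_tss_distance(position: BreakPosition, tss_set: Sequence[TssRecord]):
    """Scalar convenience wrapper; returns None off any TSS-bearing chromosome."""
    df = nearest_tss_distances([position], tss_set)
    if df.empty:
        return None
    row = df.iloc[0]
    return int(row["distance"]), row["gene_id"], row["strand_class"]


def build_bin_grid(tss_set: Sequence[TssRecord], genome: GenomeModel,
                   window: int = 5000, bin_width: int = 20) -> BinGrid:
    """Average per-bin non-repeat ratio NR_j over all expressed genes.

    Bin j (1-based) covers gene-oriented offsets [-window + bw*(j-1),
    -window + bw*j); the bin containing the TSS base starts at offset 0.
    Bases beyond a chromosome end count as non-usable (LNR excludes them).
    """
    if not tss_set:
        raise ValueError("no expressed genes")
    n_bins = 2 * window // bin_width
    edges = -window + bin_width * np.arange(n_bins + 1, dtype=np.int64)
    total = np.zeros(n_bins, dtype=float)
    for rec in tss_set:
        t = rec.operative_tss
        if rec.strand == "+":
            starts = t + edges[:-1]
            ends = t + edges[1:]
        else:  # offset o -> genomic t - o; [a, b) maps to [t-b+1, t-a+1)
            starts = t - edges[1:] + 1
            ends = t - edges[:-1] + 1
        lnr = genome.nonrepeat_lengths(rec.chrom, starts, ends)
        total += lnr / bin_width
    return BinGrid(window=window, bin_width=bin_width, nr=total / len(tss_set),
                   n_genes=len(tss_set))


def density_profile(positions: Iterable[BreakPosition], tss_set: Sequence[TssRecord],
                    grid: BinGrid, total_positions: int | None = None,
                    sample_id: str = "sample") -> dict[str, DensityProfile]:
    """Per-strand-class normalized density profiles D_ij.

    ``total_positions`` (T_i) defaults to the sample's genome-wide position
    count.  Bins with NR_j = 0 are reported as NaN, not zero.
    """
    positions = list(positions)
    if total_positions is None:
        total_positions = len(positions)
    if total_positions == 0:
        raise ValueError("T_i must be positive")
    df = nearest_tss_distances(positions, tss_set)
    out: dict[str, DensityProfile] = {}
    for strand_class in (TEMPLATE, NON_TEMPLATE):
        sub = df[df["strand_class"] == strand_class]
        d = sub["distance"].to_numpy()
        in_grid = (d >= -grid.window) & (d < grid.window)
        bins = (d[in_grid] + grid.window) // grid.bin_width
        counts = np.bincount(bins.astype(np.int64), minlength=grid.n_bins).astype(np.int64)
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(grid.nr > 0,
                            counts * 1e6 / (grid.nr * total_positions), np.nan)
        out[strand_class] = DensityProfile(sample_id, strand_class, counts, dens,
                                           total_positions, grid)
    return out


def _window_lengths(tss_set: Sequence[TssRecord], genome: GenomeModel,
                    half_width: int) -> int:
    """Per-gene summed non-repeat bases in the closed +/-half_width window."""
    total = 0
    by_chrom: dict[str, list[int]] = {}
    for rec in tss_set:
        by_chrom.setdefault(rec.chrom, []).append(rec.operative_tss)
    for chrom, coords in by_chrom.items():
        c = np.asarray(coords, dtype=np.int64)
        total += int(genome.nonrepeat_lengths(chrom, c - half_width, c + half_width + 1).sum())
    return total


def enrichment_ratio(positions: Iterable[BreakPosition], tss_set: Sequence[TssRecord],
                     genome: GenomeModel, inner: int = 200, outer: int = 5000,
                     strand_class: str | None = None,
                     sample_id: str = "sample") -> EnrichmentResult:
    """TSS-SSB enrichment ratio R_i with its two-sided binomial p-value.

    ``strand_class`` restricts the counted positions to template or
    non-template matches; None pools both strands.
    """
    df = nearest_tss_distances(positions, tss_set)
    if strand_class is not None:
        df = df[df["strand_class"] == strand_class]
    d = df["distance"].abs().to_numpy()
    m_inner = int((d <= inner).sum())
    m_outer = int((d <= outer).sum())
    l_inner = _window_lengths(tss_set, genome, inner)
    l_outer = _window_lengths(tss_set, genome, outer)
    return enrichment_from_counts(m_inner, m_outer, l_inner, l_outer,
                                  sample_id=sample_id,
                                  strand_class=strand_class or "combined")


def enrichment_from_counts(m_inner: int, m_outer: int, l_inner: int, l_outer: int,
                           sample_id: str = "sample",
                           strand_class: str = "combined") -> EnrichmentResult:
    """R and its binomial p-value from already-tallied counts and lengths."""
    if l_outer == 0:
        raise ValueError("no non-repeat sequence in the outer windows")
    if m_outer == 0:
        ratio, p = float("nan"), float("nan")
    else:
        ratio = (m_inner / m_outer) / (l_inner / l_outer)
        p = stats.binomtest(m_inner, n=m_outer, p=l_inner / l_outer).pvalue
    return EnrichmentResult(sample_id, strand_class,
                            m_inner, m_outer, l_inner, l_outer, ratio, float(p))


def compare_ratio_groups(group_ratios: Mapping[str, Sequence[float]],
                         reference: str) -> dict[str, float]:
    """Welch t-test (two-sided) of each treatment's per-sample R values vs the reference."""
    if reference not in group_ratios:
        raise ValueError(f"reference group {reference!r} missing")
    ref = np.asarray(group_ratios[reference], dtype=float)
    if len(ref) < 2:
        raise ValueError("reference group needs at least 2 values")
    pvals: dict[str, float] = {}
    for name, values in group_ratios.items():
        if name == reference:
            continue
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
        if np.ptp(v) == 0 and np.ptp(ref) == 0:
            pvals[name] = 1.0 if v[0] == ref[0] else 0.0
            continue
        pvals[name] = float(stats.ttest_ind(v, ref, equal_var=False).pvalue)
    return pvals
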