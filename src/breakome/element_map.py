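"""Hierarchical assignment of breaks/hotspots to 7 genomic element classes.

Classes, consulted strictly in order: (1) within +/-200 bp of an operative
TSS; (2) within +/-200 bp of any CAGE peak; (3) chromatin-state promoters;
(4) within +/-200 bp of a TTS (3' end of the longest transcript, all
annotated genes); (5) exonic; (6) intronic; (7) intergenic (the complement).
Each position gets exactly one class: the first whose interval set contains
its coordinate.  Per-class enrichment is the odds ratio

    OR_i = (M_i / T_i) / (L_i / LG)

with a two-sided binomial test (x = M_i, n = T_i, p = L_i / LG); L_i is the
non-repeat length of the element class and LG the genome's non-repeat length.
By default L_i is measured on each class's own interval set; the
priority-disjoint variant (each class minus all higher-priority classes,
under which uniform breaks give OR = 1 for every class) is available via
``disjoint_lengths=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    BreakPosition,
    GeneRecord,
    GenomeModel,
    IntervalArrays,
    interval_complement,
    interval_subtract,
    interval_union,
    merge_intervals,
)
from .tss_model import CageTag, TssRecord

__all__ = ["CLASS_NAMES", "ElementHierarchy", "OddsRatioResult", "build_hierarchy",
           "assign_elements", "element_odds_ratio", "element_enrichment"]

CLASS_NAMES = ("tss", "cage_peak", "promoter", "tts", "exonic", "intronic", "intergenic")

ChromIntervals = dict[str, IntervalArrays]


@dataclass(frozen=True)
class OddsRatioResult:
    element: str
    m: int          # M_i: positions in the class
    t: int          # T_i: total positions
    l: int          # L_i: non-repeat length of the class
    lg: int         # LG
    odds_ratio: float
    pvalue: float
    infinite: bool = False


class ElementHierarchy:
    def __init__(self, genome: GenomeModel, class_intervals: Mapping[str, ChromIntervals]):
        self.genome = genome
        self.classes: dict[str, ChromIntervals] = {n: dict(class_intervals.get(n, {}))
                                                   for n in CLASS_NAMES[:-1]}
        # intergenic = complement of the union of classes 1-6, per chromosome
        inter: ChromIntervals = {}
        for chrom, length in genome.chromosomes.items():
            sets = [self.classes[n][chrom] for n in CLASS_NAMES[:-1]
                    if chrom in self.classes[n]]
            union = interval_union(sets) if sets else merge_intervals([])
            inter[chrom] = interval_complement(union, length)
        self.classes["intergenic"] = inter
        self.lengths = {n: genome.nonrepeat_length_of(self.classes[n]) for n in CLASS_NAMES}
        self.disjoint_lengths = self._disjoint_lengths()
        self.lg = genome.LG

    def _disjoint_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        claimed: ChromIntervals = {c: merge_intervals([]) for c in self.genome.chromosomes}
        for name in CLASS_NAMES:
            own = self.classes[name]
            disjoint: ChromIntervals = {}
            for chrom, length in self.genome.chromosomes.items():
                if chrom not in own:
                    continue
                disjoint[chrom] = interval_subtract(own[chrom], claimed[chrom], length)
                claimed[chrom] = interval_union([claimed[chrom], own[chrom]])
            out[name] = self.genome.nonrepeat_length_of(disjoint)
        return out

    def length(self, name: str, disjoint: bool = False) -> int:
        return self.disjoint_lengths[name] if disjoint else self.lengths[name]


def _window_set(coords_by_chrom: Mapping[str, Sequence[int]], genome: GenomeModel,
                half_width: int = 200) -> ChromIntervals:
    out: ChromIntervals = {}
    for chrom, coords in coords_by_chrom.items():
        L = genome.chromosomes[chrom]
        ivs = [(max(c - half_width, 0), min(c + half_width + 1, L)) for c in coords]
        out[chrom] = merge_intervals(ivs)
    return out


def build_hierarchy(tss_set: Sequence[TssRecord], cage_peaks: Sequence[CageTag],
                    promoter_intervals: ChromIntervals | None,
                    genes: Sequence[GeneRecord], genome: GenomeModel,
                    window: int = 200) -> ElementHierarchy:
    """Assemble the 7-class interval hierarchy on one genome.

    TTS/exon/intron come from the longest transcript of every annotated gene
    irrespective of expression; class 1 uses operative TSSs of expressed
    genes; class 2 all called CAGE peaks.  Missing inputs leave a class empty
    (with a warning).
    """
    def group(coords: Iterable[tuple[str, int]]):
        d: dict[str, list[int]] = {}
        for chrom, c in coords:
            d.setdefault(chrom, []).append(c)
        return d

    classes: dict[str, ChromIntervals] = {}
    for name, items in (("tss", [(t.chrom, t.operative_tss) for t in tss_set]),
                        ("cage_peak", [(p.chrom, p.coord) for p in cage_peaks]),
                        ("tts", [(g.chrom, g.tts) for g in genes])):
        if not items:
            warnings.warn(f"no input for element class {name!r}; built empty")
            classes[name] = {}
        else:
            classes[name] = _window_set(group(items), genome, window)
    if promoter_intervals:
        classes["promoter"] = {c: merge_intervals(zip(s.tolist(), e.tolist()))
                               for c, (s, e) in promoter_intervals.items()}
    else:
        warnings.warn("no promoter intervals; class built empty")
        classes["promoter"] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    introns: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        exons.setdefault(g.chrom, []).extend(g.exons)
        span = merge_intervals([(g.start, g.end)])
        intr = interval_subtract(span, merge_intervals(g.exons), genome.chromosomes[g.chrom])
        introns.setdefault(g.chrom, []).extend(zip(intr[0].tolist(), intr[1].tolist()))
    classes["exonic"] = {c: merge_intervals(iv) for c, iv in exons.items()}
    classes["intronic"] = {c: merge_intervals(iv) for c, iv in introns.items()}
    return ElementHierarchy(genome, classes)


def assign_elements(positions: Iterable[BreakPosition], hierarchy: ElementHierarchy
                    ) -> tuple[dict[str, int], list[str]]:
    """First matching class in hierarchy order wins; counts partition the total."""
    positions = list(positions)
    labels = np.full(len(positions), CLASS_NAMES[-1], dtype=object)
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(positions):
        by_chrom.setdefault(p.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        coords = np.array([positions[i].coord for i in idx], dtype=np.int64)
        assigned = np.zeros(len(idx), dtype=bool)
        for name in CLASS_NAMES[:-1]:
            ivs = hierarchy.classes[name].get(chrom)
            if ivs is None or len(ivs[0]) == 0:
                continue
            starts, ends = ivs
            j = np.searchsorted(starts, coords, side="right") - 1
            inside = (j >= 0) & (coords < ends[np.clip(j, 0, None)])
            hit = inside & ~assigned
            labels[np.asarray(idx)[hit]] = name
            assigned |= inside
    counts = {name: int((labels == name).sum()) for name in CLASS_NAMES}
    return counts, labels.tolist()


def element_odds_ratio(m: int, t: int, l: int, lg: int, element: str = "") -> OddsRatioResult:
    if t <= 0 or lg <= 0:
        raise ValueError("T_i and LG must be positive")
    if l == 0:
        if m > 0:
            return OddsRatioResult(element, m, t, l, lg, float("inf"), float("nan"),
                                   infinite=True)
        return OddsRatioResult(element, m, t, l, lg, float("nan"), 1.0)
    odds = (m / t) / (l / lg)
    p = stats.binomtest(m, n=t, p=min(l / lg, 1.0)).pvalue
    return OddsRatioResult(element, m, t, l, lg, odds, float(p))


def element_enrichment(positions: Iterable[BreakPosition], hierarchy: ElementHierarchy,
                       disjoint_lengths: bool = False) -> pd.DataFrame:
    """Per-class odds ratios and binomial p-values for a set of positions."""
    counts, _ = assign_elements(positions, hierarchy)
    t = sum(counts.values())
    rows = []
    for name in CLASS_NAMES:
        res = element_odds_ratio(counts[name], t, hierarchy.length(name, disjoint_lengths),
                                 hierarchy.lg, element=name)
        rows.append({"element": name, "M": res.m, "T": res.t, "L": res.l, "LG": res.lg,
                     "odds_ratio": res.odds_ratio, "pvalue": res.pvalue})
    return pd.DataFrame(rows)
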