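"""CAGE peak calling, operative-TSS assignment, template/non-template strand calls.

An expressed gene's operative TSS is the maximum-depth CAGE peak (merged tag
depth >= 2) lying within +/-200 bp of the annotated TSS, on the gene's own
strand.  A break on the strand opposite a TSS is a template-strand match; a
break on the same strand is a non-template match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .genome_io import (
    BedFormatError,
    BreakPosition,
    GeneRecord,
    GenomeModel,
    STRANDS,
    _iter_data_lines,
)

__all__ = ["CageTag", "TssRecord", "read_cage", "merge_cage", "call_cage_peaks",
           "assign_tss", "classify_strand"]

TEMPLATE = "template"
NON_TEMPLATE = "non-template"


class CageTag(NamedTuple):
    chrom: str
    coord: int  # 0-based 5' position of the capped transcript
    strand: str
    depth: int


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    strand: str
    annotated_tss: int
    operative_tss: int
    peak_depth: int


def read_cage(path, genome: GenomeModel | None = None) -> list[CageTag]:
    """BED6 with the tag read depth in the score column."""
    tags: list[CageTag] = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 6:
            raise BedFormatError("CAGE records need 6 BED columns", lineno)
        chrom, start_s, end_s, _name, score_s, strand = fields[:6]
        try:
            start, depth = int(start_s), int(score_s)
        except ValueError as exc:
            raise BedFormatError(str(exc), lineno) from None
        if depth < 0:
            raise BedFormatError(f"negative CAGE depth {depth}", lineno)
        if strand not in STRANDS:
            raise BedFormatError(f"bad strand {strand!r}", lineno)
        tags.append(CageTag(chrom, start, strand, depth))
    return tags


def merge_cage(tag_lists: Sequence[Iterable[CageTag]]) -> list[CageTag]:
    """Combine tag files; depths at identical (chrom, coord, strand) are summed."""
    depth: dict[tuple[str, int, str], int] = {}
    for tags in tag_lists:
        for t in tags:
            if t.depth < 0:
                raise ValueError(f"negative CAGE depth at {t.chrom}:{t.coord}")
            key = (t.chrom, t.coord, t.strand)
            depth[key] = depth.get(key, 0) + t.depth
    return [CageTag(c, p, s, d) for (c, p, s), d in sorted(depth.items())]


def call_cage_peaks(tags: Iterable[CageTag], min_depth: int = 2) -> list[CageTag]:
    """Tags supported by at least ``min_depth`` reads are the CAGE peaks."""
    return [t for t in tags if t.depth >= min_depth]


def assign_tss(genes: Sequence[GeneRecord], peaks: Iterable[CageTag],
               window: int = 200) -> list[TssRecord]:
    """Pick each gene's operative TSS among same-strand peaks within +/-window bp.

    Genes without a qualifying peak are absent from the output (not expressed).
    Ties on depth break by minimal distance to the annotated TSS, then by the
    5'-most coordinate on the gene strand.
    """
    by_loc: dict[tuple[str, str], list[CageTag]] = {}
    for p in peaks:
        by_loc.setdefault((p.chrom, p.strand), []).append(p)
    records: list[TssRecord] = []
    for g in genes:
        cands = [p for p in by_loc.get((g.chrom, g.strand), ())
                 if abs(p.coord - g.tss) <= window]
        if not cands:
            continue
        five_prime = (lambda p: p.coord) if g.strand == "+" else (lambda p: -p.coord)
        best = min(cands, key=lambda p: (-p.depth, abs(p.coord - g.tss), five_prime(p)))
        records.append(TssRecord(g.gene_id, g.chrom, g.strand, g.tss, best.coord, best.depth))
    return records


def classify_strand(brk: BreakPosition, tss: TssRecord) -> str:
    """Opposite strand -> template; same strand -> non-template."""
    if brk.chrom != tss.chrom:
        raise ValueError(f"break on {brk.chrom} vs TSS on {tss.chrom}")
    return NON_TEMPLATE if brk.strand == tss.strand else TEMPLATE
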