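"""Stranded sequence context around breaks and cytosine-preference statistics.

Position labels follow the convention that the nick lies between positions
0 and 1 on the break's own strand: label 0 is base N immediately 5' of the
nick, -1 the next base 5', and 1 the first base 3'.  A +/-5 bp window is
therefore the 10-mer spanning labels -4..5, read 5'->3' on the break strand
(reverse-complemented for minus-strand breaks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import BreakPosition, GenomeModel

__all__ = ["ContextMatrix", "extract_contexts", "frequency_matrix", "cg_ratio",
           "median_cg_ratio", "position_labels"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = ("A", "C", "G", "T")


def position_labels(flank: int = 5) -> list[int]:
    """Labels -(flank-1)..0 then 1..flank (2*flank bases, nick between 0 and 1)."""
    return list(range(-(flank - 1), flank + 1))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_contexts(positions: Iterable[BreakPosition], genome: GenomeModel,
                     flank: int = 5) -> tuple[list[str], int]:
    """2*flank-base contexts on the break strand; returns (contexts, n_dropped).

    For a break at base N = coordinate c, label l sits at coordinate c + l on
    the plus strand (window [c - flank + 1, c + flank + 1)) and at c - l on
    the minus strand (reverse complement of [c - flank, c + flank)).  In both
    cases label 0 lands at string index flank - 1.  Windows running past a
    chromosome end are dropped and counted.
    """
    contexts: list[str] = []
    dropped = 0
    for p in positions:
        L = genome.chromosomes[p.chrom]
        if p.strand == "+":
            s, e = p.coord - flank + 1, p.coord + flank + 1
            if s < 0 or e > L:
                dropped += 1
                continue
            contexts.append(genome.get_seq(p.chrom, s, e))
        else:
            s, e = p.coord - flank, p.coord + flank
            if s < 0 or e > L:
                dropped += 1
                continue
            contexts.append(reverse_complement(genome.get_seq(p.chrom, s, e)))
    return contexts, dropped


@dataclass(frozen=True)
class ContextMatrix:
    counts: pd.DataFrame      # index = position labels, columns = A C G T
    n_contexts: int           # contexts actually counted
    n_ambiguous: int          # contexts dropped for non-ACGT bases

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.n_contexts

    @property
    def information(self) -> pd.Series:
        """Per-position information content in bits: 2 + sum f log2 f."""
        f = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(f > 0, f * np.log2(f), 0.0).sum(axis=1)
        return pd.Series(2.0 + h, index=self.counts.index, name="information")

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.add_suffix("_count").join(self.frequencies.add_suffix("_freq"))
        out["information"] = self.information
        out.index.name = "position"
        return out.reset_index()


def frequency_matrix(contexts: Sequence[str], flank: int = 5) -> ContextMatrix:
    """Per-position base counts/frequencies; ambiguous contexts are dropped, counted."""
    if not contexts:
        raise ValueError("no contexts")
    width = 2 * flank
    clean = []
    ambiguous = 0
    for ctx in contexts:
        ctx = ctx.upper()
        if len(ctx) != width:
            raise ValueError(f"context of length {len(ctx)}, expected {width}")
        if set(ctx) <= set(BASES):
            clean.append(ctx)
        else:
            ambiguous += 1
    if not clean:
        raise ValueError("all contexts contained ambiguous bases")
    arr = np.frombuffer("".join(clean).encode("ascii"), dtype=np.uint8).reshape(-1, width)
    counts = pd.DataFrame(
        {b: (arr == ord(b)).sum(axis=0) for b in BASES},
        index=pd.Index(position_labels(flank), name="position"),
    )
    return ContextMatrix(counts=counts, n_contexts=len(clean), n_ambiguous=ambiguous)


def cg_ratio(matrix: ContextMatrix, positions: Sequence[int] = (-1, 0)) -> dict[int, float]:
    """C/G frequency ratio at the queried positions (inf flagged when f(G)=0)."""
    freqs = matrix.frequencies
    out: dict[int, float] = {}
    for pos in positions:
        c = float(freqs.loc[pos, "C"])
        g = float(freqs.loc[pos, "G"])
        out[pos] = c / g if g > 0 else float("inf")
    return out


def median_cg_ratio(matrices: Sequence[ContextMatrix], position: int) -> float:
    """Median of per-matrix C/G ratios across an explicit list of matrices."""
    if not matrices:
        raise ValueError("no matrices")
    return float(np.median([cg_ratio(m, (position,))[position] for m in matrices]))
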