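"""Genome model, interval algebra and readers/writers for the standard formats.

The pipeline works on single-nucleotide, stranded break positions in BED
coordinates (0-based, half-open).  A break between bases N and M in the
sequence 5'-NM-3' is assigned to base N, so a ``BreakPosition`` stores the
0-based coordinate of N together with the strand the nick was detected on.

Repeat intervals (RepeatMasker-style), promoter tracks and any other plain
interval sets are held per chromosome as merged, sorted half-open intervals;
``GenomeModel`` exposes cumulative-coverage queries over them so that
non-repeat lengths of arbitrary windows can be computed in bulk.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "BedFormatError",
    "UnknownChromosomeError",
    "BreakPosition",
    "BreakSet",
    "GeneRecord",
    "GenomeModel",
    "merge_intervals",
    "interval_union",
    "interval_intersect",
    "interval_subtract",
    "interval_complement",
    "interval_total_length",
    "read_breaks",
    "filter_repeats",
    "read_intervals",
    "write_positions",
    "read_genes",
    "write_genes",
    "read_fasta",
    "write_fasta",
    "load_genome",
]

STRANDS = ("+", "-")


class BedFormatError(ValueError):
    """Malformed record in a BED/TSV input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UnknownChromosomeError(KeyError):
    """A record refers to a chromosome absent from the genome model."""


class BreakPosition(NamedTuple):
    chrom: str
    coord: int  # 0-based coordinate of base N (5' of the nick on `strand`)
    strand: str


@dataclass(frozen=True)
class BreakSet:
    """One biological replica's unique stranded break positions."""

    replica_id: str
    positions: frozenset[BreakPosition]

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self) -> Iterator[BreakPosition]:
        return iter(self.positions)

    def __contains__(self, pos: BreakPosition) -> bool:
        return pos in self.positions


@dataclass(frozen=True)
class GeneRecord:
    """A gene's longest transcript: TSS/TTS base coordinates and exon blocks.

    ``tss`` and ``tts`` are the 0-based coordinates of the first and last
    transcribed base; for a minus-strand gene ``tss > tts``.  ``exons`` are
    half-open genomic intervals sorted by start.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:  # half-open gene span end
        return max(self.tss, self.tts) + 1


IntervalArrays = tuple[np.ndarray, np.ndarray]


def _as_arrays(starts, ends) -> IntervalArrays:
    return (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> IntervalArrays:
    """Sort and merge half-open intervals; book-ended intervals merge too."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    starts: list[int] = []
    ends: list[int] = []
    for s, e in ivs:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return _as_arrays(starts, ends)


def interval_union(sets: Sequence[IntervalArrays]) -> IntervalArrays:
    pairs: list[tuple[int, int]] = []
    for starts, ends in sets:
        pairs.extend(zip(starts.tolist(), ends.tolist()))
    return merge_intervals(pairs)


def interval_intersect(a: IntervalArrays, b: IntervalArrays) -> IntervalArrays:
    """Intersection of two merged interval sets (two-pointer sweep)."""
    sa, ea = a
    sb, eb = b
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(sa) and j < len(sb):
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if lo < hi:
            out.append((int(lo), int(hi)))
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return merge_intervals(out)


def interval_complement(a: IntervalArrays, length: int) -> IntervalArrays:
    """Complement of a merged set within [0, length)."""
    starts, ends = a
    out: list[tuple[int, int]] = []
    prev = 0
    for s, e in zip(starts.tolist(), ends.tolist()):
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return merge_intervals(out)


def interval_subtract(a: IntervalArrays, b: IntervalArrays, length: int) -> IntervalArrays:
    return interval_intersect(a, interval_complement(b, length))


def interval_total_length(a: IntervalArrays) -> int:
    starts, ends = a
    return int((ends - starts).sum())


class GenomeModel:
    """Chromosome sizes, merged repeat intervals and optional sequence access.

    ``LG`` is the total non-repeat genome length (the normalising denominator
    of the element odds-ratio formula).
    """

    def __init__(
        self,
        chromosomes: Sequence[tuple[str, int]],
        repeats: Mapping[str, Iterable[tuple[int, int]]] | None = None,
        sequence_source=None,
    ):
        self.chromosomes: dict[str, int] = dict(chromosomes)
        self.repeats: dict[str, IntervalArrays] = {}
        repeats = repeats or {}
        for chrom, ivs in repeats.items():
            if chrom not in self.chromosomes:
                raise UnknownChromosomeError(chrom)
            merged = merge_intervals(ivs)
            starts, ends = merged
            if len(starts) and (starts[0] < 0 or ends[-1] > self.chromosomes[chrom]):
                raise ValueError(f"repeat interval out of bounds on {chrom}")
            self.repeats[chrom] = merged
        for chrom in self.chromosomes:
            self.repeats.setdefault(chrom, _as_arrays([], []))
        self.sequence_source = sequence_source
        # cumulative repeat lengths for O(log n) coverage queries
        self._cum: dict[str, np.ndarray] = {
            c: np.concatenate([[0], np.cumsum(e - s)])
            for c, (s, e) in self.repeats.items()
        }

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    @property
    def LG(self) -> int:
        rep = sum(interval_total_length(iv) for iv in self.repeats.values())
        return self.total_length - rep

    def repeat_mask(self, chrom: str, coords: np.ndarray) -> np.ndarray:
        """Boolean array: True where the single base at ``coords`` is repeat-masked."""
        if chrom not in self.chromosomes:
            raise UnknownChromosomeError(chrom)
        starts, ends = self.repeats[chrom]
        coords = np.asarray(coords, dtype=np.int64)
        if len(starts) == 0:
            return np.zeros(coords.shape, dtype=bool)
        idx = np.searchsorted(starts, coords, side="right") - 1
        ok = idx >= 0
        res = np.zeros(coords.shape, dtype=bool)
        res[ok] = coords[ok] < ends[idx[ok]]
        return res

    def _repeat_coverage(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Total repeat-covered bases of ``chrom`` in [0, x) for each x."""
        starts, ends = self.repeats[chrom]
        x = np.asarray(x, dtype=np.int64)
        if len(starts) == 0:
            return np.zeros(x.shape, dtype=np.int64)
        idx = np.searchsorted(starts, x, side="right")
        cov = self._cum[chrom][idx]
        trailing = idx > 0
        overshoot = np.where(trailing, ends[idx - 1] - x, 0)
        cov = cov - np.clip(overshoot, 0, None)
        return cov

    def nonrepeat_lengths(self, chrom: str, starts, ends) -> np.ndarray:
        """Non-repeat base counts of half-open windows, clipped to the chromosome."""
        if chrom not in self.chromosomes:
            raise UnknownChromosomeError(chrom)
        L = self.chromosomes[chrom]
        s = np.clip(np.asarray(starts, dtype=np.int64), 0, L)
        e = np.clip(np.asarray(ends, dtype=np.int64), 0, L)
        e = np.maximum(e, s)
        return (e - s) - (self._repeat_coverage(chrom, e) - self._repeat_coverage(chrom, s))

    def nonrepeat_length(self, chrom: str, start: int, end: int) -> int:
        return int(self.nonrepeat_lengths(chrom, [start], [end])[0])

    def nonrepeat_length_of(self, intervals: Mapping[str, IntervalArrays]) -> int:
        """Total non-repeat bases covered by a per-chromosome merged interval set."""
        total = 0
        for chrom, (s, e) in intervals.items():
            if chrom in self.chromosomes and len(s):
                total += int(self.nonrepeat_lengths(chrom, s, e).sum())
        return total

    def get_seq(self, chrom: str, start: int, end: int) -> str:
        """Uppercase plus-strand sequence for [start, end); requires a sequence source."""
        if self.sequence_source is None:
            raise ValueError("genome has no sequence source")
        src = self.sequence_source
        if isinstance(src, Mapping):
            seq = src[chrom][start:end]
            if isinstance(seq, bytes):
                return seq.decode("ascii").upper()
            return str(seq).upper()
        return str(src[chrom][start:end]).upper()  # pyfaidx.Fasta-style accessor


# ---------------------------------------------------------------------------
# BED / TSV / FASTA I/O


def _iter_data_lines(path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_breaks(path, genome: GenomeModel, replica_id: str | None = None) -> BreakSet:
    """Read single-nucleotide stranded break records from a BED6 file.

    Duplicate (chrom, coord, strand) records collapse to one position.
    Records on chromosomes absent from ``genome`` raise
    :class:`UnknownChromosomeError`; intervals wider than one base raise
    :class:`BedFormatError`.
    """
    positions: set[BreakPosition] = set()
    name = replica_id
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 6:
            raise BedFormatError("break records need 6 BED columns", lineno)
        chrom, start_s, end_s, rec_name, _score, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise BedFormatError(f"non-integer coordinate: {exc}", lineno) from None
        if end != start + 1:
            raise BedFormatError("break records must be single-nucleotide (end == start+1)", lineno)
        if strand not in STRANDS:
            raise BedFormatError(f"bad strand {strand!r}", lineno)
        if chrom not in genome.chromosomes:
            raise UnknownChromosomeError(f"line {lineno}: unknown chromosome {chrom!r}")
        if not 0 <= start < genome.chromosomes[chrom]:
            raise BedFormatError(f"coordinate {start} outside {chrom}", lineno)
        if name is None:
            name = rec_name
        positions.add(BreakPosition(chrom, start, strand))
    return BreakSet(replica_id=name or Path(path).stem, positions=frozenset(positions))


def filter_repeats(breaks: BreakSet, genome: GenomeModel) -> BreakSet:
    """Drop positions whose base N lies inside a repeat interval (input unchanged)."""
    by_chrom: dict[str, list[BreakPosition]] = {}
    for pos in breaks:
        by_chrom.setdefault(pos.chrom, []).append(pos)
    keep: list[BreakPosition] = []
    for chrom, plist in by_chrom.items():
        coords = np.array([p.coord for p in plist], dtype=np.int64)
        masked = genome.repeat_mask(chrom, coords)
        keep.extend(p for p, m in zip(plist, masked) if not m)
    return BreakSet(replica_id=breaks.replica_id, positions=frozenset(keep))


def read_intervals(path, genome: GenomeModel | None = None) -> dict[str, IntervalArrays]:
    """Read a BED3+ file into per-chromosome sorted, merged half-open intervals."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise BedFormatError("interval records need 3 BED columns", lineno)
        chrom, start_s, end_s = fields[:3]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise BedFormatError(f"non-integer coordinate: {exc}", lineno) from None
        if start >= end:
            raise BedFormatError(f"empty or inverted interval [{start}, {end})", lineno)
        if genome is not None and chrom not in genome.chromosomes:
            raise UnknownChromosomeError(f"line {lineno}: unknown chromosome {chrom!r}")
        per_chrom.setdefault(chrom, []).append((start, end))
    return {c: merge_intervals(ivs) for c, ivs in per_chrom.items()}


def write_positions(positions, path, name: str = "break", support: Mapping[BreakPosition, int] | None = None) -> None:
    """Write positions as BED6; hotspot support counts go in the score column.

    ``positions`` may be a BreakSet (name column = replica id) or any iterable
    of BreakPosition (name column = ``name``).
    """
    if isinstance(positions, BreakSet):
        name = positions.replica_id
        items = positions.positions
    else:
        items = positions
    rows = sorted(items)
    with open(path, "w") as fh:
        fh.write("# breakome positions: chrom start end name score strand\n")
        for pos in rows:
            score = support.get(pos, 0) if support is not None else 0
            fh.write(f"{pos.chrom}\t{pos.coord}\t{pos.coord + 1}\t{name}\t{score}\t{pos.strand}\n")


def write_intervals(intervals: Mapping[str, IntervalArrays], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            starts, ends = intervals[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                fh.write(f"{chrom}\t{s}\t{e}\n")


GENE_HEADER = "gene_id\tchrom\tstrand\ttss\ttts\texon_starts\texon_ends"


def write_genes(genes: Sequence[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(GENE_HEADER + "\n")
        for g in genes:
            es = ",".join(str(s) for s, _ in g.exons)
            ee = ",".join(str(e) for _, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tts}\t{es}\t{ee}\n")


def read_genes(path, genome: GenomeModel | None = None) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != GENE_HEADER:
            raise BedFormatError(f"unexpected gene table header: {header!r}", 1)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise BedFormatError("gene records need 7 columns", lineno)
            gene_id, chrom, strand, tss_s, tts_s, es, ee = fields
            if genome is not None and chrom not in genome.chromosomes:
                raise UnknownChromosomeError(f"line {lineno}: unknown chromosome {chrom!r}")
            exons = tuple(
                (int(s), int(e)) for s, e in zip(es.split(","), ee.split(","))
            )
            genes.append(GeneRecord(gene_id, chrom, strand, int(tss_s), int(tts_s), exons))
    return genes


def write_fasta(sequences: Mapping[str, bytes | str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            if isinstance(seq, (bytes, bytearray)):
                seq = seq.decode("ascii")
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, bytes]:
    """Read a (small) FASTA file fully into memory as uppercase bytes."""
    seqs: dict[str, bytes] = {}
    name = None
    buf = io.BytesIO()
    with open(path, "rb") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith(b">"):
                if name is not None:
                    seqs[name] = buf.getvalue().upper()
                name = line[1:].split()[0].decode("ascii")
                buf = io.BytesIO()
            elif line:
                buf.write(line)
    if name is not None:
        seqs[name] = buf.getvalue().upper()
    return seqs


def load_genome(fasta_path=None, repeats_path=None, chromosomes=None) -> GenomeModel:
    """Build a GenomeModel from a FASTA file and an optional repeat BED track.

    Sequence access goes through a ``pyfaidx`` index, so genomes need not fit
    in memory.
    """
    sequence = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        sequence = Fasta(str(fasta_path))
        chromosomes = [(name, len(sequence[name])) for name in sequence.keys()]
    if chromosomes is None:
        raise ValueError("need a FASTA path or explicit chromosome sizes")
    genome = GenomeModel(chromosomes, sequence_source=sequence)
    if repeats_path is not None:
        reps = read_intervals(repeats_path, genome)
        pairs = {c: list(zip(s.tolist(), e.tolist())) for c, (s, e) in reps.items()}
        genome = GenomeModel(chromosomes, repeats=pairs, sequence_source=sequence)
    return genome
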