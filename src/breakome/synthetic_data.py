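"""Synthetic genome, annotation and multi-replica breakome generator.

Emulates the statistical structure of a single-strand-break mapping study:
several biological replicas of unique, stranded, repeat-filtered break
positions that share a planted recurrent-hotspot component, a tunable
promoter-proximal break-rate boost around gene TSSs, a cytosine preference
immediately 5' of the nick, CAGE tags whose max-depth peak marks each
expressed gene's TSS, and a repeat-masked genome.

Breaks are drawn *without replacement* from an explicit per-position weight
field over all stranded non-repeat positions (baseline 1, x ``tss_enrichment_factor``
within +/-200 bp of TSSs, x ``hotspot_gain`` on planted hotspot positions),
using exact Gumbel top-k weighted sampling.  The cytosine preference is a
genuine sequence signal: a ``cytosine_bias`` fraction of each replica's draws
is taken from the sub-field of positions whose strand base is C, so motif
analysis recovers it from the emitted FASTA rather than from a label.

Everything is deterministic for a fixed seed; all per-stage random streams
are spawned from one root ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genome_io import (
    BreakPosition,
    BreakSet,
    GeneRecord,
    GenomeModel,
    IntervalArrays,
    merge_intervals,
    write_fasta,
    write_genes,
    write_intervals,
    write_positions,
)
from .tss_model import CageTag

__all__ = ["SimulationConfig", "Annotation", "generate_genome", "generate_annotation",
           "generate_breakome", "simulate_to_dir", "uniform_positions"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Per-gene slot geometry.  Each gene lives in its own slot; the slot's right
# end holds a repeat-free "promoter sanctuary" wide enough that the +/-5 kb
# analysis window around the TSS neither touches a repeat nor overlaps the
# neighbouring gene's window (promoter neighbourhoods of expressed genes are
# repeat-depleted, and this keeps planted enrichment factors exactly
# recoverable by the window statistics).
_GUARD = 5_200       # bp kept clear on each side of the TSS zone
_TSS_ZONE = 1_600    # width of the band the TSS is drawn from
_SANCTUARY = _GUARD + _TSS_ZONE + 5_000  # repeat-free suffix of every slot


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the desk-scale conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    repeat_fraction: float = 0.2
    n_genes: int = 500
    n_replicas: int = 4
    breaks_per_replica: int = 100_000
    hotspot_count: int = 500
    hotspot_gain: float = 1000.0
    tss_enrichment_factor: float = 3.0
    cytosine_bias: float = 0.25
    cage_mean_depth: float = 10.0
    cage_satellites: int = 3
    expression_coupling: float = 0.5
    gene_min_len: int = 2_000
    gene_max_len: int = 20_000
    tss_window: int = 200
    promoter_jitter_sigma: float = 0.25

    def validate(self) -> None:
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must be in [0, 1]")
        if not 0.0 <= self.cytosine_bias <= 1.0:
            raise ValueError("cytosine_bias must be in [0, 1]")
        if not 0.0 <= self.expression_coupling <= 1.0:
            raise ValueError("expression_coupling must be in [0, 1]")
        for name in ("n_chromosomes", "chromosome_length", "n_genes", "n_replicas",
                     "breaks_per_replica", "hotspot_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hotspot_gain < 1 or self.tss_enrichment_factor < 1:
            raise ValueError("hotspot_gain and tss_enrichment_factor must be >= 1")
        if self.repeat_fraction >= 1.0 and self.n_genes > 0:
            raise ValueError("repeat_fraction = 1 leaves no non-repeat space for genes")

    def seed_sequences(self):
        root = np.random.SeedSequence(self.seed)
        kids = root.spawn(4)
        return {"genome": kids[0], "annotation": kids[1], "breakome": kids[2], "extra": kids[3]}


class Annotation(NamedTuple):
    genes: list[GeneRecord]
    cage_tags: list[CageTag]
    expression: pd.DataFrame  # gene_id, fpkm_rep1, fpkm_rep2, mean_fpkm
    gene_truth: pd.DataFrame  # gene_id, promoter_jitter (j_g, mean 1)
    promoters: dict[str, IntervalArrays]


# ---------------------------------------------------------------------------
# genome


def _gene_allocation(config: SimulationConfig) -> list[int]:
    """Genes per chromosome (equal-length chromosomes, near-even split)."""
    base = config.n_genes // config.n_chromosomes
    alloc = [base] * config.n_chromosomes
    for i in range(config.n_genes - base * config.n_chromosomes):
        alloc[i] += 1
    return alloc


def _slot_geometry(config: SimulationConfig) -> list[tuple[int, int]]:
    """(slot width, gene count) per chromosome; raises if genes cannot fit."""
    out = []
    for n_here in _gene_allocation(config):
        L = config.chromosome_length
        slot = L // n_here if n_here else L
        if n_here and slot < _SANCTUARY + 500:
            raise ValueError("chromosomes too short for the requested gene count")
        out.append((slot, n_here))
    return out


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[0], mask.view(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def generate_genome(config: SimulationConfig) -> GenomeModel:
    """Random genome with i.i.d. uniform ACGT sequence and planted repeat intervals.

    Repeat intervals are placed at random and trimmed so their merged length
    per chromosome equals ``round(repeat_fraction * chromosome_length)`` exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed_sequences()["genome"])
    geometry = _slot_geometry(config)
    chroms: list[tuple[str, int]] = []
    repeats: dict[str, list[tuple[int, int]]] = {}
    sequences: dict[str, bytes] = {}
    L = config.chromosome_length
    for i in range(config.n_chromosomes):
        name = f"chr{i + 1}"
        chroms.append((name, L))
        codes = rng.integers(0, 4, size=L, dtype=np.uint8)
        sequences[name] = _BASES[codes].tobytes()
        # repeat-allowed zones: everything except each slot's promoter sanctuary
        slot, n_here = geometry[i]
        zones = [(k * slot, (k + 1) * slot - _SANCTUARY) for k in range(n_here)]
        if n_here * slot < L:
            zones.append((n_here * slot, L))
        zone_starts = np.array([z[0] for z in zones], dtype=np.int64)
        zone_widths = np.array([z[1] - z[0] for z in zones], dtype=np.int64)
        allowed = int(zone_widths.sum())
        target = int(round(config.repeat_fraction * L))
        if target > int(0.98 * allowed):
            raise ValueError("repeat_fraction infeasible at this gene density "
                             "(promoter neighbourhoods are kept repeat-free)")
        mask = np.zeros(L, dtype=bool)
        covered = 0
        p_zone = zone_widths / allowed
        while covered < target:
            n = 256
            zi = rng.choice(len(zones), size=n, p=p_zone)
            offs = rng.integers(0, zone_widths[zi])
            starts = zone_starts[zi] + offs
            stops = zone_starts[zi] + zone_widths[zi]
            lengths = rng.integers(200, 2000, size=n)
            for s, ln, stop in zip(starts.tolist(), lengths.tolist(), stops.tolist()):
                e = min(int(s) + int(ln), int(stop))  # clip to the allowed zone
                gain = int(e - s - mask[s:e].sum())
                if gain:
                    mask[s:e] = True
                    covered += gain
                if covered >= target:
                    break
        ivs = _mask_to_intervals(mask)
        overshoot = covered - target
        while overshoot > 0 and ivs:  # trim from the right to hit the target exactly
            s, e = ivs[-1]
            cut = min(e - s, overshoot)
            overshoot -= cut
            if cut == e - s:
                ivs.pop()
            else:
                ivs[-1] = (s, e - cut)
        repeats[name] = ivs
    return GenomeModel(chroms, repeats=repeats, sequence_source=sequences)


# ---------------------------------------------------------------------------
# annotation, CAGE, expression


def generate_annotation(config: SimulationConfig, genome: GenomeModel,
                        max_retries: int = 200) -> Annotation:
    rng = np.random.default_rng(config.seed_sequences()["annotation"])
    chrom_names = list(genome.chromosomes)
    geometry = _slot_geometry(config)

    genes: list[GeneRecord] = []
    gid = 0
    for chrom, (slot, n_here) in zip(chrom_names, geometry):
        max_len = min(config.gene_max_len, _GUARD - config.tss_window)
        if max_len < config.gene_min_len:
            raise ValueError("gene_min_len too large for the slot geometry")
        for k in range(n_here):
            placed = False
            for _ in range(max_retries):
                glen = int(rng.integers(config.gene_min_len, max_len + 1))
                # TSS drawn from the slot's sanctuary band, clear of repeats
                zone_end = (k + 1) * slot - _GUARD
                tss = int(rng.integers(zone_end - _TSS_ZONE, zone_end))
                strand = "+" if rng.random() < 0.5 else "-"
                g0 = tss if strand == "+" else tss - glen + 1
                if g0 < 0 or g0 + glen > genome.chromosomes[chrom]:
                    continue
                if genome.repeat_mask(chrom, np.array([tss]))[0]:
                    continue
                tts = g0 + glen - 1 if strand == "+" else g0
                genes.append(GeneRecord(f"gene{gid:05d}", chrom, strand, tss, tts,
                                        _random_exons(rng, g0, g0 + glen)))
                gid += 1
                placed = True
                break
            if not placed:
                raise RuntimeError(f"could not place gene {gid} on {chrom} after {max_retries} tries")

    n = len(genes)
    # promoter-weight jitter (mean 1) and rank-coupled expression via a Gaussian copula
    sigma = config.promoter_jitter_sigma
    z_w = rng.standard_normal(n)
    jitter = np.exp(sigma * z_w) / np.exp(sigma * sigma / 2.0)
    c = config.expression_coupling
    z_e = c * z_w + np.sqrt(max(1.0 - c * c, 0.0)) * rng.standard_normal(n)
    base_expr = np.exp(1.5 * z_e + 2.0)
    rep_noise = np.exp(0.1 * rng.standard_normal((n, 2)))
    fpkm = base_expr[:, None] * rep_noise

    cage: list[CageTag] = []
    mean_extra = max(config.cage_mean_depth - 1.0, 0.0)
    for g in genes:
        d0 = 1 + int(rng.poisson(mean_extra))
        cage.append(CageTag(g.chrom, g.tss, g.strand, d0))
        n_sat = int(rng.integers(0, config.cage_satellites + 1))
        L = genome.chromosomes[g.chrom]
        for _ in range(n_sat):
            off = 0
            while off == 0:
                off = int(rng.integers(-config.tss_window, config.tss_window + 1))
            coord = g.tss + off
            if not 0 <= coord < L:
                continue
            depth = int(rng.integers(1, d0)) if d0 > 1 else 1
            cage.append(CageTag(g.chrom, coord, g.strand, depth))

    expression = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "fpkm_rep1": fpkm[:, 0],
        "fpkm_rep2": fpkm[:, 1],
    })
    expression["mean_fpkm"] = expression[["fpkm_rep1", "fpkm_rep2"]].mean(axis=1)
    gene_truth = pd.DataFrame({"gene_id": [g.gene_id for g in genes],
                               "promoter_jitter": jitter})

    promoters: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.strand == "+":
            iv = (max(g.tss - 1500, 0), min(g.tss + 500, genome.chromosomes[g.chrom]))
        else:
            iv = (max(g.tss - 500, 0), min(g.tss + 1500, genome.chromosomes[g.chrom]))
        promoters.setdefault(g.chrom, []).append(iv)
    merged_prom = {c: merge_intervals(ivs) for c, ivs in promoters.items()}
    return Annotation(genes, cage, expression, gene_truth, merged_prom)


def _random_exons(rng: np.random.Generator, start: int, end: int) -> tuple[tuple[int, int], ...]:
    n_ex = int(rng.integers(1, 6))
    if n_ex == 1 or end - start < 2 * n_ex:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(start + 1, end - 1), size=2 * (n_ex - 1), replace=False))
    bounds = [start, *cuts.tolist(), end]
    return tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2))


# ---------------------------------------------------------------------------
# breakome


class _PositionSpace:
    """Flat index over all stranded positions: per chromosome, '+' block then '-' block."""

    def __init__(self, genome: GenomeModel):
        self.chroms = list(genome.chromosomes)
        self.lengths = np.array([genome.chromosomes[c] for c in self.chroms], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(2 * self.lengths)])
        self.size = int(self.offsets[-1])

    def block(self, chrom_i: int, strand: str) -> tuple[int, int]:
        L = int(self.lengths[chrom_i])
        base = int(self.offsets[chrom_i]) + (0 if strand == "+" else L)
        return base, base + L

    def decode(self, idx: np.ndarray):
        idx = np.asarray(idx, dtype=np.int64)
        ci = np.searchsorted(self.offsets, idx, side="right") - 1
        rel = idx - self.offsets[ci]
        minus = rel >= self.lengths[ci]
        coord = rel - np.where(minus, self.lengths[ci], 0)
        return ci, coord, minus


def _weight_field(config: SimulationConfig, genome: GenomeModel,
                  genes: list[GeneRecord], gene_multipliers: dict[str, float],
                  rng: np.random.Generator):
    space = _PositionSpace(genome)
    W = np.ones(space.size, dtype=np.float32)
    for i, chrom in enumerate(space.chroms):
        starts, ends = genome.repeats[chrom]
        for strand in "+-":
            base, _ = space.block(i, strand)
            for s, e in zip(starts.tolist(), ends.tolist()):
                W[base + s : base + e] = 0.0
    # promoter boost: maximum over overlapping gene windows, both strands
    w = config.tss_window
    boost = np.ones(space.size, dtype=np.float32)
    for g in genes:
        i = space.chroms.index(g.chrom)
        L = int(space.lengths[i])
        s, e = max(g.tss - w, 0), min(g.tss + w + 1, L)
        m = np.float32(gene_multipliers[g.gene_id])
        for strand in "+-":
            base, _ = space.block(i, strand)
            np.maximum(boost[base + s : base + e], m, out=boost[base + s : base + e])
    W *= boost
    # planted hotspots: uniform over currently non-zero positions
    hot = _uniform_nonzero(rng, W, config.hotspot_count)
    W[hot] *= np.float32(config.hotspot_gain)
    return space, W, np.sort(hot)


def _uniform_nonzero(rng: np.random.Generator, W: np.ndarray, k: int) -> np.ndarray:
    """k distinct uniform indices among W > 0 (rejection + first-occurrence dedup)."""
    chosen: list[np.ndarray] = []
    seen = np.zeros(0, dtype=np.int64)
    need = k
    while need > 0:
        cand = rng.integers(0, len(W), size=max(4 * need, 64))
        cand = cand[W[cand] > 0]
        cand = pd.unique(cand)
        cand = cand[~np.isin(cand, seen)][:need]
        chosen.append(cand.astype(np.int64))
        seen = np.concatenate([seen, cand])
        need = k - len(seen)
    return np.concatenate(chosen)


def _gumbel_topk(rng: np.random.Generator, logw: np.ndarray, k: int) -> np.ndarray:
    """Exact weighted sampling without replacement via Gumbel perturbation."""
    if k == 0:
        return np.zeros(0, dtype=np.int64)
    keys = logw + rng.gumbel(size=len(logw)).astype(np.float32)
    idx = np.argpartition(-keys, k - 1)[:k]
    return idx.astype(np.int64)


def _c_mask(space: _PositionSpace, genome: GenomeModel) -> np.ndarray:
    """True where the base at the position, read on its own strand, is C."""
    mask = np.zeros(space.size, dtype=bool)
    for i, chrom in enumerate(space.chroms):
        seq = np.frombuffer(genome.sequence_source[chrom], dtype=np.uint8)
        b_plus, _ = space.block(i, "+")
        b_minus, _ = space.block(i, "-")
        mask[b_plus : b_plus + len(seq)] = seq == ord("C")
        mask[b_minus : b_minus + len(seq)] = seq == ord("G")  # complement of G is C
    return mask


def generate_breakome(config: SimulationConfig, genome: GenomeModel,
                      genes: list[GeneRecord],
                      gene_truth: pd.DataFrame | None = None,
                      gene_multipliers: dict[str, float] | None = None,
                      ) -> tuple[list[BreakSet], pd.DataFrame]:
    """Draw ``n_replicas`` replicas of unique stranded break positions.

    Returns the replicas plus a planted-truth table of the hotspot positions
    with their sampling weights.  ``gene_multipliers`` overrides the per-gene
    promoter boost (gene_id -> multiplier); by default the boost is
    ``1 + (tss_enrichment_factor - 1) * j_g`` with ``j_g`` the mean-1 jitter
    from the annotation truth table, so the neutral factor 1 yields an exactly
    uniform field.
    """
    config.validate()
    rng = np.random.default_rng(config.seed_sequences()["breakome"])
    f = config.tss_enrichment_factor
    if gene_multipliers is None:
        if gene_truth is not None:
            j = dict(zip(gene_truth["gene_id"], gene_truth["promoter_jitter"]))
        else:
            j = {g.gene_id: 1.0 for g in genes}
        gene_multipliers = {gid: 1.0 + (f - 1.0) * jg for gid, jg in j.items()}
    space, W, hot = _weight_field(config, genome, genes, gene_multipliers, rng)
    n_available = int((W > 0).sum())
    if config.breaks_per_replica > n_available:
        raise ValueError("breaks_per_replica exceeds the available non-repeat positions")

    with np.errstate(divide="ignore"):
        logw = np.where(W > 0, np.log(W, dtype=np.float32), np.float32(-np.inf))
    logw_c = None
    if config.cytosine_bias > 0:
        cmask = _c_mask(space, genome)
        logw_c = np.where(cmask, logw, np.float32(-np.inf))

    replicas: list[BreakSet] = []
    for r in range(config.n_replicas):
        b = config.breaks_per_replica
        n_c = int(rng.binomial(b, config.cytosine_bias)) if logw_c is not None else 0
        idx_c = _gumbel_topk(rng, logw_c, n_c) if n_c else np.zeros(0, dtype=np.int64)
        idx_u = _gumbel_topk(rng, logw, b - n_c)
        idx = np.unique(np.concatenate([idx_c, idx_u]))
        ci, coord, minus = space.decode(idx)
        positions = frozenset(
            BreakPosition(space.chroms[c], int(p), "-" if m else "+")
            for c, p, m in zip(ci.tolist(), coord.tolist(), minus.tolist())
        )
        replicas.append(BreakSet(replica_id=f"rep{r + 1}", positions=positions))

    ci, coord, minus = space.decode(hot)
    truth = pd.DataFrame({
        "chrom": [space.chroms[c] for c in ci.tolist()],
        "coord": coord,
        "strand": np.where(minus, "-", "+"),
        "weight": W[hot].astype(float),
        "is_hotspot": True,
    })
    return replicas, truth


def uniform_positions(genome: GenomeModel, n: int, seed) -> list[BreakPosition]:
    """n distinct stranded positions uniform over the non-repeat genome."""
    space = _PositionSpace(genome)
    ok = np.ones(space.size, dtype=np.float32)
    for i, chrom in enumerate(space.chroms):
        starts, ends = genome.repeats[chrom]
        for strand in "+-":
            base, _ = space.block(i, strand)
            for s, e in zip(starts.tolist(), ends.tolist()):
                ok[base + s : base + e] = 0.0
    rng = np.random.default_rng(seed)
    idx = _uniform_nonzero(rng, ok, n)
    ci, coord, minus = space.decode(idx)
    return [BreakPosition(space.chroms[c], int(p), "-" if m else "+")
            for c, p, m in zip(ci.tolist(), coord.tolist(), minus.tolist())]


# ---------------------------------------------------------------------------
# on-disk emission


def simulate_to_dir(config: SimulationConfig, outdir) -> dict[str, object]:
    """Run the full generator and write every input the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    ann = generate_annotation(config, genome)
    replicas, truth = generate_breakome(config, genome, ann.genes, ann.gene_truth)

    write_fasta(genome.sequence_source, outdir / "genome.fa")
    write_intervals(genome.repeats, outdir / "repeats.bed")
    write_genes(ann.genes, outdir / "genes.tsv")
    with open(outdir / "cage.bed", "w") as fh:
        for t in sorted(ann.cage_tags):
            fh.write(f"{t.chrom}\t{t.coord}\t{t.coord + 1}\tcage\t{t.depth}\t{t.strand}\n")
    ann.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False, float_format="%.6g")
    write_intervals(ann.promoters, outdir / "promoters.bed")
    breaks_dir = outdir / "breaks"
    breaks_dir.mkdir(exist_ok=True)
    for rep in replicas:
        write_positions(rep, breaks_dir / f"{rep.replica_id}.bed")
    truth.sort_values(["chrom", "coord", "strand"]).to_csv(
        outdir / "truth_hotspots.tsv", sep="\t", index=False, float_format="%.6g")
    ann.gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False, float_format="%.6g")
    with open(outdir / "sim_config.yaml", "w") as fh:
        for k, v in asdict(config).items():
            fh.write(f"{k}: {v}\n")
    return {"genome": genome, "annotation": ann, "replicas": replicas, "truth": truth,
            "dir": outdir}
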