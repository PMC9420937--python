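# breakome

Genome-wide analysis of single-strand DNA break (SSB) hotspots and their
enrichment at transcription start sites.

Nucleotide-resolution SSB mapping assays (SSiNGLe-style 3′-OH tagging) yield,
per biological replica, a set of unique stranded single-nucleotide break
positions.  Most breaks are singletons, but some positions recur across
independent replicas — *hotspots* — and these recur preferentially in the
immediate vicinity of active transcription start sites.  This package
implements the downstream statistics of that analysis for researchers working
with called break positions (BED), CAGE tag files, gene annotation, a repeat
track, and a per-gene expression table:

- **Hotspot calling** — a position is a hotspot when found in ≥ k (default 2)
  replicas; the observed shared fraction is tested against 100 Monte-Carlo
  simulations that redraw the same numbers of samples and breaks per sample
  uniformly from the non-repeat position space (two-sided one-sample Student
  t-test of the simulated fractions against the observation).
- **Operative TSS assignment** — CAGE tags are merged per cell type, tags with
  depth ≥ 2 are peaks, and each expressed gene's TSS is the maximum-depth peak
  within ±200 bp of its annotated TSS on the gene's own strand.  Breaks on the
  strand opposite a TSS are *template*-strand matches; same strand,
  *non-template*.
- **TSS metagene profiles and enrichment ratio** — signed nearest-TSS
  distances are binned into 500 × 20-bp bins over ±5,000 bp; densities are
  normalized by the average non-repeat ratio of each bin,
  `D_ij = N_ij · 10⁶ / (NR_j · T_i)`, and the TSS-SSB enrichment ratio is

  ```
  R_i = (M_i^200 / M_i^5000) / (L^200 / L^5000)
  ```

  with a two-sided binomial test (x = M_i^200, n = M_i^5000,
  p = L^200/L^5000).  Per-sample combined-strand ratios support treatment
  comparisons (Welch t-test vs a reference group).
- **Element hierarchy** — every break/hotspot is assigned to exactly one of 7
  classes in strict priority order (TSS ±200, CAGE peak ±200, promoter,
  TTS ±200, exonic, intronic, intergenic) with per-class odds ratios
  `OR_i = (M_i/T_i)/(L_i/LG)` and binomial tests, where `L_i` is the class's
  non-repeat length and `LG` the genome's.
- **Expression stratification** — observed/expected odds ratios of breaks
  within ±200 bp and ±(200–5,000) bp of the TSSs of the top 5/10/25/50%
  expressed genes, with expectations from uniformly simulated random breaks
  over the non-repeat genome.
- **Break sequence context** — stranded ±5-bp windows around breaks (the nick
  lies between positions 0 and 1; position 0 is the base 5′ of the nick),
  position frequency matrices with information content, and C/G ratios at
  positions −1 and 0.
- **Synthetic data generator** — a model genome with repeat intervals, gene
  annotation, CAGE tags, expression values, and multi-replica breakomes with
  planted hotspots, tunable promoter enrichment and a genuine cytosine
  sequence bias, so the whole pipeline is testable end-to-end without any
  external download.

## Worked example

```python
from breakome import SimulationConfig
from breakome.synthetic_data import generate_genome, generate_annotation, generate_breakome
from breakome.hotspots import build_support, call_hotspots, hotspot_fraction, \
    simulate_null, hotspot_significance
from breakome.tss_model import merge_cage, call_cage_peaks, assign_tss
from breakome.tss_enrichment import enrichment_ratio

cfg = SimulationConfig(seed=7, chromosome_length=2_000_000, n_genes=200,
                       n_replicas=4, breaks_per_replica=40_000)
genome = generate_genome(cfg)
ann = generate_annotation(cfg, genome)
replicas, truth = generate_breakome(cfg, genome, ann.genes, ann.gene_truth)

support = build_support(replicas)
hotspots = call_hotspots(support, k=2)
frac = hotspot_fraction(support, 2)
null = simulate_null(4, [len(r) for r in replicas], space_size=2 * genome.LG,
                     n_sim=100, seed=8)
t, p, _ = hotspot_significance(frac, null)
print(f"{len(support):,} unique positions, {len(hotspots):,} hotspots "
      f"({100*frac:.2f}% vs {100*null.fractions.mean():.2f}% expected, p = {p:.3g})")

peaks = call_cage_peaks(merge_cage([ann.cage_tags]))
tss = assign_tss(ann.genes, peaks)
r = enrichment_ratio(sorted(hotspots.positions), tss, genome)
print(f"{len(tss)} expressed genes; hotspot TSS enrichment ratio "
      f"R = {r.ratio:.2f} (M200={r.m_inner}, M5000={r.m_outer}, p = {r.pvalue:.3g})")
```

prints

```
155,922 unique positions, 2,365 hotspots (1.52% vs 0.94% expected, p = 8.72e-138)
200 expressed genes; hotspot TSS enrichment ratio R = 5.58 (M200=357, M5000=1595, p = 1.16e-154)
```

The 2,365 recurrent positions are ~1.6× the chance expectation (the planted
hotspots on top of coincidental overlaps), and the hotspot track is strongly
concentrated within ±200 bp of operative TSSs relative to the ±5,000 bp
background, mirroring the structure the generator plants.

## Command line

```bash
breakome simulate --seed 7 --out data/            # synthetic dataset
breakome hotspots --breaks data/breaks --fasta data/genome.fa \
    --repeats data/repeats.bed --min-support 2 --nsim 100 --seed 7 --out out/
breakome tss --genes data/genes.tsv --cage data/cage.bed --out out/tss.tsv
breakome motif --breaks data/breaks/rep1.bed --fasta data/genome.fa --out out/motif.tsv
breakome all --config run.yaml                    # full pipeline + manifest
```

`breakome all` runs every stage from one YAML config (single root seed,
per-stage derived streams) and writes a `manifest.json` with config snapshot
and sha256 checksums of every output; re-running the same config reproduces
identical checksums.

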