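"""Shared fixtures: a small hand-made genome and session-scoped synthetic runs."""

import numpy as np
import pytest

from breakome.genome_io import BreakPosition, GenomeModel
from breakome.synthetic_data import (
    SimulationConfig,
    generate_annotation,
    generate_breakome,
    generate_genome,
)
from breakome.tss_model import assign_tss, call_cage_peaks, merge_cage


@pytest.fixture
def toy_genome():
    """Two short chromosomes with known repeats and a fixed random sequence."""
    rng = np.random.default_rng(42)
    seqs = {
        "chr1": bytes(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), 1000)),
        "chr2": bytes(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), 800)),
    }
    return GenomeModel(
        [("chr1", 1000), ("chr2", 800)],
        repeats={"chr1": [(100, 200), (400, 450)], "chr2": [(0, 50)]},
        sequence_source=seqs,
    )


def make_dataset(cfg: SimulationConfig) -> dict:
    genome = generate_genome(cfg)
    ann = generate_annotation(cfg, genome)
    replicas, truth = generate_breakome(cfg, genome, ann.genes, ann.gene_truth)
    peaks = call_cage_peaks(merge_cage([ann.cage_tags]))
    tss = assign_tss(ann.genes, peaks)
    return {"config": cfg, "genome": genome, "ann": ann, "replicas": replicas,
            "truth": truth, "peaks": peaks, "tss": tss}


@pytest.fixture(scope="session")
def neutral_run():
    """All biases at neutral values: uniform breaks over the non-repeat genome."""
    cfg = SimulationConfig(seed=101, tss_enrichment_factor=1.0, hotspot_gain=1.0,
                           cytosine_bias=0.0, expression_coupling=0.0, n_replicas=2)
    return make_dataset(cfg)


@pytest.fixture(scope="session")
def planted_run():
    """Default study conditions: planted hotspots, TSS boost, cytosine bias."""
    return make_dataset(SimulationConfig(seed=303))


SMALL_PIPELINE_CONFIG = {
    "seed": 11,
    "simulation": {"chromosome_length": 1_000_000, "n_genes": 100,
                   "breaks_per_replica": 20_000, "n_replicas": 3,
                   "hotspot_count": 100},
    "n_sim": 20,
    "n_random": 50_000,
}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    from breakome.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline")
    manifest = run_pipeline(dict(SMALL_PIPELINE_CONFIG), outdir)
    return {"manifest": manifest, "dir": outdir}


def positions(*triples) -> list[BreakPosition]:
    return [BreakPosition(c, p, s) for c, p, s in triples]
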