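"""Stage orchestration: simulate/load -> hotspots -> tss -> enrich -> elements
-> expression -> motif, behind one flat configuration mapping.

All randomness flows from one root seed; per-stage streams are spawned from
it so a stage can be re-run stably.  Every run writes a JSON manifest with
the config snapshot, stage statuses and sha256 checksums of each output
file; re-running with the same config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import element_map, expression_link, genome_io, hotspots, motif, synthetic_data
from . import tss_enrichment, tss_model

__all__ = ["PipelineError", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("breakome")

ALL_STAGES = ("simulate", "hotspots", "tss", "enrich", "elements", "expression", "motif")

_STAGE_DEPS = {
    "hotspots": ("simulate",),
    "tss": ("simulate",),
    "enrich": ("simulate", "hotspots", "tss"),
    "elements": ("simulate", "hotspots", "tss"),
    "expression": ("simulate", "hotspots", "tss"),
    "motif": ("simulate", "hotspots"),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping or a path to a YAML mapping")
    return dict(config)


def _validate_config(cfg: dict) -> None:
    known = {"seed", "outdir", "stages", "simulation", "inputs", "min_support",
             "n_sim", "inner", "outer", "n_random", "flank", "min_cage_depth",
             "tss_window", "disjoint_lengths"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    stages = cfg.get("stages")
    if stages is not None:
        bad = set(stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def run_pipeline(config, outdir=None) -> dict:
    """Execute the configured stages in dependency order; returns the manifest.

    ``config`` is a flat mapping (or YAML path) with keys: ``seed``,
    ``outdir``, ``stages`` (subset of ALL_STAGES; default all), ``simulation``
    (SimulationConfig overrides), optional ``inputs`` (paths to pre-existing
    breaks/annotation files instead of simulating), and per-stage scalars
    (``min_support``, ``n_sim``, ``inner``, ``outer``, ``n_random``,
    ``flank``, ``min_cage_depth``, ``disjoint_lengths``).
    """
    cfg = _load_config(config)
    _validate_config(cfg)
    outdir = Path(outdir or cfg.get("outdir") or "breakome_run")
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = tuple(cfg.get("stages") or ALL_STAGES)
    ss = np.random.SeedSequence(seed)
    stage_seeds = {name: child for name, child in zip(ALL_STAGES, ss.spawn(len(ALL_STAGES)))}

    manifest: dict = {"config": cfg, "seed": seed, "stages": {},
                      "outputs": {}, "version": 1}
    state: dict = {}

    def record(name: str, paths: list[Path]):
        for p in paths:
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
        manifest["stages"][name] = {"status": "ok"}

    ordered = [s for s in ALL_STAGES if s in stages]
    failed_at = None
    for name in ordered:
        missing = [d for d in _STAGE_DEPS.get(name, ()) if d in stages and
                   manifest["stages"].get(d, {}).get("status") != "ok"]
        if failed_at or missing:
            manifest["stages"][name] = {"status": "skipped",
                                        "reason": f"upstream failure in {failed_at or missing}"}
            continue
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            paths = _STAGE_FUNCS[name](cfg, outdir, state, stage_seeds[name], seed)
            record(name, paths)
            log.info("stage %s: ok (%.1fs)", name, time.time() - t0)
        except Exception as exc:  # noqa: BLE001 - recorded, then re-raised below
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            failed_at = name
            log.error("stage %s: failed: %s", name, exc)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    if failed_at:
        stage_info = manifest["stages"][failed_at]
        raise PipelineError(failed_at, RuntimeError(stage_info["error"]))
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, outdir, state, stage_seed, seed):
    inputs = cfg.get("inputs")
    if inputs:
        genome = genome_io.load_genome(inputs["fasta"], inputs.get("repeats"))
        breaks_dir = Path(inputs["breaks_dir"])
        replicas = [genome_io.filter_repeats(genome_io.read_breaks(p, genome), genome)
                    for p in sorted(breaks_dir.glob("*.bed"))]
        genes = genome_io.read_genes(inputs["genes"], genome) if inputs.get("genes") else []
        cage = tss_model.read_cage(inputs["cage"], genome) if inputs.get("cage") else []
        expression = (pd.read_csv(inputs["expression"], sep="\t")
                      if inputs.get("expression") else pd.DataFrame())
        promoters = (genome_io.read_intervals(inputs["promoters"], genome)
                     if inputs.get("promoters") else {})
        state.update(genome=genome, replicas=replicas, genes=genes, cage_tags=cage,
                     expression=expression, promoters=promoters)
        return []
    sim_cfg = synthetic_data.SimulationConfig(**{"seed": seed, **(cfg.get("simulation") or {})})
    res = synthetic_data.simulate_to_dir(sim_cfg, outdir / "sim")
    ann = res["annotation"]
    state.update(genome=res["genome"], replicas=res["replicas"], genes=ann.genes,
                 cage_tags=ann.cage_tags, expression=ann.expression,
                 promoters=ann.promoters, truth=res["truth"])
    simdir = outdir / "sim"
    return sorted(p for p in simdir.rglob("*") if p.is_file())


def _stage_hotspots(cfg, outdir, state, stage_seed, seed):
    k = int(cfg.get("min_support", 2))
    n_sim = int(cfg.get("n_sim", 100))
    replicas = state["replicas"]
    genome = state["genome"]
    support = hotspots.build_support(replicas)
    hs = hotspots.call_hotspots(support, k)
    frac = hotspots.hotspot_fraction(support, k)
    null = hotspots.simulate_null(len(replicas), [len(r) for r in replicas],
                                  space_size=2 * genome.LG, n_sim=n_sim, seed=stage_seed, k=k)
    t_stat, pval, degenerate = hotspots.hotspot_significance(frac, null)
    state.update(support=support, hotspot_set=hs)
    paths = [outdir / "hotspots.bed", outdir / "support.tsv", outdir / "null.tsv",
             outdir / "summary.tsv"]
    genome_io.write_positions(hs.positions, paths[0], name="hotspot", support=hs.support)
    sup_rows = sorted((p.chrom, p.coord, p.strand, c) for p, c in support.counts.items())
    pd.DataFrame(sup_rows, columns=["chrom", "coord", "strand", "support"]).to_csv(
        paths[1], sep="\t", index=False)
    pd.DataFrame({"simulation": np.arange(1, null.n_simulations + 1),
                  "shared_fraction": null.fractions}).to_csv(paths[2], sep="\t", index=False)
    pd.DataFrame([{
        "n_replicas": len(replicas), "min_support": k,
        "n_union_positions": len(support), "n_hotspots": len(hs),
        "hotspot_fraction": frac, "null_mean": float(null.fractions.mean()),
        "t": t_stat, "pvalue": pval, "degenerate_null": degenerate,
    }]).to_csv(paths[3], sep="\t", index=False)
    return paths


def _stage_tss(cfg, outdir, state, stage_seed, seed):
    peaks = tss_model.call_cage_peaks(tss_model.merge_cage([state["cage_tags"]]),
                                      int(cfg.get("min_cage_depth", 2)))
    tss_set = tss_model.assign_tss(state["genes"], peaks, int(cfg.get("tss_window", 200)))
    state.update(cage_peaks=peaks, tss_set=tss_set)
    path = outdir / "tss.tsv"
    pd.DataFrame([{"gene_id": t.gene_id, "chrom": t.chrom, "strand": t.strand,
                   "annotated_tss": t.annotated_tss, "operative_tss": t.operative_tss,
                   "peak_depth": t.peak_depth} for t in tss_set]).to_csv(
        path, sep="\t", index=False)
    return [path]


def _pooled_breaks(state):
    pooled = frozenset().union(*(r.positions for r in state["replicas"]))
    return sorted(pooled)


def _stage_enrich(cfg, outdir, state, stage_seed, seed):
    genome, tss_set = state["genome"], state["tss_set"]
    inner, outer = int(cfg.get("inner", 200)), int(cfg.get("outer", 5000))
    grid = tss_enrichment.build_bin_grid(tss_set, genome, window=outer)
    tracks = {"all_breaks": _pooled_breaks(state),
              "hotspots": sorted(state["hotspot_set"].positions)}
    profiles, ratios = [], []
    for track, positions in tracks.items():
        for prof in tss_enrichment.density_profile(positions, tss_set, grid,
                                                   sample_id=track).values():
            profiles.append(prof.to_frame())
        for sc in (tss_model.TEMPLATE, tss_model.NON_TEMPLATE, None):
            r = tss_enrichment.enrichment_ratio(positions, tss_set, genome, inner, outer,
                                                strand_class=sc, sample_id=track)
            ratios.append(vars(r))
    # per-replica combined-strand ratios (the treatment-comparison statistic)
    for rep in state["replicas"]:
        r = tss_enrichment.enrichment_ratio(sorted(rep.positions), tss_set, genome,
                                            inner, outer, sample_id=rep.replica_id)
        ratios.append(vars(r))
    state["grid"] = grid
    paths = [outdir / "profile.tsv", outdir / "enrichment.tsv"]
    pd.concat(profiles, ignore_index=True).to_csv(paths[0], sep="\t", index=False,
                                                  float_format="%.6g")
    pd.DataFrame(ratios).to_csv(paths[1], sep="\t", index=False, float_format="%.6g")
    return paths


def _stage_elements(cfg, outdir, state, stage_seed, seed):
    hierarchy = element_map.build_hierarchy(state["tss_set"], state["cage_peaks"],
                                            state.get("promoters"), state["genes"],
                                            state["genome"])
    disjoint = bool(cfg.get("disjoint_lengths", False))
    frames = []
    for track, positions in (("all_breaks", _pooled_breaks(state)),
                             ("hotspots", sorted(state["hotspot_set"].positions))):
        df = element_map.element_enrichment(positions, hierarchy, disjoint_lengths=disjoint)
        df.insert(0, "track", track)
        frames.append(df)
    state["hierarchy"] = hierarchy
    path = outdir / "elements.tsv"
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.6g")
    return [path]


def _stage_expression(cfg, outdir, state, stage_seed, seed):
    n_random = int(cfg.get("n_random", 200_000))
    expr = state["expression"]
    tss_set = state["tss_set"]
    strata = expression_link.rank_strata(expr)
    tss_strata = {f: [t for t in tss_set if t.gene_id in genes]
                  for f, genes in strata.items()}
    tss_strata = {f: recs for f, recs in tss_strata.items() if recs}
    expected = expression_link.expected_fractions(n_random, state["genome"], tss_strata,
                                                  seed=stage_seed)
    frames = []
    for track, positions in (("all_breaks", _pooled_breaks(state)),
                             ("hotspots", sorted(state["hotspot_set"].positions))):
        frames.append(expression_link.expression_odds_ratios(positions, tss_strata,
                                                             expected, track=track))
    ors = pd.concat(frames, ignore_index=True)
    ors["n_random"] = n_random
    path = outdir / "expr_or.tsv"
    ors.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return [path]


def _stage_motif(cfg, outdir, state, stage_seed, seed):
    flank = int(cfg.get("flank", 5))
    genome = state["genome"]
    paths = []
    summary = []
    for track, positions in (("all_breaks", _pooled_breaks(state)),
                             ("hotspots", sorted(state["hotspot_set"].positions))):
        contexts, dropped = motif.extract_contexts(positions, genome, flank)
        mat = motif.frequency_matrix(contexts, flank)
        p = outdir / f"motif_{track}.tsv"
        mat.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths.append(p)
        ratios = motif.cg_ratio(mat, (-1, 0))
        summary.append({"track": track, "n_contexts": mat.n_contexts,
                        "n_dropped_edge": dropped, "n_ambiguous": mat.n_ambiguous,
                        "cg_ratio_minus1": ratios[-1], "cg_ratio_0": ratios[0]})
    p = outdir / "motif_summary.tsv"
    pd.DataFrame(summary).to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths.append(p)
    return paths


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "hotspots": _stage_hotspots,
    "tss": _stage_tss,
    "enrich": _stage_enrich,
    "elements": _stage_elements,
    "expression": _stage_expression,
    "motif": _stage_motif,
}
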