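"""End-to-end orchestration: simulate -> synteny -> regions -> offtarget ->
expression -> network, with per-stage TSV outputs and a machine-readable
summary.

Reruns with the same configuration are byte-identical (no timestamps are
written). Every stage can be toggled off; a failing stage aborts the run
with the stage named.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr
from . import io as sio
from . import network as net
from . import offtarget as ot
from . import regions as reg
from . import simulate as sim
from . import synteny as syn


@dataclass
class PipelineConfig:
    """Serializable configuration for the whole pipeline."""

    seed: int = 0
    outdir: str = "syndel_out"
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "synteny": True, "regions": True,
        "offtarget": True, "expression": True, "network": True,
    })
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    chain: syn.ChainParams = field(default_factory=syn.ChainParams)
    merge_gap_genes: int = 40
    alpha_beta_max: float = 1.2          # Ks boundary between recent WGDs and the old WGT
    tandem_max_rank_gap: int = 10
    spacer: str | None = None            # default: drawn from the seed
    pam_pattern: str = "NNGRRT"
    max_mismatches: int = 3
    max_dna_bulge: int = 2
    max_rna_bulge: int = 1
    offtarget_genome_length: int = 20_000
    de_fdr_threshold: float = 0.05
    n_boot: int = 10_000
    density_target: float = 2.15

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["wgd_events"] = [dataclasses.asdict(e) if not isinstance(e, dict) else e
                                         for e in d["simulation"]["wgd_events"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            s = dict(d["simulation"])
            s["wgd_events"] = [sim.WgdEvent(**e) for e in s.get("wgd_events", [])]
            for key in ("within_module_weight", "between_module_weight"):
                if key in s and isinstance(s[key], list):
                    s[key] = tuple(s[key])
            d["simulation"] = sim.SimulationConfig(**s)
        if "chain" in d:
            d["chain"] = syn.ChainParams(**d["chain"])
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and write per-stage tables under
    ``config.outdir``. Returns the summary dictionary (also written as
    ``summary.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages_run": []}
    state: dict = {}

    stage_order = ["simulate", "synteny", "regions", "offtarget", "expression", "network"]
    runners = {
        "simulate": _stage_simulate, "synteny": _stage_synteny,
        "regions": _stage_regions, "offtarget": _stage_offtarget,
        "expression": _stage_expression, "network": _stage_network,
    }
    for name in stage_order:
        if not config.stages.get(name, False):
            continue
        try:
            runners[name](config, state, summary, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        summary["stages_run"].append(name)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    with open(out / "run_log.txt", "w") as fh:
        fh.write("syndel pipeline run\n")
        fh.write(json.dumps(config.to_dict(), indent=2, sort_keys=True, default=_jsonable))
        fh.write("\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_simulate(config, state, summary, out):
    scfg = dataclasses.replace(config.simulation, seed=config.seed)
    genome = sim.generate_genome(scfg)
    state["genome"] = genome
    sio.write_gff3(genome.annotation, out / "genome.gff3")
    sio.write_tsv(genome.anchors, out / "anchors.tsv")
    sio.write_tsv(genome.truth_blocks, out / "truth_blocks.tsv")
    sio.write_orthogroups(genome.orthogroups, out / "orthogroups.tsv")
    summary["simulate"] = {
        "n_genes": int(len(genome.annotation.genes)),
        "n_tes": int(len(genome.annotation.tes)),
        "n_anchors": int(len(genome.anchors)),
        "n_truth_blocks": int(len(genome.truth_blocks)),
    }


def _stage_synteny(config, state, summary, out):
    genome = state["genome"]
    blocks = syn.chain_anchors(genome.anchors, config.chain)
    blocks = syn.merge_blocks(blocks, config.merge_gap_genes)
    syn.date_blocks(blocks, alpha_beta_max=config.alpha_beta_max)
    state["blocks"] = blocks
    sio.write_tsv(syn.blocks_to_frame(blocks, genome.annotation), out / "blocks.tsv")
    stats = syn.block_stats(blocks, genome.annotation)
    sio.write_tsv(stats, out / "block_stats.tsv")
    summary["synteny"] = {"n_blocks": len(blocks)}


def _stage_regions(config, state, summary, out):
    genome, blocks = state["genome"], state["blocks"]
    tandems = syn.find_tandem_duplicates(genome.annotation.genes, genome.orthogroups,
                                         config.tandem_max_rank_gap)
    tandem_genes = set().union(*tandems) if tandems else set()
    candidates = reg.select_candidates(blocks, genome.annotation,
                                       require_no_lethal=True, tandem_genes=tandem_genes)
    state["candidates"] = candidates
    sio.write_tsv(reg.region_report(candidates), out / "candidate_regions.tsv")
    if candidates:
        focal = candidates[0]
        block = next(b for b in blocks if b.block_id == focal.block_id)
        reg.categorize_genes(focal, set(block.genes_a), genome.orthogroups)
        state["focal_region"] = focal
        cats = pd.DataFrame(sorted(focal.gene_categories.items()),
                            columns=["gene", "category"])
        sio.write_tsv(cats, out / "focal_region_gene_categories.tsv")
        summary["regions"] = {
            "n_candidates": len(candidates),
            "focal_block": focal.block_id,
            "focal_length_bp": focal.length,
            "focal_genes": focal.gene_count,
        }
    else:
        summary["regions"] = {"n_candidates": 0}


def _stage_offtarget(config, state, summary, out):
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 99)))
    spacer = config.spacer or "".join(rng.choice(list("ACGT"), size=21))
    planted = [
        sim.PlantedSite(0), sim.PlantedSite(2), sim.PlantedSite(3, strand="-"),
        sim.PlantedSite(1, "dna", 1), sim.PlantedSite(2, "rna", 1, strand="-"),
        sim.PlantedSite(5),  # beyond-threshold decoy
    ]
    genome_seq, truth = sim.generate_offtarget_genome(
        spacer, planted, config.offtarget_genome_length,
        pam_pattern=config.pam_pattern, seed=config.seed)
    query = ot.SpacerQuery(spacer, config.pam_pattern, config.max_mismatches,
                           config.max_dna_bulge, config.max_rna_bulge)
    hits = ot.search(query, genome_seq)
    sio.write_fasta(genome_seq, out / "offtarget_genome.fa")
    sio.write_tsv(truth, out / "offtarget_truth.tsv")
    sio.write_tsv(ot.hits_to_frame(hits), out / "offtarget_hits.tsv")
    summary["offtarget"] = {"spacer": spacer, "n_hits": len(hits),
                            "n_planted": len(planted)}


def _stage_expression(config, state, summary, out):
    genome = state["genome"]
    focal = state.get("focal_region")
    region_genes = focal.genes if focal else []
    counts = sim.generate_counts(genome, region_genes)
    state["counts"] = counts
    sio.write_tsv(counts.counts, out / "counts.tsv", index=True)
    sio.write_tsv(counts.meta, out / "sample_meta.tsv")
    de = {}
    for geno in ("het", "hom"):
        de[geno] = expr.nb_test(counts.counts, counts.meta, contrast=(geno, "wt"),
                                fdr_threshold=config.de_fdr_threshold)
        sio.write_tsv(de[geno].reset_index(), out / f"de_{geno}_vs_wt.tsv")
    state["de"] = de
    dosage = expr.orthogroup_dosage(counts.counts, counts.meta, genome.orthogroups,
                                    region_genes, mutant="het")
    sio.write_tsv(dosage, out / "dosage_het_vs_wt.tsv")
    summary["expression"] = {
        "n_de_up_hom": int((de["hom"]["status"] == "up").sum()),
        "n_de_down_hom": int((de["hom"]["status"] == "down").sum()),
        "n_affected_orthogroups": int(len(dosage)),
    }


def _stage_network(config, state, summary, out):
    genome = state["genome"]
    focal = state.get("focal_region")
    region_genes = [g for g in (focal.genes if focal else [])]
    network = sim.generate_network(genome)
    state["network"] = network
    enr = net.module_enrichment(region_genes, network, list_name="deleted")
    sio.write_tsv(enr, out / "module_enrichment.tsv")
    summary["network"] = {"n_enriched_modules": int(enr["significant"].sum())}
    if not region_genes:
        return
    obs, p = net.centrality_bootstrap(network, region_genes, n_boot=config.n_boot,
                                      seed=config.seed)
    results = []
    weights = net.max_edge_to_set(network, region_genes)
    for direction in ("up", "down"):
        status = (state["de"]["hom"]["status"] == direction).astype(int)
        status = status.loc[status.index.intersection(weights.index)]
        if status.nunique() < 2:
            continue  # no DE genes in this direction: regression undefined
        results.append(net.logistic_connectivity(
            weights, status, deletion_label=focal.block_id if focal else "",
            comparison_label=f"hom vs wt DE {direction}"))
    if results:
        table = net.adjust_regressions(results)
        sio.write_tsv(table, out / "connectivity_regression.tsv")
    summary["network"].update({
        "deleted_mean_wnc": float(obs), "centrality_p": float(p),
        "n_regressions": len(results),
    })
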