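"""Synthetic inputs with the statistical structure the analyses assume.

The generators emulate a post-polyploidy plant genome: duplicated syntenic
blocks planted under fractionation, per-event lognormal Ks clouds, tandem
duplicates, TE annotations and lethality flags; negative-binomial RNA-seq
counts per genotype (wt / heterozygous / homozygous deletion) with optional
paralogue compensation; a modular weighted coexpression network; and a small
genome with planted nuclease off-target sites.

Every generator draws from its own seeded stream keyed off the master seed,
so adding one generator never perturbs the output of another, and a fixed
seed yields byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .models import (
    ANCHOR_COLUMNS,
    FEATURE_COLUMNS,
    CoexpressionNetwork,
    GenomeAnnotation,
)

# fixed stream keys: (seed, key) seeds an independent PCG64 stream
_STREAM_GENOME = 1
_STREAM_COUNTS = 2
_STREAM_NETWORK = 3
_STREAM_OFFTARGET = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes to the set of bases they match
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


@dataclass(frozen=True)
class WgdEvent:
    """One polyploidy event: its name, the mode and log-scale SD of its Ks
    cloud, and the probability that a duplicated block survives to the
    present (block-level retention)."""

    name: str
    ks_mode: float
    ks_sd: float
    retention_rate: float

    def __post_init__(self):
        if self.ks_mode <= 0 or self.ks_sd <= 0:
            raise ValueError("ks_mode and ks_sd must be positive")
        if not (0 < self.retention_rate <= 1):
            raise ValueError(
                f"retention_rate must be in (0, 1], got {self.retention_rate} "
                f"(0 leaves no anchors to chain)"
            )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome / counts / network generators.

    Defaults model a diploidized genome with two recorded polyploidy events
    (a recent one at Ks mode 0.8 and an ancient one at 2.0, echoing the
    alpha/beta vs gamma split of Brassicaceae), 40% gene fractionation
    inside retained blocks, and moderately overdispersed counts
    (NB dispersion 0.05) at a baseline mean of 100.
    """

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 1000
    wgd_events: list[WgdEvent] = field(default_factory=lambda: [
        WgdEvent("alpha_beta", ks_mode=0.8, ks_sd=0.20, retention_rate=0.5),
        WgdEvent("gamma", ks_mode=2.0, ks_sd=0.25, retention_rate=0.3),
    ])
    fractionation_rate: float = 0.4
    block_min_genes: int = 15
    block_max_genes: int = 40
    tandem_rate: float = 0.05
    tandem_max_gap: int = 3
    te_rate: float = 0.3
    lethal_rate: float = 0.1
    extra_orthogroup_rate: float = 0.02
    nb_dispersion: float = 0.05
    baseline_mean: float = 100.0
    baseline_log_sd: float = 1.0
    compensation_effect: float = 0.0
    n_replicates: int = 6
    n_modules: int = 8
    within_module_weight: tuple[float, float] = (0.6, 0.15)
    between_module_weight: tuple[float, float] = (0.1, 0.05)
    within_module_edge_p: float = 0.10
    between_module_edge_p: float = 0.005
    gene_length: int = 2000
    gene_spacing: int = 5000

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("n_chromosomes and genes_per_chromosome must be positive")
        if not self.wgd_events:
            raise ValueError("at least one WGD event is required")
        if not (0 <= self.fractionation_rate < 1):
            raise ValueError("fractionation_rate must be in [0, 1)")
        if self.block_min_genes < 2 or self.block_max_genes < self.block_min_genes:
            raise ValueError("invalid block size range")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("nb_dispersion and baseline_mean must be positive")


@dataclass
class SyntheticGenome:
    """A generated genome: annotation, anchor/Ks table, planted-block truth,
    and the orthogroup membership of every gene."""

    annotation: GenomeAnnotation
    anchors: pd.DataFrame          # ANCHOR_COLUMNS, with per-event Ks and truth label
    truth_blocks: pd.DataFrame     # one row per planted duplicate block
    orthogroups: pd.Series         # gene -> orthogroup id
    config: SimulationConfig

    def orthogroup_table(self) -> pd.DataFrame:
        """OrthoFinder-style table: one row per orthogroup, genes comma-joined."""
        grouped = self.orthogroups.groupby(self.orthogroups).groups
        rows = [
            {"Orthogroup": og, "focal": ", ".join(sorted(members))}
            for og, members in sorted(grouped.items())
        ]
        return pd.DataFrame(rows, columns=["Orthogroup", "focal"])


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label wins
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Generate an annotated genome with planted duplicated blocks.

    Chromosomes are tiled into ancestral segments; disjoint segment pairs
    are joined as duplicate blocks, each surviving for one polyploidy event
    with that event's retention probability. Within a retained block each
    ancestral gene keeps its partner (an anchor pair) with probability
    ``1 - fractionation_rate``; anchor Ks values are lognormal with mode at
    the event's ``ks_mode``. Tandem duplicates, TEs and lethality flags are
    planted independently.
    """
    rng = _rng(config.seed, _STREAM_GENOME)
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]

    # gene scaffold
    gene_rows = []
    for c in chroms:
        for i in range(config.genes_per_chromosome):
            start = 1000 + i * config.gene_spacing
            gene_rows.append({
                "feature_id": f"AT{c}G{(i + 1) * 10:05d}",
                "chrom": c,
                "start": start,
                "stop": start + config.gene_length,
                "strand": "+" if rng.random() < 0.5 else "-",
                "ftype": "gene",
                "rank": i,
                "lethal": bool(rng.random() < config.lethal_rate),
                "orthogroup": None,
            })
    genes = pd.DataFrame(gene_rows, columns=FEATURE_COLUMNS)
    ids_by_chrom = {c: genes.loc[genes["chrom"] == c, "feature_id"].tolist() for c in chroms}

    # tile each chromosome into candidate ancestral segments
    segments: list[tuple[str, int, int]] = []  # (chrom, rank_lo, length)
    for c in chroms:
        pos = 0
        while pos + config.block_min_genes <= config.genes_per_chromosome:
            size = int(rng.integers(config.block_min_genes, config.block_max_genes + 1))
            size = min(size, config.genes_per_chromosome - pos)
            segments.append((c, pos, size))
            pos += size

    order = rng.permutation(len(segments))
    pool = [segments[i] for i in order]

    anchor_rows, truth_rows = [], []
    uf = _UnionFind()
    block_no = 0
    while len(pool) >= 2:
        seg_a, seg_b = pool.pop(), pool.pop()
        event = None
        for ev in config.wgd_events:
            if rng.random() < ev.retention_rate:
                event = ev
                break
        if event is None:
            continue  # duplicate lost entirely
        block_no += 1
        block_id = f"TB{block_no:04d}"
        (ca, lo_a, len_a), (cb, lo_b, len_b) = seg_a, seg_b
        aligned = min(len_a, len_b)
        inverted = bool(rng.random() < 0.5)
        mu = math.log(event.ks_mode) + event.ks_sd ** 2  # lognormal mode = exp(mu - sd^2)
        n_kept = 0
        for i in range(aligned):
            if rng.random() < config.fractionation_rate:
                continue
            ra = lo_a + i
            rb = lo_b + (aligned - 1 - i if inverted else i)
            ga, gb = ids_by_chrom[ca][ra], ids_by_chrom[cb][rb]
            ks = float(rng.lognormal(mean=mu, sigma=event.ks_sd))
            anchor_rows.append({
                "gene_a": ga, "gene_b": gb, "chrom_a": ca, "chrom_b": cb,
                "rank_a": ra, "rank_b": rb, "ks": ks,
                "event": event.name, "truth_block": block_id,
            })
            uf.union(ga, gb)
            n_kept += 1
        truth_rows.append({
            "truth_block": block_id, "event": event.name,
            "chrom_a": ca, "rank_a_lo": lo_a, "rank_a_hi": lo_a + aligned - 1,
            "chrom_b": cb, "rank_b_lo": lo_b, "rank_b_hi": lo_b + aligned - 1,
            "orientation": -1 if inverted else 1,
            "aligned_genes": aligned, "n_anchors": n_kept,
        })

    anchors = pd.DataFrame(anchor_rows, columns=ANCHOR_COLUMNS + ["event", "truth_block"])
    truth_blocks = pd.DataFrame(truth_rows)

    # tandem duplicates: nearby same-orthogroup partners on one chromosome
    n_tandem = int(round(config.tandem_rate * len(genes)))
    tandem_seeds = rng.choice(len(genes), size=min(n_tandem, len(genes)), replace=False)
    for idx in sorted(tandem_seeds):
        row = genes.iloc[idx]
        gap = int(rng.integers(1, config.tandem_max_gap + 1))
        partner_rank = int(row["rank"]) + gap
        if partner_rank >= config.genes_per_chromosome:
            continue
        partner = ids_by_chrom[row["chrom"]][partner_rank]
        uf.union(row["feature_id"], partner)

    # extra multigene families beyond synteny/tandem
    n_extra = int(round(config.extra_orthogroup_rate * len(genes)))
    for _ in range(n_extra):
        size = int(rng.integers(3, 9))
        members = rng.choice(genes["feature_id"].to_numpy(), size=size, replace=False)
        for m in members[1:]:
            uf.union(str(members[0]), str(m))

    roots = {gid: uf.find(gid) for gid in genes["feature_id"]}
    root_ids = {r: f"OG{i:07d}" for i, r in enumerate(sorted(set(roots.values())))}
    og = pd.Series({gid: root_ids[r] for gid, r in roots.items()}, name="orthogroup")
    genes["orthogroup"] = genes["feature_id"].map(og)

    # TEs in intergenic space
    te_rows = []
    n_te = int(round(config.te_rate * len(genes)))
    host = rng.choice(len(genes), size=n_te, replace=True)
    for k, idx in enumerate(sorted(host)):
        row = genes.iloc[idx]
        start = int(row["stop"]) + int(rng.integers(100, config.gene_spacing - config.gene_length - 600))
        te_rows.append({
            "feature_id": f"TE{row['chrom']}_{k:05d}", "chrom": row["chrom"],
            "start": start, "stop": start + 500, "strand": "+",
            "ftype": "transposable_element", "rank": np.nan,
            "lethal": False, "orthogroup": None,
        })
    features = pd.concat([genes, pd.DataFrame(te_rows, columns=FEATURE_COLUMNS)],
                         ignore_index=True)
    features = features.sort_values(["chrom", "start", "feature_id"]).reset_index(drop=True)

    return SyntheticGenome(GenomeAnnotation(features), anchors, truth_blocks, og, config)


@dataclass
class CountData:
    """Simulated RNA-seq counts with sample metadata."""

    counts: pd.DataFrame          # genes x samples, integer
    meta: pd.DataFrame            # sample, genotype, timepoint
    true_means: pd.DataFrame      # genes x samples expected values
    compensated_genes: list[str]


_COPY_FACTOR = {"wt": 1.0, "het": 0.5, "hom": 0.0}


def generate_counts(
    genome: SyntheticGenome,
    region_genes: list[str],
    config: SimulationConfig | None = None,
    genotypes: tuple[str, ...] = ("wt", "het", "hom"),
    timepoints: tuple[str, ...] = ("t1",),
) -> CountData:
    """Simulate NB counts per genotype for a deletion of ``region_genes``.

    Gene means scale linearly with copy number inside the deleted region
    (1.0 wt / 0.5 het / 0.0 hom). When ``compensation_effect`` is nonzero,
    retained paralogues of deleted genes (same orthogroup, outside the
    region) have their mean multiplied by ``2**compensation_effect`` in the
    deletion genotypes only.
    """
    config = config or genome.config
    if config.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (differential expression needs replication)")
    unknown = [g for g in region_genes if g not in set(genome.orthogroups.index)]
    if unknown:
        raise ValueError(f"region genes absent from genome: {unknown[:3]}")
    for g in genotypes:
        if g not in _COPY_FACTOR:
            raise ValueError(f"unknown genotype {g!r}")

    rng = _rng(config.seed, _STREAM_COUNTS)
    gene_ids = list(genome.orthogroups.index)
    n_genes = len(gene_ids)
    base = rng.lognormal(mean=math.log(config.baseline_mean), sigma=config.baseline_log_sd,
                         size=n_genes)

    region_set = set(region_genes)
    region_ogs = set(genome.orthogroups.loc[list(region_set)])
    compensated = [
        g for g in gene_ids
        if g not in region_set and genome.orthogroups[g] in region_ogs
    ]

    in_region = np.array([g in region_set for g in gene_ids])
    comp_mask = np.array([g in set(compensated) for g in gene_ids])

    samples, col_means = [], []
    for tp in timepoints:
        for geno in genotypes:
            factor = np.ones(n_genes)
            factor[in_region] = _COPY_FACTOR[geno]
            if geno != "wt" and config.compensation_effect != 0:
                factor[comp_mask] *= 2.0 ** config.compensation_effect
            for r in range(config.n_replicates):
                samples.append({"sample": f"{geno}_{tp}_{r + 1}", "genotype": geno,
                                "timepoint": tp})
                col_means.append(base * factor)

    mu = np.column_stack(col_means)
    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)  # scale 0 -> lambda 0 -> count 0
    counts = rng.poisson(lam)

    meta = pd.DataFrame(samples)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=meta["sample"])
    means_df = pd.DataFrame(mu, index=gene_ids, columns=meta["sample"])
    return CountData(counts_df, meta, means_df, compensated)


def generate_network(
    genome: SyntheticGenome,
    config: SimulationConfig | None = None,
    hub_genes: tuple[str, ...] = (),
    hub_factor: float = 10.0,
) -> CoexpressionNetwork:
    """Generate a modular weighted coexpression network over the genome's genes.

    Genes are split evenly into ``n_modules`` modules; within-module edges
    are denser and heavier than between-module edges (truncated-normal
    weights; non-positive draws are dropped, so a between-module weight
    distribution with all mass at 0 yields disconnected module subgraphs).
    ``hub_genes`` have their incident edge weights multiplied by
    ``hub_factor`` to plant known high-centrality genes.
    """
    config = config or genome.config
    genes = list(genome.orthogroups.index)
    if config.n_modules < 2:
        raise ValueError("n_modules must be >= 2")
    if config.n_modules > len(genes):
        raise ValueError("more modules than genes")

    rng = _rng(config.seed, _STREAM_NETWORK)
    order = rng.permutation(len(genes))
    module_of = {}
    for pos, idx in enumerate(order):
        module_of[genes[idx]] = pos % config.n_modules
    modules = pd.Series(module_of, name="module").loc[genes]

    hub_set = set(hub_genes)
    unknown_hubs = hub_set - set(genes)
    if unknown_hubs:
        raise ValueError(f"hub genes absent from genome: {sorted(unknown_hubs)[:3]}")

    g = nx.Graph()
    g.add_nodes_from(genes)

    def _add_edges(pairs: np.ndarray, loc: float, scale: float) -> None:
        if len(pairs) == 0:
            return
        w = rng.normal(loc, scale, size=len(pairs))
        for (i, j), weight in zip(pairs, w):
            if weight <= 0:
                continue
            a, b = genes[i], genes[j]
            if a in hub_set or b in hub_set:
                weight *= hub_factor
            g.add_edge(a, b, weight=float(weight))

    gene_idx = {gid: i for i, gid in enumerate(genes)}
    for m in range(config.n_modules):
        members = np.array([gene_idx[gid] for gid in modules.index[modules == m]])
        if len(members) < 2:
            continue
        ii, jj = np.triu_indices(len(members), k=1)
        keep = rng.random(len(ii)) < config.within_module_edge_p
        _add_edges(np.column_stack([members[ii[keep]], members[jj[keep]]]),
                   *config.within_module_weight)

    n = len(genes)
    n_cross_target = int(config.between_module_edge_p * n * (n - 1) / 2)
    if n_cross_target > 0:
        ii = rng.integers(0, n, size=2 * n_cross_target)
        jj = rng.integers(0, n, size=2 * n_cross_target)
        mod_arr = modules.to_numpy()
        # map positional gene index -> module via the genes ordering
        mods = pd.Series(mod_arr, index=genes)
        cross = [(int(a), int(b)) for a, b in zip(ii, jj)
                 if a != b and mods.iloc[a] != mods.iloc[b]][:n_cross_target]
        _add_edges(np.array(cross, dtype=int).reshape(-1, 2),
                   *config.between_module_weight)

    return CoexpressionNetwork(g, modules)


@dataclass(frozen=True)
class PlantedSite:
    """Description of one planted off-target site."""

    mismatches: int
    bulge_type: str = "none"   # none | dna | rna
    bulge_size: int = 0
    strand: str = "+"

    def __post_init__(self):
        if self.bulge_type not in ("none", "dna", "rna"):
            raise ValueError(f"invalid bulge_type {self.bulge_type!r}")
        if self.bulge_type == "none" and self.bulge_size != 0:
            raise ValueError("bulge_size must be 0 when bulge_type is 'none'")
        if self.bulge_type != "none" and self.bulge_size < 1:
            raise ValueError("bulged site needs bulge_size >= 1")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")


def _sample_pam(pam_pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in pam_pattern)


def generate_offtarget_genome(
    spacer: str,
    planted: list[PlantedSite],
    length: int,
    pam_pattern: str = "NNGRRT",
    seed: int = 0,
    chrom_name: str = "synth1",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with planted (possibly edited) protospacer sites.

    Each planted site is the spacer with the requested bulge applied (dna =
    bases inserted into the genomic site, rna = spacer bases absent from the
    site), the requested number of substitutions, and a concrete PAM
    instance 3' of the protospacer; reverse-strand sites are inserted as the
    reverse complement. Returns the genome as ``{chrom: sequence}`` and a
    truth table with exact protospacer coordinates (0-based half-open, on
    the forward strand) and edit descriptions.
    """
    spacer = spacer.upper()
    if len(spacer) != 21 or set(spacer) - set("ACGT"):
        raise ValueError("spacer must be 21 nt over A/C/G/T")
    rng = _rng(seed, _STREAM_OFFTARGET)
    bases = np.array(list("ACGT"))

    site_seqs = []
    for p in planted:
        core = list(spacer)
        if p.bulge_type == "dna":
            pos = int(rng.integers(1, len(core)))
            ins = [str(b) for b in rng.choice(bases, size=p.bulge_size)]
            spacer_derived = [True] * len(core)
            core = core[:pos] + ins + core[pos:]
            spacer_derived = spacer_derived[:pos] + [False] * p.bulge_size + spacer_derived[pos:]
        elif p.bulge_type == "rna":
            if p.bulge_size > len(core) - 2:
                raise ValueError("rna bulge larger than spacer allows")
            pos = int(rng.integers(1, len(core) - p.bulge_size))
            core = core[:pos] + core[pos + p.bulge_size:]
            spacer_derived = [True] * len(core)
        else:
            spacer_derived = [True] * len(core)
        editable = [i for i, d in enumerate(spacer_derived) if d]
        if p.mismatches > len(editable):
            raise ValueError("more mismatches than spacer positions")
        for i in rng.choice(editable, size=p.mismatches, replace=False):
            core[i] = str(rng.choice([b for b in "ACGT" if b != core[i]]))
        site_seqs.append("".join(core) + _sample_pam(pam_pattern, rng))

    total = sum(len(s) + 60 for s in site_seqs)
    if total > length:
        raise ValueError(f"planted sites do not fit in genome of length {length}")

    seq = rng.choice(bases, size=length)
    placed: list[tuple[int, int]] = []
    truth_rows = []
    for p, full in zip(planted, site_seqs):
        for _ in range(1000):
            start = int(rng.integers(30, length - len(full) - 30))
            if all(start + len(full) + 30 <= s or start >= e + 30 for s, e in placed):
                break
        else:
            raise ValueError("could not place planted sites without overlap")
        placed.append((start, start + len(full)))
        inserted = full if p.strand == "+" else revcomp(full)
        seq[start:start + len(full)] = list(inserted)
        core_len = len(full) - len(pam_pattern)
        if p.strand == "+":
            core_start = start
        else:
            core_start = start + len(pam_pattern)
        truth_rows.append({
            "chrom": chrom_name, "start": core_start, "stop": core_start + core_len,
            "strand": p.strand, "mismatches": p.mismatches,
            "bulge_type": p.bulge_type, "bulge_size": p.bulge_size,
            "site_seq": full[:core_len],
        })

    genome = {chrom_name: "".join(seq)}
    truth = pd.DataFrame(truth_rows).sort_values(["start"]).reset_index(drop=True)
    return genome, truth
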