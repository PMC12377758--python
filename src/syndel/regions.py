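"""Deletion-interval annotation, candidate selection and gene categorization.

An interval's content accounting mirrors the deleted-block summary tables of
block-deletion studies: genes, tandem duplicates, lethal-flagged genes,
TEs/other annotations, and syntenic (anchor) genes, with length defined as
``stop - start`` on 0-based half-open coordinates. A feature is counted if
its span overlaps the interval at all (configurable to full containment).
"""
from __future__ import annotations

import pandas as pd

from .models import DeletionRegion, GenomeAnnotation, GenomicInterval, SyntenicBlock


def annotate_interval(
    genome: GenomeAnnotation,
    interval: GenomicInterval,
    syntenic_genes: set[str] | None = None,
    tandem_genes: set[str] | None = None,
    block_id: str | None = None,
    overlap: str = "any",
) -> DeletionRegion:
    """Account for the genes, TEs, tandem duplicates, lethal genes and
    syntenic genes falling in an interval.

    ``syntenic_genes`` is the set of anchor genes from the block analysis;
    ``tandem_genes`` the union of tandem-duplicate sets. ``overlap`` is
    'any' (default) or 'within'.
    """
    hits = genome.features_in(interval, how=overlap)
    genes = hits[hits["ftype"] == "gene"]
    gene_ids = genes["feature_id"].tolist()
    syntenic_genes = syntenic_genes or set()
    tandem_genes = tandem_genes or set()
    return DeletionRegion(
        interval=interval,
        block_id=block_id,
        genes=gene_ids,
        te_count=int((hits["ftype"] != "gene").sum()),
        tandem_count=sum(g in tandem_genes for g in gene_ids),
        lethal_count=int(genes["lethal"].sum()),
        syntenic_gene_count=sum(g in syntenic_genes for g in gene_ids),
    )


def select_candidates(
    blocks: list[SyntenicBlock],
    genome: GenomeAnnotation,
    max_length: int | None = None,
    require_no_lethal: bool = True,
    side: str = "a",
    tandem_genes: set[str] | None = None,
) -> list[DeletionRegion]:
    """Deletion candidates from syntenic blocks.

    Each block's region on ``side`` is annotated; regions containing any
    lethal-flagged gene are excluded when ``require_no_lethal`` is set, as
    are regions longer than ``max_length`` bp. Sorted by length descending
    (ties by block id), deterministic.
    """
    out = []
    for b in blocks:
        interval = b.region(genome, side)
        anchor_genes = set(b.genes_a if side == "a" else b.genes_b)
        region = annotate_interval(genome, interval, syntenic_genes=anchor_genes,
                                   tandem_genes=tandem_genes, block_id=b.block_id)
        if require_no_lethal and region.lethal_count > 0:
            continue
        if max_length is not None and region.length > max_length:
            continue
        out.append(region)
    out.sort(key=lambda r: (-r.length, r.block_id or ""))
    return out


def categorize_genes(
    region: DeletionRegion,
    syntenic_genes: set[str],
    orthogroups: pd.Series,
) -> dict[str, str]:
    """Label every region gene as syntenic_paralogue, multigene_orthogroup,
    or single_copy.

    Priority: a syntenic anchor gene is a syntenic_paralogue even when its
    orthogroup is large; otherwise membership in an orthogroup with >= 2
    genes makes it multigene_orthogroup; the rest are single_copy. Genes
    absent from the orthogroup table are treated as singletons.
    """
    og_sizes = orthogroups.value_counts()
    categories = {}
    for g in region.genes:
        if g in syntenic_genes:
            categories[g] = "syntenic_paralogue"
        elif g in orthogroups.index and og_sizes[orthogroups[g]] >= 2:
            categories[g] = "multigene_orthogroup"
        else:
            categories[g] = "single_copy"
    region.gene_categories = categories
    return categories


def homeologous_interval(
    region: DeletionRegion | GenomicInterval,
    block: SyntenicBlock,
    genome: GenomeAnnotation,
) -> GenomicInterval | None:
    """The region on the block's B side homeologous to a deletion interval:
    the minimal interval spanning the partners of every anchor whose A-side
    gene falls in the deletion interval. None when no anchor falls inside."""
    interval = region.interval if isinstance(region, DeletionRegion) else region
    if interval.chromosome != block.chrom_a:
        raise ValueError("interval chromosome does not match the block's A side")
    partners = []
    for _, a in block.anchors.iterrows():
        feat = genome.feature(a["gene_a"])
        if interval.overlaps(int(feat["start"]), int(feat["stop"])):
            partners.append(a["gene_b"])
    if not partners:
        return None
    rows = genome.features[genome.features["feature_id"].isin(partners)]
    return GenomicInterval(block.chrom_b, int(rows["start"].min()), int(rows["stop"].max()))


def region_report(regions: list[DeletionRegion]) -> pd.DataFrame:
    """Deleted-region summary table (one row per region, bp coordinates)."""
    rows = [{
        "block_id": r.block_id, "chrom": r.interval.chromosome,
        "start": r.interval.start, "stop": r.interval.stop, "length": r.length,
        "genes": r.gene_count, "tandem_duplicates": r.tandem_count,
        "lethal_genes": r.lethal_count, "tes_other": r.te_count,
        "syntenic_genes": r.syntenic_gene_count,
    } for r in regions]
    return pd.DataFrame(rows, columns=["block_id", "chrom", "start", "stop", "length",
                                       "genes", "tandem_duplicates", "lethal_genes",
                                       "tes_other", "syntenic_genes"])
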