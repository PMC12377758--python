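"""Core data containers shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; GFF3 files are
converted on read/write. Gene order ("rank") is the index of a gene along
its chromosome, counting genes only — collinearity chaining operates on
ranks, interval accounting on base pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: column order for anchor-pair tables (one homologous collinear gene pair per row)
ANCHOR_COLUMNS = ["gene_a", "gene_b", "chrom_a", "chrom_b", "rank_a", "rank_b", "ks"]

#: column order for annotation feature tables
FEATURE_COLUMNS = [
    "feature_id", "chrom", "start", "stop", "strand", "ftype",
    "rank", "lethal", "orthogroup",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, so ``length == stop - start``."""

    chromosome: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(f"stop ({self.stop}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.stop - self.start

    def overlaps(self, start: int, stop: int) -> bool:
        return start < self.stop and stop > self.start

    def contains(self, start: int, stop: int) -> bool:
        return start >= self.start and stop <= self.stop


class GenomeAnnotation:
    """Ordered gene and TE records on chromosomes.

    Wraps a feature table with columns :data:`FEATURE_COLUMNS`. Genes carry a
    per-chromosome rank (0-based gene-order index); TEs and other
    annotations have rank NaN.
    """

    def __init__(self, features: pd.DataFrame):
        missing = set(FEATURE_COLUMNS) - set(features.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        if features["feature_id"].duplicated().any():
            dup = features.loc[features["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise ValueError(f"duplicate feature ID: {dup}")
        if (features["stop"] < features["start"]).any():
            raise ValueError("feature with stop < start")
        self.features = features.reset_index(drop=True)
        self._by_id = self.features.set_index("feature_id", drop=False)

    @property
    def genes(self) -> pd.DataFrame:
        return self.features[self.features["ftype"] == "gene"]

    @property
    def tes(self) -> pd.DataFrame:
        return self.features[self.features["ftype"] != "gene"]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.features["chrom"].unique())

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id.index

    def feature(self, feature_id: str) -> pd.Series:
        return self._by_id.loc[feature_id]

    def gene_rank(self, gene_id: str) -> int:
        return int(self._by_id.loc[gene_id, "rank"])

    def features_in(self, interval: GenomicInterval, how: str = "any") -> pd.DataFrame:
        """Features overlapping (``how='any'``) or contained in (``'within'``) an interval."""
        if interval.chromosome not in set(self.features["chrom"]):
            raise KeyError(f"unknown chromosome: {interval.chromosome!r}")
        on_chrom = self.features[self.features["chrom"] == interval.chromosome]
        if how == "any":
            mask = (on_chrom["start"] < interval.stop) & (on_chrom["stop"] > interval.start)
        elif how == "within":
            mask = (on_chrom["start"] >= interval.start) & (on_chrom["stop"] <= interval.stop)
        else:
            raise ValueError(f"how must be 'any' or 'within', got {how!r}")
        return on_chrom[mask]

    def genes_between_ranks(self, chrom: str, lo: int, hi: int) -> pd.DataFrame:
        """Genes with rank in [lo, hi] on one chromosome, in rank order."""
        g = self.genes[self.genes["chrom"] == chrom]
        g = g[(g["rank"] >= lo) & (g["rank"] <= hi)]
        return g.sort_values("rank")


@dataclass
class SyntenicBlock:
    """A pair of collinear regions joined by anchor gene pairs.

    ``orientation`` is +1 when rank_b increases with rank_a and -1 when it
    decreases (an inverted block). Anchors are stored sorted by rank_a.
    """

    block_id: str
    chrom_a: str
    chrom_b: str
    orientation: int
    anchors: pd.DataFrame
    ks_mode: float | None = None
    age_class: str = "unassigned"
    merged_from: list[str] = field(default_factory=list)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def rank_span_a(self) -> tuple[int, int]:
        return int(self.anchors["rank_a"].min()), int(self.anchors["rank_a"].max())

    @property
    def rank_span_b(self) -> tuple[int, int]:
        return int(self.anchors["rank_b"].min()), int(self.anchors["rank_b"].max())

    @property
    def genes_a(self) -> list[str]:
        return list(self.anchors["gene_a"])

    @property
    def genes_b(self) -> list[str]:
        return list(self.anchors["gene_b"])

    def region(self, genome: GenomeAnnotation, side: str = "a") -> GenomicInterval:
        """Minimal bp interval covering all anchor genes on one side."""
        chrom = self.chrom_a if side == "a" else self.chrom_b
        genes = self.genes_a if side == "a" else self.genes_b
        rows = genome.features[genome.features["feature_id"].isin(genes)]
        return GenomicInterval(chrom, int(rows["start"].min()), int(rows["stop"].max()))


@dataclass
class DeletionRegion:
    """A candidate or realized deletion interval with its content accounting."""

    interval: GenomicInterval
    block_id: str | None
    genes: list[str]
    te_count: int
    tandem_count: int
    lethal_count: int
    syntenic_gene_count: int
    gene_categories: dict[str, str] = field(default_factory=dict)

    @property
    def gene_count(self) -> int:
        return len(self.genes)

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class CoexpressionNetwork:
    """Weighted undirected gene graph with a module assignment per gene."""

    graph: nx.Graph
    modules: pd.Series  # gene -> module id

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def module_members(self, module) -> list[str]:
        return list(self.modules.index[self.modules == module])

    def copy(self) -> "CoexpressionNetwork":
        return CoexpressionNetwork(self.graph.copy(), self.modules.copy())


def as_anchor_frame(records) -> pd.DataFrame:
    """Build a canonical anchor table from records, validating dtypes."""
    df = pd.DataFrame(records, columns=ANCHOR_COLUMNS)
    if len(df) and (df["ks"].dropna() < 0).any():
        raise ValueError("negative Ks value in anchor table")
    df["rank_a"] = df["rank_a"].astype(np.int64)
    df["rank_b"] = df["rank_b"].astype(np.int64)
    return df
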