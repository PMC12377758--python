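"""Syntenic-block detection from anchor pairs, plus Ks-mode dating.

Collinear chaining follows the DAGChainer-style parameterization used by
SynMap: a maximum gene-rank gap of 20 between consecutive anchors in both
genomes (-D 20) and at least 5 anchors per chain (-A 5), i.e. blocks have
at least five syntenic genes per 20-gene window. Chains are found by
dynamic programming per chromosome pair and orientation, peeling off the
best chain and repeating; the score is the anchor count (no gap penalty),
with ties broken by leftmost (rank_a, rank_b) for determinism.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .models import GenomeAnnotation, SyntenicBlock


@dataclass(frozen=True)
class ChainParams:
    """Collinearity chaining parameters (gene-rank units)."""

    max_gap_genes: int = 20
    min_anchors: int = 5
    window_genes: int = 20

    def __post_init__(self):
        if min(self.max_gap_genes, self.min_anchors, self.window_genes) <= 0:
            raise ValueError("all chaining parameters must be positive")
        if self.min_anchors > self.window_genes:
            raise ValueError("min_anchors must be <= window_genes")


def _best_chain(ra: np.ndarray, rb: np.ndarray, orientation: int, max_gap: int):
    """Longest collinear chain by DP over anchors sorted by (rank_a, rank_b).

    Returns (indices into the arrays, length). Strictly increasing in rank_a;
    rank_b strictly increasing (orientation +1) or decreasing (-1); consecutive
    gaps <= max_gap on both sides. Ties prefer the leftmost chain.
    """
    n = len(ra)
    if n == 0:
        return [], 0
    order = np.lexsort((rb if orientation > 0 else -rb, ra))
    ra_s, rb_s = ra[order], rb[order]
    score = np.ones(n, dtype=int)
    prev = np.full(n, -1)
    for i in range(n):
        for j in range(i):
            da = ra_s[i] - ra_s[j]
            if da <= 0 or da > max_gap:
                continue
            db = (rb_s[i] - rb_s[j]) * orientation
            if db <= 0 or db > max_gap:
                continue
            if score[j] + 1 > score[i]:
                score[i] = score[j] + 1
                prev[i] = j
    best = int(np.argmax(score))  # argmax takes the first (leftmost) maximum
    chain = []
    k = best
    while k != -1:
        chain.append(k)
        k = prev[k]
    chain.reverse()
    return [int(order[k]) for k in chain], int(score[best])


def chain_anchors(anchors: pd.DataFrame, params: ChainParams = ChainParams()) -> list[SyntenicBlock]:
    """Chain anchor pairs into syntenic blocks.

    Anchors are grouped by chromosome pair; within each pair, best chains in
    either orientation are peeled off greedily until none with at least
    ``min_anchors`` anchors remains. Output is deterministic and
    independent of the input row order.
    """
    if anchors.empty:
        return []
    anchors = anchors.drop_duplicates(subset=["gene_a", "gene_b"])
    for side in "ab":
        per_gene = anchors.groupby(f"gene_{side}")[f"rank_{side}"].nunique()
        if (per_gene > 1).any():
            raise ValueError(f"inconsistent rank_{side} for gene(s): "
                             f"{list(per_gene.index[per_gene > 1])[:3]}")

    blocks: list[SyntenicBlock] = []
    for (ca, cb), grp in sorted(anchors.groupby(["chrom_a", "chrom_b"]),
                                key=lambda kv: kv[0]):
        grp = grp.sort_values(["rank_a", "rank_b"]).reset_index(drop=True)
        remaining = grp
        while len(remaining) >= params.min_anchors:
            ra = remaining["rank_a"].to_numpy()
            rb = remaining["rank_b"].to_numpy()
            cand = []
            for orientation in (1, -1):
                idx, length = _best_chain(ra, rb, orientation, params.max_gap_genes)
                cand.append((length, -orientation, idx))  # prefer + on ties
            length, neg_orient, idx = max(cand, key=lambda t: (t[0], t[1]))
            if length < params.min_anchors:
                break
            chain_df = remaining.iloc[idx].sort_values("rank_a").reset_index(drop=True)
            blocks.append(SyntenicBlock(
                block_id="", chrom_a=ca, chrom_b=cb, orientation=-neg_orient,
                anchors=chain_df.reset_index(drop=True),
            ))
            remaining = remaining.drop(remaining.index[idx]).reset_index(drop=True)

    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.rank_span_a, b.rank_span_b))
    for i, b in enumerate(blocks):
        b.block_id = f"SB{i + 1:04d}"
    return blocks


def _mergeable(b1: SyntenicBlock, b2: SyntenicBlock, gap: int) -> bool:
    if (b1.chrom_a, b1.chrom_b, b1.orientation) != (b2.chrom_a, b2.chrom_b, b2.orientation):
        return False
    lo1, hi1 = b1.rank_span_a
    lo2, hi2 = b2.rank_span_a
    if lo1 > lo2:
        b1, b2 = b2, b1
        lo1, hi1, lo2, hi2 = lo2, hi2, lo1, hi1
    if lo2 - hi1 > gap or lo2 - hi1 < 0:
        return False
    # gap on the B side, respecting orientation
    if b1.orientation > 0:
        gap_b = b2.rank_span_b[0] - b1.rank_span_b[1]
    else:
        gap_b = b1.rank_span_b[0] - b2.rank_span_b[1]
    return 0 <= gap_b <= gap


def merge_blocks(blocks: list[SyntenicBlock], merge_gap_genes: int = 40) -> list[SyntenicBlock]:
    """Merge nearby same-pair, same-orientation blocks (quota-align style).

    The merge relation is closed transitively (connected components), so the
    result is order-independent and the operation is idempotent.
    """
    n = len(blocks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _mergeable(blocks[i], blocks[j], merge_gap_genes):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(blocks[members[0]])
            continue
        parts = [blocks[i] for i in members]
        anchors = (pd.concat([p.anchors for p in parts])
                   .sort_values(["rank_a", "rank_b"]).reset_index(drop=True))
        provenance = []
        for p in parts:
            provenance.extend(p.merged_from or [p.block_id])
        merged.append(SyntenicBlock(
            block_id="", chrom_a=parts[0].chrom_a, chrom_b=parts[0].chrom_b,
            orientation=parts[0].orientation, anchors=anchors,
            merged_from=sorted(provenance),
        ))
    merged.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.rank_span_a, b.rank_span_b))
    for i, b in enumerate(merged):
        if not b.block_id:
            b.block_id = f"MB{i + 1:04d}"
    return merged


KS_GRID = np.arange(0.0, 5.0 + 1e-9, 0.005)


def ks_mode(ks_values, bandwidth: float | str = "silverman") -> float:
    """Mode of a Ks sample by Gaussian KDE evaluated on a fixed grid (0-5,
    step 0.005). Degenerate samples (single value or zero spread) return
    that value directly. Returns NaN when no Ks values are present."""
    ks = np.asarray(pd.Series(ks_values).dropna(), dtype=float)
    if ks.size == 0:
        return float("nan")
    if ks.size == 1 or np.ptp(ks) == 0:
        return float(ks[0])
    kde = gaussian_kde(ks, bw_method=bandwidth)
    density = kde(KS_GRID)
    return float(KS_GRID[int(np.argmax(density))])


def classify_age(mode: float, alpha_beta_max: float) -> str:
    """Classify a block's duplication age from its Ks mode.

    ``alpha_beta_max`` is the caller-supplied Ks boundary separating the
    recent duplications (alpha/beta) from the ancient triplication (gamma);
    the boundary itself is inclusive on the alpha/beta side. No universal
    boundary exists — it depends on the lineage's substitution rate — so it
    must be given explicitly.
    """
    if np.isnan(mode):
        return "unassigned"
    if mode < 0:
        raise ValueError("ks mode must be non-negative")
    return "alpha_beta" if mode <= alpha_beta_max else "gamma"


def date_blocks(blocks: list[SyntenicBlock], alpha_beta_max: float,
                bandwidth: float | str = "silverman") -> list[SyntenicBlock]:
    """Fill each block's ks_mode and age_class in place; returns the list."""
    for b in blocks:
        b.ks_mode = ks_mode(b.anchors["ks"], bandwidth)
        b.age_class = classify_age(b.ks_mode, alpha_beta_max)
    return blocks


def find_tandem_duplicates(genes: pd.DataFrame, groups: pd.Series,
                           max_rank_gap: int = 10) -> list[set[str]]:
    """Maximal runs of >= 2 same-group genes on one chromosome with at most
    ``max_rank_gap`` intervening genes between consecutive members
    (transitive closure, so a run may span more than the gap overall).

    ``genes`` needs columns feature_id / chrom / rank; ``groups`` maps gene
    to its homology group. Returns sets of gene IDs, deterministic order.
    """
    out: list[set[str]] = []
    df = genes[["feature_id", "chrom", "rank"]].copy()
    df["group"] = df["feature_id"].map(groups)
    df = df.dropna(subset=["group"])
    for (_, _), grp in sorted(df.groupby(["chrom", "group"]), key=lambda kv: kv[0]):
        grp = grp.sort_values("rank")
        run = [grp.iloc[0]]
        for _, row in grp.iloc[1:].iterrows():
            if row["rank"] - run[-1]["rank"] - 1 <= max_rank_gap:
                run.append(row)
            else:
                if len(run) >= 2:
                    out.append({r["feature_id"] for r in run})
                run = [row]
        if len(run) >= 2:
            out.append({r["feature_id"] for r in run})
    return out


def conservation_rate(block: SyntenicBlock, genome: GenomeAnnotation) -> float:
    """Anchors divided by the number of genes spanned by region A."""
    lo, hi = block.rank_span_a
    n_genes = len(genome.genes_between_ranks(block.chrom_a, lo, hi))
    return block.n_anchors / n_genes if n_genes else float("nan")


def block_stats(blocks: list[SyntenicBlock], genome: GenomeAnnotation) -> pd.DataFrame:
    """Per-age-class summary: mean/SD region-A length (bp), mean gene count,
    mean conservation rate (anchors / genes in region A)."""
    if not blocks:
        return pd.DataFrame(columns=["age_class", "n_blocks", "mean_length_bp",
                                     "sd_length_bp", "mean_genes", "mean_conservation"])
    rows = []
    for b in blocks:
        region = b.region(genome, "a")
        lo, hi = b.rank_span_a
        rows.append({
            "age_class": b.age_class,
            "length_bp": region.length,
            "genes": len(genome.genes_between_ranks(b.chrom_a, lo, hi)),
            "conservation": conservation_rate(b, genome),
        })
    per_block = pd.DataFrame(rows)
    out = (per_block.groupby("age_class")
           .agg(n_blocks=("length_bp", "size"),
                mean_length_bp=("length_bp", "mean"),
                sd_length_bp=("length_bp", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
                mean_genes=("genes", "mean"),
                mean_conservation=("conservation", "mean"))
           .reset_index())
    return out


def blocks_to_frame(blocks: list[SyntenicBlock], genome: GenomeAnnotation | None = None) -> pd.DataFrame:
    """Flat per-block table (one record per block pair)."""
    rows = []
    for b in blocks:
        row = {
            "block_id": b.block_id, "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
            "orientation": b.orientation, "n_anchors": b.n_anchors,
            "rank_a_lo": b.rank_span_a[0], "rank_a_hi": b.rank_span_a[1],
            "rank_b_lo": b.rank_span_b[0], "rank_b_hi": b.rank_span_b[1],
            "ks_mode": b.ks_mode, "age_class": b.age_class,
            "merged_from": ",".join(b.merged_from),
        }
        if genome is not None:
            region = b.region(genome, "a")
            row.update(start_a=region.start, stop_a=region.stop, length_a=region.length)
        rows.append(row)
    return pd.DataFrame(rows)
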