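"""Readers and writers for the standard formats the pipeline consumes.

GFF3 is 1-based inclusive on disk and converted to 0-based half-open in
memory (and back on write). Bespoke tables travel as TSV with header rows.
Orthogroup tables follow the OrthoFinder ``Orthogroups.tsv`` dialect: one
row per orthogroup, one column per species, genes comma-separated within a
cell (an empty cell means zero genes for that species). Numeric columns in
curated fixture tables may carry thousands separators; they are parsed on
ingestion.
"""
from __future__ import annotations

import importlib.resources

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import ANCHOR_COLUMNS, FEATURE_COLUMNS, GenomeAnnotation


# --- genome annotation -------------------------------------------------------

def write_gff3(genome: GenomeAnnotation, path) -> None:
    """Write an annotation as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in genome.features.iterrows():
            attrs = [f"ID={row['feature_id']}"]
            if row["ftype"] == "gene":
                attrs.append(f"rank={int(row['rank'])}")
                attrs.append(f"lethal={'1' if row['lethal'] else '0'}")
                if row["orthogroup"]:
                    attrs.append(f"orthogroup={row['orthogroup']}")
            fh.write("\t".join([
                str(row["chrom"]), "syndel", str(row["ftype"]),
                str(int(row["start"]) + 1), str(int(row["stop"])),
                ".", str(row["strand"]), ".", ";".join(attrs),
            ]) + "\n")


def read_gff3(path) -> GenomeAnnotation:
    """Read a GFF3 annotation into a :class:`GenomeAnnotation` (coordinates
    converted to 0-based half-open)."""
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    rows = []
    for feat in db.all_features():
        if feat.end < feat.start:
            raise ValueError(f"feature {feat.id}: stop < start")
        rank = feat.attributes.get("rank", [None])[0]
        rows.append({
            "feature_id": feat.attributes.get("ID", [feat.id])[0],
            "chrom": feat.seqid,
            "start": feat.start - 1,
            "stop": feat.end,
            "strand": feat.strand or "+",
            "ftype": "gene" if feat.featuretype == "gene" else feat.featuretype,
            "rank": float(rank) if rank is not None else np.nan,
            "lethal": feat.attributes.get("lethal", ["0"])[0] == "1",
            "orthogroup": feat.attributes.get("orthogroup", [None])[0],
        })
    return GenomeAnnotation(pd.DataFrame(rows, columns=FEATURE_COLUMNS))


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (already 0-based half-open) into a feature frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "stop", "feature_id"][:df.shape[1]]
    if (df["stop"] < df["start"]).any():
        raise ValueError("BED record with stop < start")
    df["chrom"] = df["chrom"].astype(str)
    return df


# --- sequence ----------------------------------------------------------------

def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --- tabular -----------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_anchors(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})
    missing = set(ANCHOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"anchor table missing columns: {sorted(missing)}")
    return df


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene IDs in count matrix")
    return df


def read_sample_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError("sample metadata needs a 'sample' column")
    return df


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_a", "gene_b", "weight"}
    if not need <= set(df.columns):
        raise ValueError(f"edge list needs columns {sorted(need)}")
    return df


def read_modules(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")["module"]


def read_orthogroups(path) -> pd.Series:
    """OrthoFinder Orthogroups.tsv dialect -> Series gene -> orthogroup.

    Every species column is pooled; empty cells contribute no genes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    og_col = df.columns[0]
    mapping = {}
    for _, row in df.iterrows():
        for col in df.columns[1:]:
            cell = row[col]
            if pd.isna(cell) or not str(cell).strip():
                continue
            for gene in str(cell).split(","):
                gene = gene.strip()
                if gene:
                    mapping[gene] = row[og_col]
    return pd.Series(mapping, name="orthogroup")


def write_orthogroups(orthogroups: pd.Series, path, species: str = "focal") -> None:
    grouped = orthogroups.groupby(orthogroups).groups
    rows = [{"Orthogroup": og, species: ", ".join(sorted(members))}
            for og, members in sorted(grouped.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- curated coordinates -----------------------------------------------------

def load_deletion_blocks() -> pd.DataFrame:
    """Coordinates and content accounting of the four targeted syntenic
    block pairs in the TAIR10 assembly (deleted block and homeologous
    partner per pair), as curated for this pipeline.

    Numeric columns use thousands separators in the source table and are
    parsed to integers.
    """
    with importlib.resources.files("syndel.data").joinpath(
            "deletion_blocks.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", thousands=",", dtype={"chrom": str})
    return df
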