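"""Readers and writers for the tabular and sequence dialects used throughout.

Coordinate conventions: everything in memory is 0-based half-open.  GFF3 is
converted to/from 1-based closed on I/O.  All tables are plain TSV; commented
header lines start with '#'.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HITS_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
TAXONOMY_COLUMNS = ["sseqid", "superkingdom", "genus"]
DIFF_COLUMNS = ["strain", "chromosome", "category", "start", "end"]
DIFF_CATEGORIES = frozenset({"GAP", "DUP", "JMP", "INV", "BRK"})
BLOCK_COLUMNS = [
    "ref_chromosome", "ref_start", "ref_end",
    "query_chromosome", "query_start", "query_end", "pident",
]
BEDMETHYL_COLUMNS = ["chromosome", "position", "strand", "coverage", "methylated_count"]
BEDGRAPH_COLUMNS = ["chromosome", "start", "end", "value"]
COUNTS_COLUMNS = ["gene_id", "count", "length"]


@dataclass
class GeneModel:
    """A gene or intergenic ORF located on one strain assembly."""

    id: str
    chromosome: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "+"
    kind: str = "annotated_gene"  # or "intergenic_orf"
    intron_count: int = 0
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models

def write_gff3_genes(genes: Iterable[GeneModel], path: str | os.PathLike,
                     source: str = "gevescan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "gene" if g.kind == "annotated_gene" else "ORF"
            attrs = f"ID={g.id};intron_count={g.intron_count}"
            if g.frame is not None:
                attrs += f";frame={g.frame}"
            fh.write("\t".join([
                g.chromosome, source, ftype, str(g.start + 1), str(g.end),
                ".", g.strand, ".", attrs,
            ]) + "\n")


def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("gene", "ORF"):
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            genes.append(GeneModel(
                id=attr["ID"],
                chromosome=chrom,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                kind="annotated_gene" if ftype == "gene" else "intergenic_orf",
                intron_count=int(attr.get("intron_count", 0)),
                frame=int(attr["frame"]) if "frame" in attr else None,
            ))
    return genes


# ---------------------------------------------------------------------------
# Generic TSV helpers

def _read_tsv(path: str | os.PathLike, columns: list[str],
              dtypes: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=columns,
                     dtype=dtypes)
    return df


def _write_tsv(df: pd.DataFrame, path: str | os.PathLike, header_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Homology hits (outfmt-6 dialect) and taxonomy

def read_hits(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] != len(HITS_COLUMNS):
        raise ValueError(
            f"{path}: expected {len(HITS_COLUMNS)} columns (outfmt 6), got {df.shape[1]}")
    df.columns = HITS_COLUMNS
    return df


def write_hits(df: pd.DataFrame, path: str | os.PathLike) -> None:
    _write_tsv(df[HITS_COLUMNS], path, "\t".join(HITS_COLUMNS))


def read_taxonomy(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] != len(TAXONOMY_COLUMNS):
        raise ValueError(f"{path}: expected columns {TAXONOMY_COLUMNS}")
    df.columns = TAXONOMY_COLUMNS
    return df


def write_taxonomy(df: pd.DataFrame, path: str | os.PathLike) -> None:
    _write_tsv(df[TAXONOMY_COLUMNS], path, "\t".join(TAXONOMY_COLUMNS))


# ---------------------------------------------------------------------------
# Whole-genome alignment blocks and diff records

def read_diff(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_tsv(path, DIFF_COLUMNS)
    bad = set(df["category"]) - DIFF_CATEGORIES
    if bad:
        raise ValueError(f"{path}: unknown diff categories {sorted(bad)}")
    return df


def write_diff(df: pd.DataFrame, path: str | os.PathLike) -> None:
    _write_tsv(df[DIFF_COLUMNS], path,
               "strain chromosome category start end (0-based half-open)")


def read_blocks(path: str | os.PathLike) -> pd.DataFrame:
    return _read_tsv(path, BLOCK_COLUMNS)


def write_blocks(df: pd.DataFrame, path: str | os.PathLike) -> None:
    _write_tsv(df[BLOCK_COLUMNS], path,
               "ref/query chromosome start end pident (0-based half-open)")


# ---------------------------------------------------------------------------
# Methylation, coverage, counts

def read_bedmethyl(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_tsv(path, BEDMETHYL_COLUMNS)
    if ((df["methylated_count"] < 0) | (df["methylated_count"] > df["coverage"])).any():
        raise ValueError(f"{path}: methylated_count outside [0, coverage]")
    return df


def write_bedmethyl(df: pd.DataFrame, path: str | os.PathLike) -> None:
    _write_tsv(df[BEDMETHYL_COLUMNS], path,
               "chromosome position(0-based) strand coverage methylated_count")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    with open(path) as fh:
        rows = []
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed bedGraph at line {i}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed bedGraph at line {i}") from exc
    return pd.DataFrame(rows, columns=BEDGRAPH_COLUMNS)


def write_bedgraph(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[BEDGRAPH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    return _read_tsv(path, COUNTS_COLUMNS)


def write_counts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    _write_tsv(df[COUNTS_COLUMNS], path, "gene_id count effective_length_bp")


# ---------------------------------------------------------------------------
# BED intervals (regions, repeats, telomeres)

def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["chromosome", "start", "end"]
    if "name" in df.columns:
        cols.append("name")
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Hi-C triplets (one chromosome per file; bin size in the header comment)

def write_hic_triplets(matrix: np.ndarray, bin_size: int, chromosome: str,
                       path: str | os.PathLike) -> None:
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("contact matrix must be square")
    with open(path, "w") as fh:
        fh.write(f"# bin_size={bin_size} chromosome={chromosome} n_bins={matrix.shape[0]}\n")
        iu, ju = np.nonzero(np.triu(matrix))
        for i, j in zip(iu, ju):
            fh.write(f"{i}\t{j}\t{matrix[i, j]:g}\n")


def read_hic_triplets(path: str | os.PathLike) -> tuple[np.ndarray, int, str]:
    """Return (dense symmetric matrix, bin_size, chromosome)."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing Hi-C header comment")
        meta = dict(kv.split("=", 1) for kv in header[1:].split() if "=" in kv)
        bin_size = int(meta["bin_size"])
        chromosome = meta.get("chromosome", ".")
        n_bins = int(meta["n_bins"])
        mat = np.zeros((n_bins, n_bins))
        for line in fh:
            if not line.strip():
                continue
            i_s, j_s, c_s = line.split("\t")
            i, j, c = int(i_s), int(j_s), float(c_s)
            mat[i, j] = c
            mat[j, i] = c
    return mat, bin_size, chromosome
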