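"""Viral LGT candidate calling from ranked homology hits.

A gene (or intergenic ORF) is retained as a viral candidate when its best
surviving homology hit is viral, or when viral subjects make up half or more
of its top ten surviving hits.  Hits to the self genus are removed first so
recent transfers are not masked by the query's own species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, HITS_COLUMNS

logger = logging.getLogger(__name__)

_STOPS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class CallingThresholds:
    min_orf_nt: int = 150
    evalue_cutoff: float = 0.001
    vote_window: int = 10
    self_genus: str = "Amoebozoon"

    def __post_init__(self) -> None:
        if self.min_orf_nt <= 0 or self.evalue_cutoff <= 0 or self.vote_window <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ViralCandidate:
    gene_id: str
    call_basis: str                  # best_hit_viral | majority_vote
    best_viral_subject: str
    best_viral_taxon: str
    n_viral_in_top_ten: int
    conservation_status: str = "unassigned"


# ---------------------------------------------------------------------------
# intergenic ORF extraction

def intergenic_intervals(chrom_length: int, genes: list[GeneModel]) -> list[tuple[int, int]]:
    """Complement of gene spans over [0, chrom_length)."""
    spans = sorted((g.start, g.end) for g in genes)
    out, cursor = [], 0
    for s, e in spans:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < chrom_length:
        out.append((cursor, chrom_length))
    return out


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_frames(seq: str, min_nt: int) -> list[tuple[int, int, int]]:
    """Maximal stop-free codon runs of >= min_nt in the three forward frames.

    Returns (start, end, frame) in the coordinates of `seq`.  Codons with
    ambiguous characters count as stops.  Runs are open at sequence ends: a
    terminal run needs no bounding stop codon.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    out = []
    for frame in range(3):
        n_codons = (n - frame) // 3
        if n_codons * 3 < min_nt:
            continue
        cod = arr[frame:frame + n_codons * 3].reshape(n_codons, 3)
        v = valid[frame:frame + n_codons * 3].reshape(n_codons, 3).all(axis=1)
        is_t = cod[:, 0] == ord("T")
        second = cod[:, 1]
        third = cod[:, 2]
        stop = is_t & (
            ((second == ord("A")) & ((third == ord("A")) | (third == ord("G"))))
            | ((second == ord("G")) & (third == ord("A"))))
        blocked = stop | ~v
        # runs of unblocked codons
        bounds = np.flatnonzero(np.diff(np.concatenate([[1], blocked.view(np.int8), [1]])))
        for b0, b1 in zip(bounds[::2], bounds[1::2]):
            length = 3 * (b1 - b0)
            if length >= min_nt:
                out.append((frame + 3 * int(b0), frame + 3 * int(b1), frame))
    return out


def extract_intergenic_orfs(sequences: dict[str, str], genes: list[GeneModel],
                            thresholds: CallingThresholds | None = None) -> list[GeneModel]:
    """All maximal stop-to-stop ORFs >= min_orf_nt in intergenic space.

    Both strands, three frames each; no start codon required; forward-strand
    coordinates, 0-based half-open.
    """
    thresholds = thresholds or CallingThresholds()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    orfs: list[GeneModel] = []
    counter = 0
    for chrom, seq in sequences.items():
        n_ambiguous = sum(1 for c in seq if c not in "ACGT")
        if n_ambiguous > len(seq) // 2:
            logger.warning("%s: sequence not ACGT-dominant; ambiguous codons "
                           "treated as stops", chrom)
        for istart, iend in intergenic_intervals(len(seq), by_chrom.get(chrom, [])):
            if iend - istart < thresholds.min_orf_nt:
                continue
            sub = seq[istart:iend]
            for s, e, frame in _scan_frames(sub, thresholds.min_orf_nt):
                counter += 1
                orfs.append(GeneModel(
                    id=f"orf{counter:06d}", chromosome=chrom,
                    start=istart + s, end=istart + e, strand="+",
                    kind="intergenic_orf", frame=frame))
            rc = _revcomp(sub)
            L = len(sub)
            for s, e, frame in _scan_frames(rc, thresholds.min_orf_nt):
                counter += 1
                orfs.append(GeneModel(
                    id=f"orf{counter:06d}", chromosome=chrom,
                    start=istart + L - e, end=istart + L - s, strand="-",
                    kind="intergenic_orf", frame=frame))
    orfs.sort(key=lambda g: (g.chromosome, g.start, g.end, g.strand))
    return orfs


# ---------------------------------------------------------------------------
# hit ranking and the taxonomic vote

def attach_taxonomy(hits: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Left-join subject taxonomy onto hits; missing subjects get NaN."""
    return hits.merge(taxonomy, on="sseqid", how="left")


def rank_hits(hits: pd.DataFrame, thresholds: CallingThresholds,
              untaxed: set[str] | None = None) -> pd.DataFrame:
    """Filter and order one query's hits.

    Drops hits above the e-value cutoff, hits to the self genus and hits
    whose subject has no taxonomy (recorded in `untaxed`); keeps the best
    hit per subject; orders by bitscore desc, e-value asc, subject id.
    """
    if hits.empty:
        return hits
    if hits["qseqid"].nunique() > 1:
        raise ValueError("rank_hits expects hits for a single query")
    df = hits[hits["evalue"] <= thresholds.evalue_cutoff]
    missing = df["superkingdom"].isna()
    if missing.any() and untaxed is not None:
        untaxed.update(df.loc[missing, "sseqid"])
    df = df[~missing]
    df = df[df["genus"] != thresholds.self_genus]
    df = df.sort_values(["bitscore", "evalue", "sseqid"],
                        ascending=[False, True, True], kind="mergesort")
    df = df.drop_duplicates(subset="sseqid", keep="first")
    return df.reset_index(drop=True)


def classify_viral_candidate(ranked: pd.DataFrame,
                             thresholds: CallingThresholds) -> ViralCandidate | None:
    """Apply the best-hit / majority-vote retention rule to a ranked hit list."""
    if ranked.empty:
        return None
    top = ranked.head(thresholds.vote_window)
    is_viral = (top["superkingdom"] == "Viruses").to_numpy()
    n_viral = int(is_viral.sum())
    best_viral_rows = top[is_viral]
    best_subject = best_viral_rows.iloc[0]["sseqid"] if n_viral else ""
    best_taxon = best_viral_rows.iloc[0]["genus"] if n_viral else ""
    qid = ranked.iloc[0]["qseqid"]
    if is_viral[0]:
        return ViralCandidate(qid, "best_hit_viral", best_subject, best_taxon, n_viral)
    if n_viral >= math.ceil(len(top) / 2):
        return ViralCandidate(qid, "majority_vote", best_subject, best_taxon, n_viral)
    return None


def call_all_candidates(genes: list[GeneModel], hits: pd.DataFrame,
                        taxonomy: pd.DataFrame,
                        thresholds: CallingThresholds | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Classify every gene/ORF; return a candidate table and summary counts.

    The candidate table has one row per retained query with columns
    gene_id, chromosome, start, end, call_basis, best_viral_taxon,
    n_viral_in_top_ten.
    """
    thresholds = thresholds or CallingThresholds()
    ids = [g.id for g in genes]
    dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
    if dupes:
        raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
    gene_by_id = {g.id: g for g in genes}
    merged = attach_taxonomy(hits, taxonomy)
    untaxed: set[str] = set()
    rows = []
    for qid, group in merged.groupby("qseqid", sort=True):
        if qid not in gene_by_id:
            continue
        ranked = rank_hits(group, thresholds, untaxed)
        cand = classify_viral_candidate(ranked, thresholds)
        if cand is None:
            continue
        g = gene_by_id[qid]
        rows.append((cand.gene_id, g.chromosome, g.start, g.end, cand.call_basis,
                     cand.best_viral_taxon, cand.n_viral_in_top_ten))
    table = pd.DataFrame(rows, columns=[
        "gene_id", "chromosome", "start", "end", "call_basis",
        "best_viral_taxon", "n_viral_in_top_ten"])
    summary = {
        "n_queries": len(genes),
        "n_candidates": len(table),
        "by_basis": table["call_basis"].value_counts().to_dict(),
        "best_taxon_distribution": table["best_viral_taxon"].value_counts().to_dict(),
        "n_untaxed_subjects": len(untaxed),
    }
    if untaxed:
        logger.warning("%d subjects had no taxonomy and were excluded", len(untaxed))
    return table, summary
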