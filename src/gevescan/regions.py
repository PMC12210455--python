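"""Cross-strain conservation calls, divergent-region construction and
viral-region flagging.

A gene is conserved if it overlaps any confidently aligned block by at least
one base, non-conserved if its span lies entirely within the union of
alignment gaps, and unresolved otherwise.  Divergent regions are maximal
concatenations of contiguous GAP/DUP/JMP diff records; INV and BRK records
terminate concatenation.  A divergent region is a viral region when at least
one full viral candidate gene lies within it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MERGEABLE = ("GAP", "DUP", "JMP")
BREAKERS = ("INV", "BRK")
HALLMARKS = ("MCP", "A32_ATPase", "polB", "VLTF3", "SFII")


@dataclass
class DivergentRegion:
    region_id: str
    chromosome: str
    start: int
    end: int
    record_ids: list[int] = field(default_factory=list)
    is_viral: bool = False
    n_full_viral_genes: int = 0
    curation_note: str = ""


# ---------------------------------------------------------------------------
# interval utilities

def merge_intervals(intervals: list[tuple[int, int]], slack: int = 0
                    ) -> list[tuple[int, int]]:
    """Union of intervals, joining any that overlap, abut or lie within slack."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + slack:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _covered_by_union(start: int, end: int, union: list[tuple[int, int]]) -> bool:
    for s, e in union:
        if s <= start and end <= e:
            return True
        if s > start:
            break
    return False


# ---------------------------------------------------------------------------
# conservation classification

def classify_conservation(gene_span: tuple[str, int, int], blocks: pd.DataFrame,
                          diff: pd.DataFrame, strain_side: str = "ref") -> str:
    """Status of one gene span against alignment blocks and GAP records.

    `strain_side` selects which side of the blocks table carries this
    strain's coordinates ("ref" or "query").
    """
    chrom, start, end = gene_span
    cpfx = f"{strain_side}_"
    b = blocks[blocks[cpfx + "chromosome"] == chrom]
    gaps = diff[(diff["chromosome"] == chrom) & (diff["category"] == "GAP")]
    if b.empty and gaps.empty:
        logger.warning("chromosome %s absent from alignment; gene unresolved", chrom)
        return "unresolved"
    overlap = ((b[cpfx + "start"] < end) & (b[cpfx + "end"] > start)).any()
    if overlap:
        return "conserved"
    union = merge_intervals(list(zip(gaps["start"], gaps["end"])))
    if _covered_by_union(start, end, union):
        return "non_conserved"
    return "unresolved"


def classify_all(candidates: pd.DataFrame, blocks: pd.DataFrame, diff: pd.DataFrame,
                 strain: str, strain_side: str = "ref") -> pd.DataFrame:
    """Vectorized conservation status for every candidate row (one strain)."""
    d = diff[diff["strain"] == strain]
    out = candidates.copy()
    statuses = []
    # pre-index per chromosome
    by_chrom_blocks = {c: g for c, g in blocks.groupby(f"{strain_side}_chromosome")}
    by_chrom_gaps = {
        c: merge_intervals(list(zip(g["start"], g["end"])))
        for c, g in d[d["category"] == "GAP"].groupby("chromosome")}
    for _, row in candidates.iterrows():
        chrom, start, end = row["chromosome"], row["start"], row["end"]
        b = by_chrom_blocks.get(chrom)
        union = by_chrom_gaps.get(chrom, [])
        if b is None and not union:
            statuses.append("unresolved")
            continue
        if b is not None and ((b[f"{strain_side}_start"] < end)
                              & (b[f"{strain_side}_end"] > start)).any():
            statuses.append("conserved")
        elif _covered_by_union(start, end, union):
            statuses.append("non_conserved")
        else:
            statuses.append("unresolved")
    out["conservation_status"] = statuses
    return out


def summarize_conservation(candidates: pd.DataFrame) -> dict:
    """Per-strain totals, conserved counts and rounded percentages.

    Expects a candidate table with a `conservation_status` column and,
    optionally, a `strain` column; without one the table is treated as a
    single strain named "all".
    """
    if "strain" not in candidates.columns:
        candidates = candidates.assign(strain="all")
    out: dict[str, dict] = {}
    for strain, grp in candidates.groupby("strain"):
        total = len(grp)
        conserved = int((grp["conservation_status"] == "conserved").sum())
        non_conserved = int((grp["conservation_status"] == "non_conserved").sum())
        unresolved = int((grp["conservation_status"] == "unresolved").sum())
        pct = None if total == 0 else int(round(100.0 * conserved / total))
        out[str(strain)] = {
            "total": total, "conserved": conserved, "non_conserved": non_conserved,
            "unresolved": unresolved, "percent_conserved": pct,
        }
        assert conserved + non_conserved + unresolved == total
    return out


# ---------------------------------------------------------------------------
# divergent-region construction

def build_divergent_regions(diff: pd.DataFrame, merge_slack: int = 0
                            ) -> list[DivergentRegion]:
    """Concatenate contiguous GAP/DUP/JMP records into maximal regions.

    Records merge when they overlap, abut, or lie within `merge_slack` bp of
    the growing region; an INV/BRK record intersecting the space between two
    otherwise-mergeable records blocks the join.  Idempotent on its output.
    """
    if merge_slack < 0:
        raise ValueError("merge_slack must be >= 0")
    regions: list[DivergentRegion] = []
    counter = 0
    group_keys = ["chromosome"]
    if "strain" in diff.columns:
        group_keys = ["strain", "chromosome"]
    for key, grp in diff.groupby(group_keys, sort=True):
        chrom = key[-1] if isinstance(key, tuple) else key
        grp = grp.sort_values(["start", "end"]).reset_index()
        breakers = [(r.start, r.end) for r in grp.itertuples()
                    if r.category in BREAKERS]
        cur: DivergentRegion | None = None
        for r in grp.itertuples():
            if r.category not in MERGEABLE:
                continue
            blocked = cur is not None and r.start > cur.end and any(
                bs < r.start and be > cur.end for bs, be in breakers)
            if cur is not None and r.start <= cur.end + merge_slack and not blocked:
                cur.end = max(cur.end, r.end)
                cur.record_ids.append(int(r.index))
            else:
                counter += 1
                cur = DivergentRegion(
                    region_id=f"region{counter:04d}", chromosome=str(chrom),
                    start=int(r.start), end=int(r.end), record_ids=[int(r.index)])
                if isinstance(key, tuple):
                    cur.curation_note = f"strain={key[0]}"
                regions.append(cur)
    return regions


def flag_viral_regions(regions: list[DivergentRegion],
                       candidates: pd.DataFrame) -> list[DivergentRegion]:
    """Set is_viral on each region containing >= 1 fully-contained candidate.

    Genes straddling a region boundary do not count.
    """
    by_chrom = {c: g for c, g in candidates.groupby("chromosome")}
    for region in regions:
        g = by_chrom.get(region.chromosome)
        if g is None:
            region.is_viral, region.n_full_viral_genes = False, 0
            continue
        full = (g["start"] >= region.start) & (g["end"] <= region.end)
        region.n_full_viral_genes = int(full.sum())
        region.is_viral = region.n_full_viral_genes >= 1
    return regions


def regions_to_frame(regions: list[DivergentRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "region_id": r.region_id, "chromosome": r.chromosome, "start": r.start,
        "end": r.end, "is_viral": r.is_viral,
        "n_full_viral_genes": r.n_full_viral_genes,
        "n_records": len(r.record_ids), "curation_note": r.curation_note,
    } for r in regions])


# ---------------------------------------------------------------------------
# hallmark completeness

def hallmark_completeness(regions: list[DivergentRegion], hallmark_hits: pd.DataFrame,
                          evalue_cutoff: float = 1e-5) -> pd.DataFrame:
    """Presence/absence of the five hallmark genes per viral region.

    `hallmark_hits` columns: chromosome, start, end, hallmark, evalue.  Hits
    at or above the cutoff are discarded (the retention rule is strictly
    "below"); hits outside viral regions are discarded; unknown hallmark
    labels are tallied under "other" and excluded from the full-suite test.
    """
    viral = [r for r in regions if r.is_viral]
    rows = []
    for r in viral:
        sel = hallmark_hits[
            (hallmark_hits["chromosome"] == r.chromosome)
            & (hallmark_hits["start"] >= r.start)
            & (hallmark_hits["end"] <= r.end)
            & (hallmark_hits["evalue"] < evalue_cutoff)]
        present = {h: bool((sel["hallmark"] == h).any()) for h in HALLMARKS}
        other = int((~sel["hallmark"].isin(HALLMARKS)).sum())
        rows.append({"region_id": r.region_id, **present,
                     "other": other, "full_suite": all(present.values())})
    return pd.DataFrame(rows, columns=["region_id", *HALLMARKS, "other", "full_suite"])
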