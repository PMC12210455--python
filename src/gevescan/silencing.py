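"""Epigenetic-silencing profiles: per-CpG methylation, gene-level
classification, windowed methylation/coverage tracks, TPM and category-wise
Welch comparisons.

The methylation level of a site is the fraction of methylated reads covering
it; a gene is methylated when the unweighted mean of its per-site levels is
at least the classification threshold (default 5%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

METHYLATION_THRESHOLD = 0.05


@dataclass
class GeneMethylation:
    gene_id: str
    n_sites: int
    mean_level: float | None
    is_methylated: bool | None


@dataclass
class CategoryComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    df: float
    p_value: float
    flagged: bool = False


# ---------------------------------------------------------------------------
# methylation

def combine_cpg_strands(sites: pd.DataFrame) -> pd.DataFrame:
    """Merge the two strands of each symmetric CpG by summing read counts.

    A minus-strand call at position p reports the G of the CpG whose C sits
    at p-1; it is folded onto that C position.
    """
    df = sites.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "position"] = df.loc[minus, "position"] - 1
    agg = (df.groupby(["chromosome", "position"], as_index=False)
             .agg(coverage=("coverage", "sum"),
                  methylated_count=("methylated_count", "sum")))
    agg["strand"] = "."
    return agg[["chromosome", "position", "strand", "coverage", "methylated_count"]]


def site_levels(sites: pd.DataFrame) -> pd.DataFrame:
    df = sites.copy()
    df["level"] = df["methylated_count"] / df["coverage"]
    return df


def gene_methylation(sites: pd.DataFrame, gene_id: str, chromosome: str,
                     start: int, end: int, min_coverage: int = 5,
                     threshold: float = METHYLATION_THRESHOLD) -> GeneMethylation:
    """Unweighted mean of per-site levels within one gene span."""
    sel = sites[(sites["chromosome"] == chromosome)
                & (sites["position"] >= start) & (sites["position"] < end)
                & (sites["coverage"] >= min_coverage)]
    if sel.empty:
        return GeneMethylation(gene_id, 0, None, None)
    levels = sel["methylated_count"].to_numpy() / sel["coverage"].to_numpy()
    mean = float(levels.mean())
    return GeneMethylation(gene_id, len(sel), mean, mean >= threshold)


def gene_methylation_table(sites: pd.DataFrame, genes: pd.DataFrame,
                           min_coverage: int = 5,
                           threshold: float = METHYLATION_THRESHOLD) -> pd.DataFrame:
    """Gene-level methylation for a whole gene table (gene_id chromosome start end).

    Genes without usable sites get NaN mean and a null classification; their
    count is logged.
    """
    usable = sites[sites["coverage"] >= min_coverage]
    rows = []
    for chrom, grp in genes.groupby("chromosome"):
        s = usable[usable["chromosome"] == chrom].sort_values("position")
        pos = s["position"].to_numpy()
        lev = s["methylated_count"].to_numpy() / s["coverage"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(lev)])
        for r in grp.itertuples():
            i0 = np.searchsorted(pos, r.start, side="left")
            i1 = np.searchsorted(pos, r.end, side="left")
            n = int(i1 - i0)
            if n == 0:
                rows.append((r.gene_id, 0, np.nan, None))
            else:
                mean = (csum[i1] - csum[i0]) / n
                rows.append((r.gene_id, n, mean, bool(mean >= threshold)))
    out = pd.DataFrame(rows, columns=["gene_id", "n_sites", "mean_level", "is_methylated"])
    n_excluded = int(out["is_methylated"].isna().sum())
    if n_excluded:
        logger.info("%d genes had no usable CpG sites and were excluded", n_excluded)
    return out


def methylation_track(sites: pd.DataFrame, chromosome_lengths: dict[str, int],
                      window_bp: int = 5000, step_bp: int = 1000) -> pd.DataFrame:
    """Sliding-window mean methylation level, windows anchored at step multiples.

    Windows with no sites carry NaN.
    """
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")
    if window_bp <= 0 or step_bp > window_bp:
        raise ValueError("need 0 < step_bp <= window_bp")
    rows = []
    for chrom, L in chromosome_lengths.items():
        s = sites[sites["chromosome"] == chrom].sort_values("position")
        pos = s["position"].to_numpy()
        lev = (s["methylated_count"].to_numpy() / s["coverage"].to_numpy()
               if len(s) else np.empty(0))
        csum = np.concatenate([[0.0], np.cumsum(lev)])
        for wstart in range(0, max(1, L), step_bp):
            wend = min(wstart + window_bp, L)
            i0 = np.searchsorted(pos, wstart, side="left")
            i1 = np.searchsorted(pos, wend, side="left")
            n = i1 - i0
            value = (csum[i1] - csum[i0]) / n if n else np.nan
            rows.append((chrom, wstart, wend, value))
            if wend >= L:
                break
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "value"])


# ---------------------------------------------------------------------------
# expression

def compute_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """TPM from read counts and effective lengths.

    rate_g = count_g / (length_g / 1000); TPM_g = 1e6 * rate_g / sum(rates).
    With all counts zero, TPM is zero everywhere (no division).
    """
    df = counts.copy()
    if (df["length"] <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = df["count"] / (df["length"] / 1000.0)
    total = rate.sum()
    df["tpm"] = 0.0 if total == 0 else 1e6 * rate / total
    df["log2_tpm1"] = np.log2(df["tpm"] + 1.0)
    return df


def coverage_track(bedgraph: pd.DataFrame, chromosome_lengths: dict[str, int],
                   window_bp: int = 2500) -> pd.DataFrame:
    """log2(mean per-base coverage in window + 1) over tiling windows."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if (bedgraph["value"] < 0).any():
        raise ValueError("coverage must be non-negative")
    rows = []
    for chrom, L in chromosome_lengths.items():
        per_base = np.zeros(L)
        for r in bedgraph[bedgraph["chromosome"] == chrom].itertuples():
            per_base[max(0, r.start):min(L, r.end)] = r.value
        for wstart in range(0, max(1, L), window_bp):
            wend = min(wstart + window_bp, L)
            mean = per_base[wstart:wend].mean() if wend > wstart else 0.0
            rows.append((chrom, wstart, wend, float(np.log2(mean + 1.0))))
            if wend >= L:
                break
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "value"])


# ---------------------------------------------------------------------------
# statistics

def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, bool]:
    """Welch t statistic, Welch-Satterthwaite df, two-sided p, degenerate flag."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    flagged = False
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0, False
        return math.inf, 1.0, 0.0, True
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    if (va == 0 and len(a) == 2) or (vb == 0 and len(b) == 2):
        flagged = True
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), flagged


def compare_categories(groups: dict[str, np.ndarray]) -> list[CategoryComparison]:
    """Pairwise Welch comparisons across labeled groups of values."""
    labels = sorted(groups)
    out = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            a, b = np.asarray(groups[la], float), np.asarray(groups[lb], float)
            t, df, p, flagged = welch_ttest(a, b)
            out.append(CategoryComparison(
                la, lb, len(a), len(b), float(a.mean()), float(b.mean()),
                t, df, p, flagged))
    return out


def comparisons_to_frame(comps: list[CategoryComparison],
                         adjust: bool = False) -> pd.DataFrame:
    df = pd.DataFrame([vars(c) for c in comps])
    if adjust and len(df):
        # Benjamini-Hochberg
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_rev, idx in enumerate(order[::-1]):
            k = m - rank_rev
            running = min(running, p[idx] * m / k)
            adj[idx] = running
        df["p_adjusted"] = adj
    return df


def methylated_fraction_by_category(gene_meth: pd.DataFrame,
                                    labels: pd.DataFrame) -> pd.DataFrame:
    """Percent methylated genes per category label.

    `labels` columns: gene_id, category.  Genes without a usable
    classification are reported in the excluded column; empty categories are
    omitted with a warning.
    """
    df = labels.merge(gene_meth, on="gene_id", how="left")
    rows = []
    for cat, grp in df.groupby("category"):
        classified = grp[grp["is_methylated"].notna()]
        excluded = len(grp) - len(classified)
        if classified.empty:
            logger.warning("category %s has no classified genes; row omitted", cat)
            continue
        n_meth = int(classified["is_methylated"].astype(bool).sum())
        rows.append((cat, len(classified), n_meth,
                     100.0 * n_meth / len(classified), excluded))
    return pd.DataFrame(rows, columns=[
        "category", "n_classified", "n_methylated", "percent_methylated", "n_excluded"])
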