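"""Genomic context of viral regions: telomeric repeat arrays, chromosome-end
bias, mobile-element composition, GC shifts, region-to-region similarity
links and Hi-C compaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_TELOMERE = "TTAGGG"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class TelomereArray:
    chromosome: str
    start: int
    end: int
    unit: str          # the orientation matched (unit or its reverse complement)
    unit_count: int
    purity: float      # fraction of units matching exactly
    degenerate: bool


@dataclass
class RegionLink:
    region_a: str
    region_b: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    span: int
    percent_identity: float
    anchor_count: int


# ---------------------------------------------------------------------------
# telomeric repeat arrays

def _unit_mismatch_runs(seq: np.ndarray, unit: np.ndarray, max_mm: int,
                        min_units: int) -> list[tuple[int, int, float]]:
    """Maximal runs of consecutive unit-length windows each within max_mm."""
    u = len(unit)
    n = len(seq)
    if n < u:
        return []
    # mismatches of every window vs the unit
    mm = np.zeros(n - u + 1, dtype=np.int32)
    for k in range(u):
        mm += seq[k:n - u + 1 + k] != unit[k]
    ok = mm <= max_mm
    exact = mm == 0
    runs = []
    # a chain steps by u, so work per start-phase residue class
    for phase in range(u):
        okp = ok[phase::u]
        if not okp.any():
            continue
        exp = exact[phase::u]
        csum = np.concatenate([[0], np.cumsum(exp)])
        edges = np.flatnonzero(np.diff(np.concatenate(
            [[0], okp.view(np.int8), [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            count = int(b - a)
            if count >= min_units:
                purity = float(csum[b] - csum[a]) / count
                runs.append((int(phase + a * u), int(phase + b * u), purity))
    return runs


def detect_telomeric_arrays(sequence: str, chromosome: str = ".",
                            unit: str = CANONICAL_TELOMERE,
                            max_mismatch_per_unit: int = 1,
                            min_units: int = 3) -> list[TelomereArray]:
    """Tandem arrays of the telomeric unit (either orientation), allowing
    up to max_mismatch_per_unit differences per copy."""
    if len(unit) < 3:
        raise ValueError("telomeric unit must be at least 3 nt")
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    arrays: list[TelomereArray] = []
    rc = unit.translate(_COMPLEMENT)[::-1]
    for oriented in (unit, rc):
        u = np.frombuffer(oriented.encode(), dtype=np.uint8)
        for start, end, purity in _unit_mismatch_runs(
                seq, u, max_mismatch_per_unit, min_units):
            arrays.append(TelomereArray(
                chromosome=chromosome, start=start, end=end, unit=oriented,
                unit_count=(end - start) // len(unit), purity=purity,
                degenerate=purity < 1.0))
    # drop arrays contained in a longer array of the same orientation
    arrays.sort(key=lambda a: (a.unit, a.start, -(a.end - a.start)))
    kept: list[TelomereArray] = []
    for a in arrays:
        if any(k.unit == a.unit and k.start <= a.start and a.end <= k.end
               for k in kept):
            continue
        kept.append(a)
    kept.sort(key=lambda a: (a.start, a.end))
    return kept


# ---------------------------------------------------------------------------
# chromosome-end bias

def end_distances(features: pd.DataFrame,
                  chromosome_lengths: dict[str, int]) -> pd.DataFrame:
    """min(start, length-end) and its length-normalized form per feature."""
    rows = []
    for r in features.itertuples():
        L = chromosome_lengths[r.chromosome]
        if r.end - r.start > L:
            raise ValueError(f"feature longer than chromosome {r.chromosome}")
        d = min(r.start, L - r.end)
        rows.append((getattr(r, "name", None) or f"f{r.Index}", r.chromosome,
                     L, int(d), d / L))
    return pd.DataFrame(rows, columns=[
        "feature_id", "chromosome", "chromosome_length", "distance", "normalized"])


def end_distance_enrichment(features: pd.DataFrame,
                            chromosome_lengths: dict[str, int],
                            n_permutations: int = 1000,
                            seed: int | np.random.Generator = 0) -> dict:
    """Permutation test for sub-telomeric bias of feature placement.

    Null: each feature placed uniformly at random on its own chromosome.
    p = (1 + #{null mean <= observed mean}) / (n_permutations + 1).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    obs = end_distances(features, chromosome_lengths)
    observed_mean = float(obs["normalized"].mean())
    lengths = obs["chromosome_length"].to_numpy(float)
    spans = (features["end"] - features["start"]).to_numpy(float)
    # vectorized null: uniform starts in [0, L - span]
    u = rng.random((n_permutations, len(obs)))
    starts = u * (lengths - spans)
    dist = np.minimum(starts, lengths - (starts + spans)) / lengths
    null_means = dist.mean(axis=1)
    p = (1 + int((null_means <= observed_mean).sum())) / (n_permutations + 1)
    return {"observed_mean_normalized": observed_mean,
            "null_mean": float(null_means.mean()),
            "n_features": len(obs), "n_permutations": n_permutations,
            "p_value": float(p)}


# ---------------------------------------------------------------------------
# mobile-element composition

def mobile_element_context_chisq(table: pd.DataFrame, min_expected: float = 5.0,
                                 monte_carlo_reps: int = 2000,
                                 seed: int | np.random.Generator = 0) -> dict:
    """Pearson chi-square on a mobile-element class x genomic context table.

    Zero-margin rows/columns are dropped with a warning.  When any expected
    count falls below min_expected, a fixed-margins Monte Carlo p-value is
    computed in addition to the asymptotic one.
    """
    t = table.to_numpy(dtype=float)
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning("dropping %d zero rows and %d zero columns",
                       int((~row_ok).sum()), int((~col_ok).sum()))
        t = t[row_ok][:, col_ok]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zero margins")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    statistic = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    out = {"statistic": statistic, "df": df, "p_value": p,
           "min_expected": float(expected.min()), "monte_carlo_p": None}
    if expected.min() < min_expected:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        row_labels = np.repeat(np.arange(t.shape[0]), t.sum(axis=1).astype(int))
        col_labels = np.repeat(np.arange(t.shape[1]), t.sum(axis=0).astype(int))
        hits = 0
        for _ in range(monte_carlo_reps):
            perm = rng.permutation(col_labels)
            sim = np.zeros_like(t)
            np.add.at(sim, (row_labels, perm), 1.0)
            s = ((sim - expected) ** 2 / expected).sum()
            if s >= statistic - 1e-12:
                hits += 1
        out["monte_carlo_p"] = (hits + 1) / (monte_carlo_reps + 1)
    return out


# ---------------------------------------------------------------------------
# GC shifts

def gc_shift_track(sequence: str, chromosome: str = ".", window_bp: int = 1000,
                   shift_threshold: float = 0.10) -> tuple[pd.DataFrame, list[int]]:
    """Per-window GC fraction plus boundaries where adjacent windows jump.

    Returns (windows frame, list of flagged boundary coordinates).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    rows, values = [], []
    for wstart in range(0, len(arr), window_bp):
        wend = min(wstart + window_bp, len(arr))
        gc = float(is_gc[wstart:wend].mean())
        rows.append((chromosome, wstart, wend, gc))
        values.append(gc)
    boundaries = [i * window_bp for i in range(1, len(values))
                  if abs(values[i] - values[i - 1]) > shift_threshold]
    return (pd.DataFrame(rows, columns=["chromosome", "start", "end", "value"]),
            boundaries)


# ---------------------------------------------------------------------------
# region-to-region similarity links

def _mask_low_complexity(seq: str, min_run: int = 8) -> str:
    """Mask homopolymer and dinucleotide runs of >= min_run bp with N."""
    arr = list(seq)
    n = len(seq)
    i = 0
    while i < n - 1:
        # homopolymer
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            for k in range(i, j):
                arr[k] = "N"
            i = j
            continue
        # dinucleotide repeat
        j = i + 2
        while j + 1 < n and seq[j] == seq[j - 2] and seq[j + 1] == seq[j - 1]:
            j += 2
        if j - i >= min_run and seq[i] != seq[i + 1]:
            for k in range(i, j):
                arr[k] = "N"
            i = j
            continue
        i += 1
    return "".join(arr)


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        counts[kmer] = counts.get(kmer, 0) + 1
        pos[kmer] = i
    return {kmer: p for kmer, p in pos.items() if counts[kmer] == 1}


def region_similarity_links(region_sequences: dict[str, str], k: int = 15,
                            min_link_bp: int = 500, min_identity: float = 80.0,
                            max_anchor_gap: int = 500) -> list[RegionLink]:
    """Pairwise similarity links between regions via unique k-mer anchors.

    Shared unique k-mers are chained collinearly along a common diagonal;
    chains spanning >= min_link_bp are scored by direct base comparison of
    the anchored span and reported when identity >= min_identity.
    """
    names = sorted(region_sequences)
    masked = {}
    for name in names:
        if len(region_sequences[name]) < k:
            logger.warning("region %s shorter than k=%d; skipped", name, k)
            continue
        masked[name] = _mask_low_complexity(region_sequences[name].upper())
    kmers = {name: _unique_kmers(seq, k) for name, seq in masked.items()}
    links: list[RegionLink] = []
    kept = [n for n in names if n in masked]
    for ai in range(len(kept)):
        for bi in range(ai + 1, len(kept)):
            na, nb = kept[ai], kept[bi]
            shared = set(kmers[na]) & set(kmers[nb])
            if not shared:
                continue
            anchors = sorted((kmers[na][m], kmers[nb][m]) for m in shared)
            link = _chain_and_score(masked[na], masked[nb], anchors, k,
                                    min_link_bp, min_identity, max_anchor_gap)
            if link is not None:
                links.append(RegionLink(na, nb, *link))
    return links


def _chain_and_score(seq_a: str, seq_b: str, anchors: list[tuple[int, int]],
                     k: int, min_link_bp: int, min_identity: float,
                     max_gap: int) -> tuple | None:
    """Greedy chaining of collinear anchors on a near-constant diagonal."""
    best = None
    chain: list[tuple[int, int]] = []
    def flush(chain):
        nonlocal best
        if not chain:
            return
        a0, b0 = chain[0]
        a1, b1 = chain[-1]
        span = a1 + k - a0
        if span < min_link_bp:
            return
        sa = seq_a[a0:a1 + k]
        sb = seq_b[b0:b0 + len(sa)]
        L = min(len(sa), len(sb))
        if L == 0:
            return
        matches = sum(1 for x, y in zip(sa[:L], sb[:L]) if x == y and x != "N")
        identity = 100.0 * matches / L
        if identity < min_identity:
            return
        cand = (a0, a1 + k, b0, b0 + L, L, round(identity, 2), len(chain))
        if best is None or cand[4] > best[4]:
            best = cand
    for a, b in anchors:
        if chain:
            pa, pb = chain[-1]
            same_diag = abs((a - b) - (pa - pb)) <= 2
            close = 0 < a - pa <= max_gap and 0 < b - pb <= max_gap
            if same_diag and close:
                chain.append((a, b))
                continue
            flush(chain)
        chain = [(a, b)]
    flush(chain)
    return best


# ---------------------------------------------------------------------------
# Hi-C detrending and compaction

def detrend_contact_matrix(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Observed/expected detrending; expected(s) = mean count at separation s.

    Entries on diagonals with zero expected stay 0.  Per-diagonal mean of the
    output is 1 wherever expected is nonzero.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact matrix must be square")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("contact matrix not symmetric within tolerance")
    n = m.shape[0]
    oe = np.zeros_like(m)
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    for s in range(n):
        diag_vals = m[idx == s]
        expected = diag_vals.mean()
        if expected > 0:
            oe[idx == s] = m[idx == s] / expected
    return oe


def region_compaction_score(oe: np.ndarray, region_start: int, region_end: int,
                            bin_size: int) -> float | None:
    """log2 mean of intra-region off-diagonal O/E entries.

    Bins fully inside [region_start, region_end) are used; regions spanning
    fewer than two bins are undefined (None).
    """
    b0 = -(-region_start // bin_size)
    b1 = region_end // bin_size
    b0, b1 = max(0, b0), min(oe.shape[0], b1)
    if b1 - b0 < 2:
        return None
    sub = oe[b0:b1, b0:b1]
    off = ~np.eye(b1 - b0, dtype=bool)
    vals = sub[off]
    mean = vals.mean()
    if mean <= 0:
        return None
    return float(np.log2(mean))


def compaction_permutation_test(oe_by_chrom: dict[str, np.ndarray],
                                regions: pd.DataFrame, bin_size: int,
                                n_permutations: int = 1000,
                                seed: int | np.random.Generator = 0) -> dict:
    """Are the given regions more self-contacting than random matched regions?

    Null regions preserve each region's chromosome and length; the statistic
    is the mean compaction score over regions with a defined score.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    obs_scores = []
    specs = []
    for r in regions.itertuples():
        oe = oe_by_chrom.get(r.chromosome)
        if oe is None:
            continue
        s = region_compaction_score(oe, r.start, r.end, bin_size)
        if s is not None:
            obs_scores.append(s)
            specs.append((r.chromosome, r.end - r.start))
    if not obs_scores:
        return {"observed_mean": None, "p_value": None, "n_regions": 0}
    observed = float(np.mean(obs_scores))
    null_means = []
    for _ in range(n_permutations):
        vals = []
        for chrom, span in specs:
            oe = oe_by_chrom[chrom]
            max_start = oe.shape[0] * bin_size - span
            if max_start <= 0:
                continue
            start = int(rng.integers(0, max_start))
            s = region_compaction_score(oe, start, start + span, bin_size)
            if s is not None:
                vals.append(s)
        if vals:
            null_means.append(np.mean(vals))
    null_means = np.asarray(null_means)
    p = (1 + int((null_means >= observed).sum())) / (len(null_means) + 1)
    return {"observed_mean": observed, "null_mean": float(null_means.mean()),
            "p_value": float(p), "n_regions": len(obs_scores)}
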