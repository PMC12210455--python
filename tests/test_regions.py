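import numpy as np
import pandas as pd
import pytest

from gevescan.regions import (DivergentRegion, build_divergent_regions,
                              classify_all, classify_conservation,
                              flag_viral_regions, hallmark_completeness,
                              merge_intervals, regions_to_frame,
                              summarize_conservation)


BLOCK_COLS = ["ref_chromosome", "ref_start", "ref_end",
              "query_chromosome", "query_start", "query_end", "pident"]


def _blocks(intervals, chrom="c"):
    return pd.DataFrame([{
        "ref_chromosome": chrom, "ref_start": s, "ref_end": e,
        "query_chromosome": chrom, "query_start": s, "query_end": e,
        "pident": 90.0} for s, e in intervals], columns=BLOCK_COLS)


def _diff(records, chrom="c", strain="A"):
    return pd.DataFrame([{"strain": strain, "chromosome": chrom,
                          "category": cat, "start": s, "end": e}
                         for cat, s, e in records],
                        columns=["strain", "chromosome", "category", "start", "end"])


# ---------------------------------------------------------------------------
# conservation classification

class TestClassifyConservation:
    def test_fully_inside_gap_is_non_conserved(self):
        status = classify_conservation(("c", 1000, 2000), _blocks([]),
                                       _diff([("GAP", 500, 5000)]))
        assert status == "non_conserved"

    def test_one_bp_block_overlap_is_conserved(self):
        status = classify_conservation(("c", 1000, 2000), _blocks([(1999, 3000)]),
                                       _diff([("GAP", 0, 1999)]))
        assert status == "conserved"

    def test_neither_is_unresolved(self):
        status = classify_conservation(("c", 1000, 2000), _blocks([(5000, 6000)]),
                                       _diff([("GAP", 0, 1500)]))
        assert status == "unresolved"

    def test_absent_chromosome_unresolved(self):
        status = classify_conservation(("other", 0, 100), _blocks([(0, 10)]),
                                       _diff([("GAP", 0, 10)]))
        assert status == "unresolved"

    def test_gap_union_covers_gene_split_across_records(self):
        status = classify_conservation(("c", 1000, 2000), _blocks([]),
                                       _diff([("GAP", 900, 1500), ("GAP", 1500, 2100)]))
        assert status == "non_conserved"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 1000
        for _ in range(200):
            blocks = [(int(s), int(s + rng.integers(5, 80)))
                      for s in rng.integers(0, L - 80, size=rng.integers(0, 5))]
            gaps = [(int(s), int(s + rng.integers(5, 80)))
                    for s in rng.integers(0, L - 80, size=rng.integers(0, 5))]
            gs = int(rng.integers(0, L - 50))
            ge = gs + int(rng.integers(1, 50))
            got = classify_conservation(("c", gs, ge), _blocks(blocks),
                                        _diff([("GAP", s, e) for s, e in gaps]))
            # per-base oracle
            base_in_block = [any(s <= p < e for s, e in blocks)
                             for p in range(gs, ge)]
            base_in_gap = [any(s <= p < e for s, e in gaps)
                           for p in range(gs, ge)]
            if not blocks and not gaps:
                want = "unresolved"
            elif any(base_in_block):
                want = "conserved"
            elif all(base_in_gap):
                want = "non_conserved"
            else:
                want = "unresolved"
            assert got == want

    def test_conserved_wins_when_block_and_gap_overlap(self):
        status = classify_conservation(("c", 1000, 2000), _blocks([(0, 5000)]),
                                       _diff([("GAP", 0, 5000)]))
        assert status == "conserved"


# ---------------------------------------------------------------------------
# conservation summary (in-paper arithmetic)

class TestSummary:
    @staticmethod
    def _table(total, conserved, strain="s"):
        statuses = (["conserved"] * conserved
                    + ["non_conserved"] * (total - conserved))
        return pd.DataFrame({"strain": strain, "gene_id": range(total),
                             "conservation_status": statuses})

    def test_neff_like_percentage(self):
        summary = summarize_conservation(self._table(750, 282))["s"]
        assert summary["percent_conserved"] == 38
        assert summary["non_conserved"] == 468

    def test_c3_like_percentage(self):
        summary = summarize_conservation(self._table(642, 338))["s"]
        assert summary["percent_conserved"] == 53
        assert summary["non_conserved"] == 304

    def test_all_conserved_is_100(self):
        assert summarize_conservation(self._table(10, 10))["s"][
            "percent_conserved"] == 100

    def test_empty_is_undefined(self):
        summary = summarize_conservation(self._table(0, 0))
        assert summary == {} or summary.get("s", {}).get("percent_conserved") is None

    def test_partition_sums(self):
        df = self._table(100, 40)
        df.loc[95:, "conservation_status"] = "unresolved"
        s = summarize_conservation(df)["s"]
        assert s["conserved"] + s["non_conserved"] + s["unresolved"] == s["total"]


# ---------------------------------------------------------------------------
# divergent-region construction

def region_union_oracle(records, slack):
    """Union-find over pairwise merge decisions; independent of scan order."""
    merges = [(i, r) for i, r in enumerate(records) if r[0] in ("GAP", "DUP", "JMP")]
    breakers = [r for r in records if r[0] in ("INV", "BRK")]
    parent = {i: i for i, _ in merges}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for ii, (i, (_, s1, e1)) in enumerate(merges):
        for j, (_, s2, e2) in merges[ii + 1:]:
            lo, hi = min(e1, e2), max(s1, s2)
            gap = hi - lo
            if gap > slack:
                continue
            if gap > 0 and any(bs < hi and be > lo for _, bs, be in breakers):
                continue
            parent[find(i)] = find(j)
    groups = {}
    for i, (_, s, e) in merges:
        groups.setdefault(find(i), []).append((s, e))
    return sorted((min(s for s, _ in g), max(e for _, e in g))
                  for g in groups.values())


class TestBuildRegions:
    def test_abutting_gap_and_jmp_merge(self):
        regions = build_divergent_regions(
            _diff([("GAP", 100, 200), ("JMP", 200, 350)]))
        assert [(r.start, r.end) for r in regions] == [(100, 350)]

    def test_separated_gaps_stay_apart(self):
        regions = build_divergent_regions(
            _diff([("GAP", 100, 200), ("GAP", 400, 500)]))
        assert [(r.start, r.end) for r in regions] == [(100, 200), (400, 500)]

    def test_breaker_blocks_merge_within_slack(self):
        regions = build_divergent_regions(
            _diff([("GAP", 100, 200), ("INV", 210, 220), ("GAP", 230, 300)]),
            merge_slack=100)
        assert [(r.start, r.end) for r in regions] == [(100, 200), (230, 300)]

    def test_negative_slack_rejected(self):
        with pytest.raises(ValueError):
            build_divergent_regions(_diff([("GAP", 0, 10)]), merge_slack=-1)

    def test_idempotent_on_own_output(self):
        diff = _diff([("GAP", 0, 50), ("DUP", 50, 80), ("GAP", 200, 300)])
        first = build_divergent_regions(diff, merge_slack=10)
        again = build_divergent_regions(
            _diff([("GAP", r.start, r.end) for r in first]), merge_slack=10)
        assert [(r.start, r.end) for r in first] == \
               [(r.start, r.end) for r in again]

    def test_order_independent(self, rng):
        records = [("GAP", 10, 60), ("JMP", 55, 90), ("GAP", 150, 190),
                   ("INV", 120, 130), ("DUP", 190, 240), ("GAP", 400, 410)]
        base = [(r.start, r.end) for r in
                build_divergent_regions(_diff(records), merge_slack=20)]
        for _ in range(10):
            shuffled = [records[i] for i in rng.permutation(len(records))]
            got = [(r.start, r.end) for r in
                   build_divergent_regions(_diff(shuffled), merge_slack=20)]
            assert got == base

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        cats = ["GAP", "GAP", "DUP", "JMP", "INV", "BRK"]
        for _ in range(100):
            slack = int(rng.integers(0, 30))
            records = []
            for _ in range(int(rng.integers(1, 12))):
                s = int(rng.integers(0, 500))
                records.append((cats[rng.integers(0, len(cats))],
                                s, s + int(rng.integers(5, 60))))
            got = [(r.start, r.end) for r in
                   build_divergent_regions(_diff(records), merge_slack=slack)]
            assert sorted(got) == region_union_oracle(records, slack)

    def test_slack_monotonicity(self, rng):
        records = [("GAP", int(s), int(s) + 20)
                   for s in rng.integers(0, 2000, size=30)]
        counts = [len(build_divergent_regions(_diff(records), merge_slack=k))
                  for k in (0, 10, 50, 200, 1000)]
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# viral flagging

def _cand(intervals, chrom="c"):
    return pd.DataFrame([{"gene_id": f"g{i}", "chromosome": chrom,
                          "start": s, "end": e}
                         for i, (s, e) in enumerate(intervals)])


class TestFlagViral:
    def test_contained_candidate_flags_region(self):
        regions = [DivergentRegion("r1", "c", 0, 5000)]
        flag_viral_regions(regions, _cand([(1000, 2000)]))
        assert regions[0].is_viral and regions[0].n_full_viral_genes == 1

    def test_straddling_candidate_does_not_count(self):
        regions = [DivergentRegion("r1", "c", 0, 5000)]
        flag_viral_regions(regions, _cand([(4500, 5500)]))
        assert not regions[0].is_viral

    def test_planted_regions_recovered(self, small_pair):
        from gevescan import io as gio
        from gevescan.candidates import call_all_candidates
        truth = small_pair.truth
        for strain in ("A", "B"):
            diff = small_pair.diff[small_pair.diff.strain == strain]
            regions = build_divergent_regions(diff)
            cands = truth.genes.query(
                "strain == @strain and origin == 'viral'")[
                ["gene_id", "chromosome", "start", "end"]]
            regions = flag_viral_regions(regions, cands)
            got = [(r.chromosome, r.start, r.end)
                   for r in regions if r.is_viral]
            planted = []
            for r in truth.insertions.query("strain == @strain").itertuples():
                has_viral = ((cands.chromosome == r.chromosome)
                             & (cands.start >= r.start)
                             & (cands.end <= r.end)).any()
                if has_viral:
                    planted.append((r.chromosome, r.start, r.end))

            def reciprocal(a, b):
                ov = max(0, min(a[2], b[2]) - max(a[1], b[1]))
                return (a[0] == b[0] and ov >= 0.5 * (a[2] - a[1])
                        and ov >= 0.5 * (b[2] - b[1]))

            tp = sum(any(reciprocal(p, g) for g in got) for p in planted)
            recall = tp / len(planted)
            precision = sum(any(reciprocal(g, p) for p in planted)
                            for g in got) / len(got)
            assert precision >= 0.9 and recall >= 0.9


# ---------------------------------------------------------------------------
# hallmark completeness

def _hallmarks(rows):
    return pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                       "hallmark", "evalue"])


class TestHallmarks:
    REGION = [DivergentRegion("r1", "c", 0, 10_000, is_viral=True,
                              n_full_viral_genes=1)]

    def test_two_of_five(self):
        hm = hallmark_completeness(self.REGION, _hallmarks([
            ("c", 100, 200, "MCP", 1e-8), ("c", 300, 400, "A32_ATPase", 1e-8)]))
        row = hm.iloc[0]
        assert row["MCP"] and row["A32_ATPase"] and not row["full_suite"]
        assert sum(bool(row[h]) for h in
                   ["MCP", "A32_ATPase", "polB", "VLTF3", "SFII"]) == 2

    def test_full_suite(self):
        hm = hallmark_completeness(self.REGION, _hallmarks([
            ("c", i * 100, i * 100 + 50, h, 1e-10)
            for i, h in enumerate(["MCP", "A32_ATPase", "polB", "VLTF3", "SFII"])]))
        assert bool(hm.iloc[0]["full_suite"])

    def test_boundary_evalue_exactly_1e5_discarded(self):
        hm = hallmark_completeness(self.REGION, _hallmarks([
            ("c", 100, 200, "MCP", 1e-5)]))
        assert not hm.iloc[0]["MCP"]

    def test_hit_outside_viral_region_discarded(self):
        hm = hallmark_completeness(self.REGION, _hallmarks([
            ("c", 9_500, 10_500, "MCP", 1e-10)]))
        assert not hm.iloc[0]["MCP"]

    def test_unknown_label_counted_as_other(self):
        hm = hallmark_completeness(self.REGION, _hallmarks([
            ("c", 100, 200, "mystery", 1e-10)]))
        assert hm.iloc[0]["other"] == 1 and not hm.iloc[0]["full_suite"]


class TestZeroDivergencePair:
    def test_no_non_conserved_on_identical_strains(self):
        from tests.conftest import small_config
        from gevescan.simulate import simulate_strain_pair
        cfg = small_config(n_viral_insertions_per_strain=0,
                           n_nonviral_insertions_per_strain=0,
                           duplication_fraction=0.0, background_divergence=0.0)
        pair = simulate_strain_pair(cfg)
        genes = pd.DataFrame([{"gene_id": g.id, "chromosome": g.chromosome,
                               "start": g.start, "end": g.end}
                              for g in pair.genes["A"]])
        statuses = classify_all(genes, pair.blocks, pair.diff, "A")
        assert not (statuses["conservation_status"] == "non_conserved").any()
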