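import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammainc

from gevescan.context import (compaction_permutation_test,
                              detect_telomeric_arrays, detrend_contact_matrix,
                              end_distance_enrichment, end_distances,
                              gc_shift_track, mobile_element_context_chisq,
                              region_compaction_score, region_similarity_links)


def _random_seq(rng, n, gc=0.5):
    return "".join(rng.choice(list("ACGT"), size=n,
                              p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]))


class TestTelomeres:
    def test_exact_tandem(self):
        arrays = detect_telomeric_arrays("TTAGGG" * 10)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.start, a.end) == (0, 60)
        assert a.unit_count == 10 and a.purity == 1.0 and not a.degenerate

    def test_reverse_complement_orientation(self):
        arrays = detect_telomeric_arrays("CCCTAA" * 8)
        assert len(arrays) == 1 and arrays[0].unit == "CCCTAA"

    def test_alternating_mismatch_units(self):
        unit, bad = "TTAGGG", "TTAGGA"  # one mismatch
        seq = (unit + bad) * 5
        arrays = detect_telomeric_arrays(seq)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.unit_count == 10 and a.purity == pytest.approx(0.5)
        assert a.degenerate

    def test_short_unit_rejected(self):
        with pytest.raises(ValueError):
            detect_telomeric_arrays("ACGT", unit="AC")

    def test_below_min_units_ignored(self):
        assert detect_telomeric_arrays("TTAGGG" * 2 + "CCCCCCCCCC") == []

    @pytest.mark.parametrize("seed", range(10))
    def test_null_random_sequence_has_no_arrays(self, seed):
        rng = np.random.default_rng(seed)
        assert detect_telomeric_arrays(_random_seq(rng, 10_000)) == []

    def test_reverse_complement_symmetry(self, rng):
        seq = _random_seq(rng, 500) + "TTAGGG" * 6 + _random_seq(rng, 300)
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        fwd = detect_telomeric_arrays(seq)
        rev = detect_telomeric_arrays(rc)
        n = len(seq)
        mirrored = sorted((n - a.end, n - a.start) for a in rev)
        assert sorted((a.start, a.end) for a in fwd) == mirrored


class TestEndDistance:
    LENGTHS = {"c1": 1000, "c2": 2000}

    def _feats(self, rows):
        return pd.DataFrame(rows, columns=["chromosome", "start", "end"])

    def test_normalized_range(self):
        feats = self._feats([("c1", 0, 10), ("c1", 495, 505), ("c2", 1990, 2000)])
        d = end_distances(feats, self.LENGTHS)
        assert ((d["normalized"] >= 0) & (d["normalized"] <= 0.5)).all()
        assert d.iloc[0]["distance"] == 0
        assert d.iloc[1]["distance"] == 495

    def test_feature_longer_than_chromosome(self):
        with pytest.raises(ValueError):
            end_distances(self._feats([("c1", 0, 1500)]), self.LENGTHS)

    def test_extreme_case_p_is_minimal(self):
        feats = self._feats([("c1", 0, 10)] * 5)
        out = end_distance_enrichment(feats, self.LENGTHS, n_permutations=100,
                                      seed=0)
        assert out["observed_mean_normalized"] == 0.0
        assert out["p_value"] == pytest.approx(1 / 101)

    def test_reversal_symmetry(self):
        feats = self._feats([("c1", 100, 150), ("c2", 300, 420)])
        flipped = self._feats([("c1", 850, 900), ("c2", 1580, 1700)])
        a = end_distances(feats, self.LENGTHS)["normalized"]
        b = end_distances(flipped, self.LENGTHS)["normalized"]
        assert np.allclose(a, b)

    def test_null_p_values_super_uniform(self):
        # uniform placement: rejection rate at any alpha must not exceed alpha
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(500):
            starts = rng.integers(0, 900, size=30)
            feats = self._feats([("c1", int(s), int(s) + 100) for s in starts])
            out = end_distance_enrichment(feats, {"c1": 1000},
                                          n_permutations=199, seed=rng)
            pvals.append(out["p_value"])
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.10, 0.25):
            rate = (pvals <= alpha).mean()
            assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 500)
        assert abs(pvals.mean() - 0.5) < 0.06


class TestChisq:
    def test_known_2x2_statistic(self):
        out = mobile_element_context_chisq(
            pd.DataFrame([[10, 20], [20, 10]]), monte_carlo_reps=200)
        assert out["statistic"] == pytest.approx(6.667, abs=5e-4)
        assert out["df"] == 1

    def test_proportional_table_is_null(self):
        out = mobile_element_context_chisq(pd.DataFrame([[10, 20], [30, 60]]))
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_p_matches_distribution_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            t = pd.DataFrame(rng.integers(5, 80, size=(4, 3)))
            out = mobile_element_context_chisq(t, min_expected=0)
            # independent oracle via the regularized incomplete gamma function
            want = 1.0 - gammainc(out["df"] / 2.0, out["statistic"] / 2.0)
            assert out["p_value"] == pytest.approx(want, abs=1e-9)

    def test_permutation_invariance(self, rng):
        t = rng.integers(1, 50, size=(3, 3)).astype(float)
        base = mobile_element_context_chisq(pd.DataFrame(t))["statistic"]
        perm = t[np.ix_(rng.permutation(3), rng.permutation(3))]
        got = mobile_element_context_chisq(pd.DataFrame(perm))["statistic"]
        assert got == pytest.approx(base)

    def test_zero_margin_dropped(self):
        t = pd.DataFrame([[10, 20, 0], [20, 10, 0], [0, 0, 0]])
        out = mobile_element_context_chisq(t, monte_carlo_reps=100)
        assert out["df"] == 1

    def test_monte_carlo_close_to_asymptotic_when_counts_large(self):
        t = pd.DataFrame([[40, 60], [55, 45]])
        out = mobile_element_context_chisq(t, min_expected=1e9,
                                           monte_carlo_reps=4000, seed=1)
        assert out["monte_carlo_p"] == pytest.approx(out["p_value"], abs=0.03)


class TestGcShift:
    def test_homopolymer_no_shift(self):
        track, shifts = gc_shift_track("G" * 5000, window_bp=1000)
        assert np.allclose(track["value"], 1.0) and shifts == []

    def test_single_junction_flagged(self):
        seq = "AT" * 1000 + "GC" * 1000
        track, shifts = gc_shift_track(seq, window_bp=1000)
        assert shifts == [2000]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = _random_seq(rng, 5234, gc=0.4)
        track, _ = gc_shift_track(seq, window_bp=1000)
        for r in track.itertuples():
            window = seq[r.start:r.end]
            want = (window.count("G") + window.count("C")) / len(window)
            assert r.value == pytest.approx(want, abs=1e-12)


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(out)


class TestSimilarityLinks:
    def test_identical_regions_full_link(self, rng):
        seq = _random_seq(rng, 5000)
        links = region_similarity_links({"r1": seq, "r2": seq})
        assert len(links) == 1
        link = links[0]
        assert link.percent_identity >= 99.5
        assert link.span >= 4900

    @pytest.mark.parametrize("seed", range(5))
    def test_independent_random_regions_no_link(self, seed):
        rng = np.random.default_rng(seed)
        links = region_similarity_links({"r1": _random_seq(rng, 5000),
                                         "r2": _random_seq(rng, 5000)})
        assert links == []

    def test_mutated_copy_identity_matches_alignment_oracle(self):
        from Bio import Align
        rng = np.random.default_rng(5)
        a = _random_seq(rng, 4000)
        b = _mutate(rng, a, 0.10)
        links = region_similarity_links({"a": a, "b": b})
        assert len(links) == 1
        link = links[0]
        assert link.percent_identity == pytest.approx(90.0, abs=3.0)
        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=-1,
                                        open_gap_score=-5, extend_gap_score=-2)
        aln = aligner.align(a, b)[0]
        matches = sum(
            1 for (s1, e1), (s2, e2) in zip(*aln.aligned)
            for x, y in zip(a[s1:e1], b[s2:e2]) if x == y)
        oracle_identity = 100.0 * matches / len(a)
        assert link.percent_identity == pytest.approx(oracle_identity, abs=3.0)

    def test_region_shorter_than_k_skipped(self, rng):
        links = region_similarity_links({"tiny": "ACGT",
                                         "r": _random_seq(rng, 1000)})
        assert links == []

    def test_low_complexity_not_linked(self):
        # pure dinucleotide repeats share k-mers but must be masked away
        links = region_similarity_links({"r1": "AT" * 1000, "r2": "AT" * 1000})
        assert links == []


class TestDetrend:
    def test_distance_only_matrix_gives_ones(self):
        n = 30
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = 100.0 / (1.0 + idx)
        oe = detrend_contact_matrix(m)
        assert np.allclose(oe, 1.0)

    def test_all_zero_matrix(self):
        oe = detrend_contact_matrix(np.zeros((10, 10)))
        assert (oe == 0).all()

    def test_asymmetric_rejected(self):
        m = np.zeros((5, 5))
        m[0, 1] = 3
        with pytest.raises(ValueError):
            detrend_contact_matrix(m)

    @pytest.mark.parametrize("seed", range(5))
    def test_per_diagonal_means_are_one(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        upper = np.triu(rng.poisson(20, size=(n, n)).astype(float))
        m = upper + np.triu(upper, 1).T
        oe = detrend_contact_matrix(m)
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        for s in range(n):
            vals = m[idx == s]
            if vals.mean() > 0:
                assert oe[idx == s].mean() == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        n = 15
        upper = np.triu(rng.poisson(10, size=(n, n)).astype(float))
        m = upper + np.triu(upper, 1).T
        oe = detrend_contact_matrix(m)
        for i in range(n):
            for j in range(n):
                s = abs(i - j)
                vals = [m[a, b] for a in range(n) for b in range(n)
                        if abs(a - b) == s]
                expected = float(np.mean(vals))
                want = m[i, j] / expected if expected > 0 else 0.0
                assert oe[i, j] == pytest.approx(want, abs=1e-9)


class TestCompaction:
    def test_uniform_matrix_scores_zero(self):
        oe = np.ones((40, 40))
        score = region_compaction_score(oe, 0, 40_000, 1000)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_sub_two_bin_region_undefined(self):
        assert region_compaction_score(np.ones((10, 10)), 0, 1500, 1000) is None

    def test_doubled_intra_region_counts_score_one(self):
        # region small vs the matrix so the boost barely moves the expected
        n, bs = 400, 1000
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = 1000.0 / (1.0 + idx)
        region = (10, 20)  # bins
        mask = np.zeros(n, dtype=bool)
        mask[region[0]:region[1]] = True
        boost = np.outer(mask, mask) & (idx > 0)
        m2 = np.where(boost, m * 2, m)
        oe = detrend_contact_matrix(m2)
        score = region_compaction_score(oe, region[0] * bs, region[1] * bs, bs)
        assert score == pytest.approx(1.0, abs=0.1)

    def test_planted_insertions_more_compact_than_random(self, small_pair,
                                                         small_dir):
        from gevescan import io as gio
        cfg = small_pair.config
        oe_by_chrom = {}
        bin_size = cfg.hic_bin_size
        for chrom in small_pair.sequences["A"]:
            mat, bs, _ = gio.read_hic_triplets(small_dir / f"A.hic.{chrom}.tsv")
            oe_by_chrom[chrom] = detrend_contact_matrix(mat)
        ins = small_pair.truth.insertions.query("strain == 'A' and kind == 'viral'")
        regions = ins.rename(columns={"id": "region_id"})[
            ["region_id", "chromosome", "start", "end"]]
        out = compaction_permutation_test(oe_by_chrom, regions, bin_size,
                                          n_permutations=500, seed=3)
        assert out["p_value"] < 0.05
        assert out["observed_mean"] > 0
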