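"""Peak processing: concordance, merging, windows, correlation, clustering, motifs."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from oracles import iupac_match_oracle, max_overlap_matching, spearman_oracle
from regtarget.genomic_io import GenomicInterval, Peak, PeakSet
from regtarget.peaks import (
    SignalMatrix,
    consensus_motif_enrichment,
    correlation_matrix,
    hierarchical_cluster,
    high_confidence_peaks,
    merge_intervals,
    normalized_signal,
    replicate_concordance,
    reverse_complement,
    spearman_rho,
    summit_windows,
)
from regtarget.simulate import generate_null_peaks, generate_signal


def shift_peaks(ps, delta, tag):
    out = []
    for p in ps:
        iv = p.interval
        out.append(Peak(GenomicInterval(iv.chrom, iv.start + delta, iv.end + delta),
                        p.summit + delta, p.score, f"{p.name}_{tag}"))
    return PeakSet(f"{ps.sample_id}_{tag}", out)


class TestConcordance:
    def test_identical_sets_fully_concordant(self, small_peakset):
        r = replicate_concordance(small_peakset, small_peakset)
        assert r.n_shared == len(small_peakset) and r.concordance == 1.0

    def test_partial_overlap_with_disjoint_extra(self, peak_factory):
        # 10 peaks; replicate B carries 8 of them shifted +10 bp plus 1 disjoint peak
        a = PeakSet("a", [peak_factory("chr1", i * 1000, i * 1000 + 200, name=f"a{i}")
                          for i in range(10)])
        shifted = shift_peaks(PeakSet("b", a.peaks[:8]), 10, "s")
        b = PeakSet("b", shifted.peaks + [peak_factory("chr2", 0, 100, name="extra")])
        r = replicate_concordance(a, b)
        assert r.n_shared == 8
        assert r.concordance == pytest.approx(8 / 9)

    def test_disjoint_sets_zero_concordance(self, peak_factory):
        a = PeakSet("a", [peak_factory("chr1", 0, 100, name="a")])
        b = PeakSet("b", [peak_factory("chr1", 200, 300, name="b")])
        assert replicate_concordance(a, b).concordance == 0.0

    def test_symmetry(self, peak_factory):
        rng = np.random.default_rng(7)
        def random_set(tag):
            starts = np.sort(rng.integers(0, 100_000, 50))
            return PeakSet(tag, [peak_factory("chr1", int(s), int(s) + 150, name=f"{tag}{i}")
                                 for i, s in enumerate(starts)])
        a, b = random_set("a"), random_set("b")
        assert (replicate_concordance(a, b).concordance
                == replicate_concordance(b, a).concordance)

    def test_empty_set_is_an_error(self, small_peakset):
        with pytest.raises(ValueError):
            replicate_concordance(small_peakset, PeakSet("e", []))

    def test_mean_denominator_option(self, peak_factory):
        a = PeakSet("a", [peak_factory("chr1", 0, 100, name="a1"),
                          peak_factory("chr1", 1000, 1100, name="a2")])
        b = PeakSet("b", [peak_factory("chr1", 50, 150, name="b1")])
        r = replicate_concordance(a, b, denominator="mean")
        assert r.concordance == pytest.approx(0.5 * (1 / 2 + 1 / 1))

    def test_greedy_pairing_is_maximum_matching_on_random_instances(self):
        for seed in range(5):
            a = generate_null_peaks({"chr1": 2_000_000}, 120, seed=seed, sample_id="a")
            b = generate_null_peaks({"chr1": 2_000_000}, 110, seed=seed + 50, sample_id="b")
            greedy = replicate_concordance(a, b).n_shared
            assert greedy == max_overlap_matching(a.sorted().peaks, b.sorted().peaks)


class TestHighConfidence:
    def test_merged_peak_takes_union_and_higher_scoring_summit(self, peak_factory):
        a = PeakSet("a", [peak_factory("chr1", 100, 200, 150, 10.0, "a1")])
        b = PeakSet("b", [peak_factory("chr1", 150, 250, 180, 20.0, "b1")])
        merged = high_confidence_peaks(a, b)
        p = merged.peaks[0]
        assert (p.interval.start, p.interval.end) == (100, 250)
        assert p.summit == 180 and p.score == 20.0

    def test_score_tie_favours_replicate_a(self, peak_factory):
        a = PeakSet("a", [peak_factory("chr1", 100, 200, 120, 5.0, "a1")])
        b = PeakSet("b", [peak_factory("chr1", 150, 250, 180, 5.0, "b1")])
        assert high_confidence_peaks(a, b).peaks[0].summit == 120

    def test_disjoint_replicates_give_empty_set(self, peak_factory):
        a = PeakSet("a", [peak_factory("chr1", 0, 100, name="a")])
        b = PeakSet("b", [peak_factory("chr2", 0, 100, name="b")])
        assert len(high_confidence_peaks(a, b)) == 0

    def test_identical_replicates_reproduce_input(self, small_peakset):
        merged = high_confidence_peaks(small_peakset, small_peakset)
        assert len(merged) == len(small_peakset)
        for p, q in zip(merged.sorted(), small_peakset.sorted()):
            assert (p.interval.start, p.interval.end, p.summit, p.score) == (
                q.interval.start, q.interval.end, q.summit, q.score)

    def test_output_never_exceeds_smaller_replicate(self, peak_factory):
        rng = np.random.default_rng(3)
        a = generate_null_peaks({"chr1": 500_000}, 40, seed=1, sample_id="a")
        b = generate_null_peaks({"chr1": 500_000}, 25, seed=2, sample_id="b")
        assert len(high_confidence_peaks(a, b)) <= min(len(a), len(b))


class TestSummitWindows:
    SIZES = {"chr1": 10_000, "chr2": 10_000}

    def test_window_centred_on_summit(self, peak_factory):
        ps = PeakSet("s", [peak_factory("chr1", 900, 1200, 1000, name="p")])
        (w,) = summit_windows(ps, self.SIZES, width=100)
        assert (w.start, w.end) == (950, 1050)

    def test_clipping_at_chromosome_start(self, peak_factory):
        ps = PeakSet("s", [peak_factory("chr1", 0, 100, 30, name="p")])
        (w,) = summit_windows(ps, self.SIZES, width=160)
        assert (w.start, w.end) == (0, 110)

    def test_odd_width_rejected(self, small_peakset):
        with pytest.raises(ValueError, match="even"):
            summit_windows(small_peakset, {"chr1": 10**6, "chr2": 10**6}, width=101)

    def test_unknown_chromosome_rejected(self, peak_factory):
        ps = PeakSet("s", [peak_factory("chr9", 0, 100, name="p")])
        with pytest.raises(KeyError):
            summit_windows(ps, self.SIZES)

    def test_merge_intervals_unions_overlaps(self):
        ivs = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150),
               GenomicInterval("chr1", 200, 300), GenomicInterval("chr2", 0, 50)]
        merged = merge_intervals(ivs)
        assert [(m.chrom, m.start, m.end) for m in merged] == [
            ("chr1", 0, 150), ("chr1", 200, 300), ("chr2", 0, 50)]


class TestNormalizedSignal:
    def test_rpm_arithmetic(self):
        assert normalized_signal([5, 10], 1e6).tolist() == [5.0, 10.0]
        assert normalized_signal([7], 2e6)[0] == pytest.approx(3.5)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            normalized_signal([1], 0)

    def test_scale_invariance(self):
        counts = np.array([3, 9, 27])
        np.testing.assert_allclose(
            normalized_signal(counts, 5e5), normalized_signal(2 * counts, 1e6))


class TestSpearman:
    def test_monotone_and_antimonotone(self):
        assert spearman_rho([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_tied_values_match_brute_force_oracle(self):
        assert spearman_rho([1, 2, 2, 3], [1, 3, 2, 4]) == pytest.approx(
            spearman_oracle([1, 2, 2, 3], [1, 3, 2, 4]), abs=1e-12)

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 51))
            x = rng.integers(0, 8, n).astype(float)   # integer grid forces ties
            y = rng.normal(size=n)
            assert spearman_rho(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_constant_vector_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="rank variance"):
            assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30, unique=True),
           st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_strictly_increasing_transform(self, xs, scale):
        # the affine map must stay strictly increasing after float rounding
        assume(len({scale * x + 1 for x in xs}) == len(xs))
        ys = list(np.linspace(0, 1, len(xs)))
        before = spearman_rho(xs, ys)
        after = spearman_rho([scale * x + 1 for x in xs], ys)
        assert before == pytest.approx(after, abs=1e-9)
        assert -1.0 <= before <= 1.0


class TestCorrelationMatrix:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        windows = [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(values.shape[0])]
        return SignalMatrix(windows, [f"s{j}" for j in range(values.shape[1])], values)

    def test_identical_columns_give_unit_offdiagonal(self):
        col = np.arange(10.0)
        cm = correlation_matrix(self._matrix(np.column_stack([col, col])))
        assert cm.rho[0, 1] == pytest.approx(1.0)

    def test_decreasing_transform_gives_minus_one(self):
        col = np.arange(10.0)
        cm = correlation_matrix(self._matrix(np.column_stack([col, 100 / (col + 1)])))
        assert cm.rho[0, 1] == pytest.approx(-1.0)

    def test_group_structure_from_generator(self):
        peaks = generate_null_peaks({"chr1": 10_000_000}, 200, seed=5)
        samples = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        libs = {s: 1e6 for s in samples}
        counts = generate_signal(peaks, samples, libs, group_effect=4.0, seed=5)
        wide = counts.pivot_table(index="window_id", columns="sample", values="count")
        sm = self._matrix(wide[["a1", "a2", "b1", "b2"]].to_numpy())
        sm.sample_ids = ["a1", "a2", "b1", "b2"]
        cm = correlation_matrix(sm)
        within = (cm.rho[0, 1] + cm.rho[2, 3]) / 2
        between = (cm.rho[0, 2] + cm.rho[0, 3] + cm.rho[1, 2] + cm.rho[1, 3]) / 4
        assert within > between


class TestHierarchicalCluster:
    def test_identical_items_merge_at_height_zero(self):
        link = hierarchical_cluster([[1.0, 2.0], [1.0, 2.0]])
        assert link.heights[0] == pytest.approx(0.0)

    def test_average_linkage_first_merge_is_closest_pair(self):
        link = hierarchical_cluster([[0.0], [1.0], [10.0]], method="average")
        assert link.heights[0] == pytest.approx(1.0)
        assert set(link.merges[0, :2].astype(int)) == {0, 1}

    def test_ward_heights_non_decreasing(self):
        rng = np.random.default_rng(2)
        link = hierarchical_cluster(rng.normal(size=(12, 4)), method="ward")
        assert np.all(np.diff(link.heights) >= -1e-12)

    def test_leaves_partition_all_items(self):
        rng = np.random.default_rng(3)
        link = hierarchical_cluster(rng.normal(size=(9, 3)))
        assert sorted(link.leaf_order) == list(range(9))

    def test_ward_with_correlation_metric_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster([[1.0, 2.0], [3.0, 4.0]], metric="one_minus_rho")

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster([[np.nan, 1.0], [0.0, 1.0]])

    def test_newick_export_contains_all_labels(self):
        link = hierarchical_cluster([[0.0], [1.0], [5.0]], labels=["x", "y", "z"])
        nwk = link.to_newick()
        assert nwk.endswith(";") and all(lbl in nwk for lbl in "xyz")


class TestMotifEnrichment:
    def test_forward_strand_match(self):
        r = consensus_motif_enrichment(["TTCAAAGAA"], n_shuffles=5, seed=0)
        assert r.n_with_match == 1

    def test_reverse_complement_match(self):
        # TTCTTTGAA reverse-complements to TTCAAAGAA, matching TTCNNNGAA
        assert reverse_complement("TTCTTTGAA") == "TTCAAAGAA"
        r = consensus_motif_enrichment(["TTCTTTGAA"], n_shuffles=5, seed=0)
        assert r.n_with_match == 1

    def test_all_no_match_gives_p_one(self):
        r = consensus_motif_enrichment(["AAAAAAAAA", "CCCCCCCCC"], n_shuffles=5, seed=0)
        assert r.n_with_match == 0 and r.p_value == 1.0

    def test_matcher_agrees_with_iupac_expansion_oracle(self):
        rng = np.random.default_rng(17)
        fwd_hits = 0
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), 200))
            r = consensus_motif_enrichment([seq], n_shuffles=1, seed=0)
            expected = iupac_match_oracle(seq, "TTCNNNGAA")
            assert (r.n_with_match == 1) == expected
            fwd_hits += expected
        assert fwd_hits > 0  # the 200-bp null should contain some hits

    def test_seed_determinism(self):
        seqs = ["TTCAAAGAAACGTACGT", "ACGTACGTACGTACGTA"]
        a = consensus_motif_enrichment(seqs, n_shuffles=20, seed=42)
        b = consensus_motif_enrichment(seqs, n_shuffles=20, seed=42)
        assert a == b

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            consensus_motif_enrichment([])

    def test_planted_motif_is_significant(self):
        rng = np.random.default_rng(23)
        seqs = []
        for _ in range(30):
            s = list(rng.choice(list("ACGT"), 60))
            pos = int(rng.integers(0, 50))
            s[pos:pos + 9] = list("TTCAAAGAA")
            seqs.append("".join(s))
        r = consensus_motif_enrichment(seqs, n_shuffles=20, seed=1)
        assert r.n_with_match == 30 and r.p_value < 1e-6
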