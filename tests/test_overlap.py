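"""Interval overlap counting, shuffling and permutation significance."""

import numpy as np
import pytest

import pbletools as pt
from pbletools.core import Interval
from pbletools.overlap import (
    count_overlapping,
    filter_exclusion,
    ir_overlap_fraction,
    peak_summaries,
    permutation_test,
    shuffle_intervals,
)

from oracles import brute_force_overlap_count


def _random_intervals(rng, n, contigs, contig_len, max_width=300):
    out = []
    for i in range(n):
        c = contigs[int(rng.integers(len(contigs)))]
        w = int(rng.integers(1, max_width))
        s = int(rng.integers(0, contig_len - w))
        out.append(Interval(c, s, s + w, label=f"iv{i}"))
    return out


class TestFilterExclusion:
    def test_one_bp_overlap_removes(self):
        assert filter_exclusion([Interval("c1", 10, 20)],
                                [Interval("c1", 19, 30)]) == []

    def test_half_open_adjacency_keeps(self):
        peaks = [Interval("c1", 10, 20)]
        assert filter_exclusion(peaks, [Interval("c1", 20, 30)]) == peaks

    def test_empty_exclusion_is_identity(self):
        peaks = [Interval("c1", 10, 20)]
        assert filter_exclusion(peaks, []) == peaks


class TestCountOverlapping:
    def test_self_overlap_counts_each_query_once(self):
        ivs = [Interval("c1", i * 100, i * 100 + 50) for i in range(7)]
        assert count_overlapping(ivs, ivs) == 7

    def test_disjoint_sets(self):
        a = [Interval("c1", 0, 10)]
        b = [Interval("c1", 50, 60), Interval("c2", 0, 10)]
        assert count_overlapping(a, b) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        q = _random_intervals(rng, 60, ["c1", "c2"], 5000)
        a = _random_intervals(rng, 40, ["c1", "c2"], 5000)
        assert count_overlapping(q, a) == brute_force_overlap_count(q, a)


class TestShuffleIntervals:
    lengths = {"c1": 10_000, "c2": 8_000}

    def test_preserves_contig_counts_and_length_multiset(self):
        rng = np.random.default_rng(3)
        ivs = _random_intervals(rng, 30, ["c1", "c2"], 5000)
        out = shuffle_intervals(ivs, self.lengths, seed=9)
        for c in self.lengths:
            assert sorted(i.length for i in out if i.contig == c) == \
                sorted(i.length for i in ivs if i.contig == c)

    def test_outputs_mutually_non_overlapping(self):
        ivs = [Interval("c1", 0, 400, label=str(i)) for i in range(20)]
        for seed in range(5):
            out = sorted(shuffle_intervals(ivs, self.lengths, seed=seed),
                         key=lambda i: i.start)
            assert all(a.end <= b.start for a, b in zip(out, out[1:]))

    def test_infeasible_raises(self):
        ivs = [Interval("c1", 0, 600), Interval("c1", 0, 600)]
        with pytest.raises(ValueError):
            shuffle_intervals(ivs, {"c1": 1000}, seed=1)

    def test_single_interval_placed_uniformly(self):
        """One 100-bp interval on a 1-kb contig: start is uniform on
        [0, 900], so the Monte-Carlo mean start is ~450."""
        starts = [
            shuffle_intervals([Interval("c1", 0, 100)], {"c1": 1000},
                              seed=s)[0].start
            for s in range(2000)
        ]
        assert abs(np.mean(starts) - 450) < 20
        assert min(starts) >= 0 and max(starts) <= 900


class TestPermutationTest:
    lengths = {"c1": 200_000, "c2": 200_000}

    def _annotations(self, seed=5):
        template = [Interval(("c1", "c2")[i % 2], 0, 400, label=f"a{i}")
                    for i in range(60)]
        return shuffle_intervals(template, self.lengths, seed=seed)

    def test_planted_enrichment_is_significant(self):
        anns = self._annotations()
        peaks, _ = pt.make_interval_sets(self.lengths, 80, 300, anns, 1.0,
                                         seed=2)
        res = permutation_test(peaks, anns, self.lengths, n_perm=500, seed=3)
        assert res.z > 0 and res.p < 0.05 and res.p_empirical < 0.05

    def test_whole_genome_annotation_is_degenerate(self):
        anns = [Interval(c, 0, L) for c, L in self.lengths.items()]
        peaks = [Interval("c1", 100, 400), Interval("c2", 100, 400)]
        res = permutation_test(peaks, anns, self.lengths, n_perm=100, seed=1)
        assert res.observed == 2 and res.null_sd == 0
        assert res.z is None and res.p is None

    def test_translation_invariance(self):
        anns = self._annotations()
        peaks, _ = pt.make_interval_sets(self.lengths, 50, 300, anns, 0.6,
                                         seed=7)
        res1 = permutation_test(peaks, anns, self.lengths, n_perm=300, seed=11)
        shift = 1234
        peaks2 = [Interval(i.contig, i.start + shift, i.end + shift)
                  for i in peaks]
        anns2 = [Interval(i.contig, i.start + shift, i.end + shift)
                 for i in anns]
        lengths2 = {c: L + shift for c, L in self.lengths.items()}
        res2 = permutation_test(peaks2, anns2, lengths2, n_perm=300, seed=11)
        assert res2.observed == res1.observed

    def test_power_increases_with_planted_enrichment(self):
        anns = self._annotations()
        mean_z = []
        for frac in (0.0, 0.3, 0.6, 0.9):
            zs = []
            for rep in range(10):
                peaks, _ = pt.make_interval_sets(
                    self.lengths, 80, 300, anns, frac, seed=100 + rep
                )
                res = permutation_test(peaks, anns, self.lengths, n_perm=300,
                                       seed=200 + rep)
                zs.append(res.z)
            mean_z.append(np.mean(zs))
        assert mean_z == sorted(mean_z)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            permutation_test([], [], self.lengths, n_perm=1)
        with pytest.raises(ValueError):
            permutation_test([], [], self.lengths, tail="sideways")


class TestPeakSummaries:
    def test_density_example(self):
        (table, _) = peak_summaries([Interval("c1", 0, 500, score=100.0)])
        assert table["density"].iloc[0] == pytest.approx(0.2)

    def test_median_example(self):
        peaks = [Interval("c1", 0, w, label="cat", score=1.0)
                 for w in (1, 2, 3)]
        _, medians = peak_summaries(peaks)
        assert medians.loc[medians.category == "cat", "width"].iloc[0] == 2

    def test_medians_match_sort_based_oracle(self):
        rng = np.random.default_rng(8)
        peaks, cats = [], []
        for i in range(60):
            w = int(rng.integers(100, 2000))
            peaks.append(Interval("c1", 0, w, score=float(rng.integers(1, 500))))
            cats.append("x" if i % 2 else "y")
        table, medians = peak_summaries(peaks, cats)
        for cat in ("x", "y"):
            widths = sorted(table.loc[table.category == cat, "width"])
            mid = (widths[len(widths) // 2 - 1] + widths[len(widths) // 2]) / 2
            assert medians.loc[medians.category == cat, "width"].iloc[0] == mid


class TestIrOverlapFraction:
    def test_all_peaks_on_planted_irs(self):
        genome, truth = pt.make_genome(
            {"c1": 50_000}, seed=3, planted={"ir_pairs": [(10, 5)] * 10}
        )
        irs = truth["ir_pairs"]
        peaks = [Interval("c1", iv.start - 20, iv.end + 20) for iv in irs]
        assert ir_overlap_fraction(peaks, irs) == 100.0

    def test_no_annotations_gives_zero(self):
        assert ir_overlap_fraction([Interval("c1", 0, 100)], []) == 0.0

    def test_matches_brute_force_fraction(self):
        rng = np.random.default_rng(12)
        peaks = _random_intervals(rng, 50, ["c1"], 20_000)
        irs = _random_intervals(rng, 30, ["c1"], 20_000, max_width=40)
        expected = 100.0 * brute_force_overlap_count(peaks, irs) / len(peaks)
        assert ir_overlap_fraction(peaks, irs) == expected
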