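"""Junction calling, deduplication, classification and summaries."""

import pytest

import pbletools as pt
from pbletools.junctions import (
    FIVE_PRIME,
    THREE_PRIME,
    JunctionEvent,
    breakpoint_histogram,
    classify,
    dedupe_and_filter,
    expected_random_fraction,
    extract_flanks,
    fold_over_random,
    summarize,
)
from pbletools.synth import (
    IMPROPER_BOTH,
    IMPROPER_TSD_PROPER_TIR,
    PROPER_TSD_IMPROPER_TIR,
    PROPER_TSD_TIR,
    UNCLASSIFIED,
)
from pbletools import ClassCounts


def _true_junction_map(events):
    out = {}
    for ev in events:
        for end, j in ((FIVE_PRIME, ev.junction5), (THREE_PRIME, ev.junction3)):
            out[(j[0], j[1], end, j[3])] = (j[2], ev.truth.true_class)
    return out


def _run_pipeline(genome, donor, events, depth=3, rate=0.0, seed=5):
    reads = pt.simulate_reads(events, per_event_depth=depth,
                              substitution_rate=rate, seed=seed)
    result = pt.call_junctions(reads, genome, donor)
    unique = pt.dedupe_and_filter(result.events)
    pt.annotate_events(unique, genome, donor)
    return result, unique


class TestCallJunctions:
    def test_error_free_recovery_is_exact(self, small_genome, mer75_donor):
        """On error-free reads every planted junction is recovered with the
        correct chromosomal and donor coordinates and signature class."""
        events, _ = pt.simulate_integrations(
            small_genome, mer75_donor, 40, seed=17
        )
        result, unique = _run_pipeline(small_genome, mer75_donor, events)
        assert result.n_no_split == 0
        truth = _true_junction_map(events)
        called = {
            (e.contig, e.chrom_pos, e.end, e.orientation): (e.donor_pos, e.klass)
            for e in unique
        }
        assert called == truth

    def test_cassette_read_discarded_at_stage_one(self, small_genome, donor):
        c0, c1 = donor.cassette
        read = donor.sequence[c0 + 10 : c0 + 260]
        result = pt.call_junctions([("r1", read)], small_genome, donor)
        assert result.n_stage1_discarded == 1 and result.events == []

    def test_unsplittable_read_dropped_and_counted(self, small_genome, donor):
        read = small_genome["chr1"][100:350]  # pure genome, no donor prefix
        result = pt.call_junctions([("r1", read)], small_genome, donor)
        assert result.n_no_split == 1 and result.events == []

    def test_short_read_rejected(self, small_genome, donor):
        with pytest.raises(ValueError):
            pt.call_junctions([("r1", "ACGT" * 5)], small_genome, donor)

    def test_robust_to_low_rate_substitutions(self, small_genome, mer75_donor):
        """With deep per-junction read duplication (as in LAM-PCR libraries)
        a 0.5% substitution rate still allows >= 95% of events to be
        recovered at both ends with the correct class."""
        events, _ = pt.simulate_integrations(
            small_genome, mer75_donor, 60, seed=23
        )
        _, unique = _run_pipeline(small_genome, mer75_donor, events,
                                  depth=15, rate=0.005, seed=29)
        truth = _true_junction_map(events)
        called = {
            (e.contig, e.chrom_pos, e.end, e.orientation): (e.donor_pos, e.klass)
            for e in unique
        }
        ok = 0
        for ev in events:
            keys = [
                (ev.junction5[0], ev.junction5[1], FIVE_PRIME, ev.junction5[3]),
                (ev.junction3[0], ev.junction3[1], THREE_PRIME, ev.junction3[3]),
            ]
            if all(k in called and called[k] == truth[k] for k in keys):
                ok += 1
        assert ok / len(events) >= 0.95


class TestDedupeAndFilter:
    def _event(self, donor_pos, donor_ends, pos=500):
        return JunctionEvent(
            contig="c1", chrom_pos=pos, orientation="+", donor_pos=donor_pos,
            end=FIVE_PRIME, donor_ends=donor_ends, read_names=["r"],
        )

    def test_identical_reads_collapse_with_summed_support(self):
        unique = dedupe_and_filter([self._event(100, [100]),
                                    self._event(100, [100])])
        assert len(unique) == 1
        assert unique[0].support == 2 and unique[0].spread == 0

    def test_spread_difference_strictly_below_three(self):
        # difference 3 -> removed; difference 2 -> retained
        assert dedupe_and_filter([self._event(100, [100, 100, 103])]) == []
        kept = dedupe_and_filter([self._event(100, [100, 100, 102])])
        assert len(kept) == 1 and kept[0].spread == 2

    def test_distinct_positions_stay_distinct(self):
        unique = dedupe_and_filter([self._event(100, [100], pos=500),
                                    self._event(100, [100], pos=501)])
        assert len(unique) == 2

    def test_duplicate_rich_input_yields_truth_count(self, small_genome, donor):
        events, _ = pt.simulate_integrations(small_genome, donor, 20, seed=31)
        _, unique = _run_pipeline(small_genome, donor, events, depth=5)
        assert len(unique) == 2 * len(events)


class TestExtractFlanks:
    def test_flanks_and_tsd_around_canonical_site(self):
        genome = pt.GenomeSequence({"c1": "G" * 20 + "TTAA" + "C" * 20})
        info = extract_flanks(genome, "c1", 24, end=FIVE_PRIME, orientation="+")
        assert info.flank_up.endswith("TTAA")
        assert info.tsd_call == "TTAA" and not info.clipped
        assert len(info.flank_up) == len(info.flank_down) == 10

    def test_clipped_near_contig_edge(self):
        genome = pt.GenomeSequence({"c1": "ACGTACGTACGTACGT"})
        info = extract_flanks(genome, "c1", 5)
        assert len(info.flank_up) == 5 and info.clipped

    def test_proper_simulated_events_all_call_ttaa(self, small_genome, donor):
        events, _ = pt.simulate_integrations(
            small_genome, donor, 30, class_mixture=(1, 0, 0, 0), seed=37
        )
        for ev in events:
            for end, j in ((FIVE_PRIME, ev.junction5),
                           (THREE_PRIME, ev.junction3)):
                info = extract_flanks(small_genome, j[0], j[1], end, j[3])
                assert info.tsd_call == "TTAA"


class TestClassify:
    def _event(self, donor_pos, end=FIVE_PRIME, tsd="TTAA"):
        return JunctionEvent(contig="c1", chrom_pos=500, orientation="+",
                             donor_pos=donor_pos, end=end, tsd_call=tsd)

    def test_two_by_two_classification(self, donor):
        t5 = donor.tir5_terminus
        assert classify(self._event(t5), donor) == PROPER_TSD_TIR
        assert classify(self._event(t5 - 12), donor) == PROPER_TSD_IMPROPER_TIR
        assert classify(self._event(t5, tsd="TGCA"), donor) == \
            IMPROPER_TSD_PROPER_TIR
        assert classify(self._event(t5 + 7, tsd="TGCA"), donor) == IMPROPER_BOTH

    def test_one_bp_slip_is_improper_tir(self, donor):
        assert classify(self._event(donor.tir5_terminus + 1), donor) == \
            PROPER_TSD_IMPROPER_TIR

    def test_cassette_breakpoints_unclassified(self, donor):
        assert classify(self._event(donor.cassette[0] + 5), donor) == \
            UNCLASSIFIED

    def test_confusion_matrix_diagonal_on_mixture(self, small_genome,
                                                  mer75_donor):
        events, _ = pt.simulate_integrations(
            small_genome, mer75_donor, 50,
            class_mixture=(0.25, 0.25, 0.25, 0.25), seed=41
        )
        _, unique = _run_pipeline(small_genome, mer75_donor, events)
        truth = _true_junction_map(events)
        for ev in unique:
            key = (ev.contig, ev.chrom_pos, ev.end, ev.orientation)
            assert truth[key][1] == ev.klass


class TestSummaries:
    def test_percentages_from_counts(self):
        cc = ClassCounts.from_counts((43, 6, 15, 319), donor="mer75")
        assert cc.total == 383
        assert list(cc.percentages.values()) == [11.2, 1.6, 3.9, 83.3]

    def test_single_event_is_hundred_percent(self):
        cc = ClassCounts.from_counts((1, 0, 0, 0))
        assert list(cc.percentages.values()) == [100.0, 0.0, 0.0, 0.0]

    def test_partition_and_rounding_invariants(self):
        cc = ClassCounts.from_counts((33, 36, 4, 1240))
        assert sum(cc.counts.values()) == cc.total == 1313
        assert abs(sum(cc.percentages.values()) - 100) <= 0.1

    def test_summarize_excludes_unclassified(self, donor):
        evs = [
            JunctionEvent("c1", 1, "+", donor.tir5_terminus, FIVE_PRIME,
                          tsd_call="TTAA", klass=PROPER_TSD_TIR),
            JunctionEvent("c1", 2, "+", donor.cassette[0] + 1, FIVE_PRIME,
                          klass=UNCLASSIFIED),
        ]
        cc = summarize(evs)
        assert cc.total == 1

    @pytest.mark.parametrize(
        "window,positions,expected",
        [(100, 4, 4.0), (4, 4, 100.0), (400, 4, 1.0)],
    )
    def test_expected_random_fraction(self, window, positions, expected):
        assert expected_random_fraction(window, positions) == expected

    @pytest.mark.parametrize(
        "obs,exp,fold", [(11.2, 3.1, 3.6), (5.8, 3.1, 1.9), (3.1, 3.1, 1.0)]
    )
    def test_fold_over_random(self, obs, exp, fold):
        assert fold_over_random(obs, exp) == fold

    def test_fold_requires_positive_expectation(self):
        with pytest.raises(ValueError):
            fold_over_random(5.0, 0.0)


class TestBreakpointHistogram:
    def test_proper_events_mass_at_tir_termini(self, small_genome, donor):
        events, _ = pt.simulate_integrations(
            small_genome, donor, 10, class_mixture=(1, 0, 0, 0), seed=43
        )
        _, unique = _run_pipeline(small_genome, donor, events)
        hist = breakpoint_histogram(unique)
        assert set(hist["donor_pos"]) == {donor.tir5_terminus,
                                          donor.tir3_terminus}
        assert hist["count"].sum() == len(unique)

    def test_totals_conserved_on_mixture(self, small_genome, mer75_donor):
        events, _ = pt.simulate_integrations(small_genome, mer75_donor, 25,
                                             seed=47)
        _, unique = _run_pipeline(small_genome, mer75_donor, events)
        hist = breakpoint_histogram(unique)
        assert hist["count"].sum() == len(unique)
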