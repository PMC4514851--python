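"""Internal exons, splice sites, PSI, peaks, control pairing, ChIA-PET."""

from collections import defaultdict

import numpy as np
import pytest

from profileseq.annotation import (
    CenteredPeak,
    ControlPair,
    FlankAssignment,
    InteractionPair,
    InternalExon,
    JunctionCounts,
    assign_flanking_peaks,
    chiapet_tables,
    compute_psi,
    extract_internal_exons,
    gc_content,
    match_controls_by_wilcoxon,
    match_tss_distance,
    pair_control_exons,
    reproducible_peaks,
    splice_site_windows,
)
from profileseq.records import AnnotationRecord, GenomicInterval, ReferencePoint


def exon_record(chrom, start, end, strand, tid, feature="exon", source="TEST"):
    attrs = (("gene_id", f"g_{tid}"), ("transcript_id", tid))
    return AnnotationRecord(feature, GenomicInterval(chrom, start, end, strand),
                            tid, f"g_{tid}", attrs, source=source)


def internal(chrom, start, end, strand, tid="tx"):
    return InternalExon(GenomicInterval(chrom, start, end, strand), tid)


class TestExtractInternalExons:
    def three_exon_transcript(self, strand="+"):
        return [
            exon_record("chr1", 5000, 5100, strand, "t1"),
            exon_record("chr1", 9000, 9150, strand, "t1"),
            exon_record("chr1", 13000, 13100, strand, "t1"),
        ]

    def test_clean_middle_exon_kept(self):
        exons = extract_internal_exons(self.three_exon_transcript())
        assert [(e.interval.start, e.interval.end) for e in exons] == [(9000, 9150)]

    def test_two_exon_transcript_yields_nothing(self):
        records = self.three_exon_transcript()[:2]
        assert extract_internal_exons(records) == []

    def test_neighbouring_exon_in_flank_excludes(self):
        records = self.three_exon_transcript()
        # an exon from another transcript 500 nt downstream of the middle exon
        records.append(exon_record("chr1", 9650, 9700, "+", "t2"))
        assert extract_internal_exons(records) == []

    def test_utr_in_flank_excludes(self):
        records = self.three_exon_transcript()
        records.append(exon_record("chr1", 8500, 8600, "+", "t3", feature="UTR"))
        assert extract_internal_exons(records) == []

    def test_tss_in_flank_excludes(self):
        records = self.three_exon_transcript()
        # another transcript starting 400 nt downstream of the middle exon
        records.append(
            exon_record("chr1", 9550, 20000, "+", "t4", feature="transcript")
        )
        assert extract_internal_exons(records) == []

    def test_blacklisted_records_ignored_entirely(self):
        records = self.three_exon_transcript()
        # a pseudogene exon inside the flank would exclude, but is filtered out
        rec = exon_record("chr1", 9650, 9700, "+", "t5")
        rec = AnnotationRecord(
            rec.feature, rec.interval, rec.transcript_id, rec.gene_id,
            rec.attributes + (("gene_type", "pseudogene"),), rec.source,
        )
        records.append(rec)
        exons = extract_internal_exons(records)
        assert len(exons) == 1

    def test_chrM_blacklisted(self):
        records = [
            exon_record("chrM", 5000, 5100, "+", "tm"),
            exon_record("chrM", 9000, 9150, "+", "tm"),
            exon_record("chrM", 13000, 13100, "+", "tm"),
        ]
        assert extract_internal_exons(records) == []

    def test_duplicate_coordinates_collapse(self):
        records = self.three_exon_transcript()
        for rec in self.three_exon_transcript():
            records.append(
                AnnotationRecord(rec.feature, rec.interval, "t1b", "g_t1b",
                                 rec.attributes, rec.source)
            )
        exons = extract_internal_exons(records)
        assert len(exons) == 1

    def test_strand_mirror_invariance(self):
        """Reflecting all coordinates and flipping strands leaves the
        internal-exon set (mirrored back) unchanged."""
        records = self.three_exon_transcript() + [
            exon_record("chr1", 30000, 30100, "+", "t9"),
            exon_record("chr1", 34000, 34150, "+", "t9"),
            exon_record("chr1", 38000, 38100, "+", "t9"),
            exon_record("chr1", 34800, 34900, "+", "t8"),  # blocks t9's middle
        ]
        base = extract_internal_exons(records)
        L = 100000
        flip = {"+": "-", "-": "+"}
        mirrored_records = [
            AnnotationRecord(
                r.feature,
                GenomicInterval(r.interval.chrom, L - r.interval.end,
                                L - r.interval.start, flip[r.interval.strand]),
                r.transcript_id, r.gene_id, r.attributes, r.source,
            )
            for r in records
        ]
        mirrored = extract_internal_exons(mirrored_records)
        back = sorted(
            (L - e.interval.end, L - e.interval.start) for e in mirrored
        )
        assert back == sorted(
            (e.interval.start, e.interval.end) for e in base
        )


class TestSpliceSiteWindows:
    def test_plus_strand_windows(self):
        w3, w5 = splice_site_windows(internal("chr1", 1000, 1200, "+"))
        assert (w3.start, w3.end) == (980, 1002)
        assert (w5.start, w5.end) == (1198, 1206)

    def test_minus_strand_windows_mirror(self):
        w3, w5 = splice_site_windows(internal("chr1", 1000, 1200, "-"))
        assert (w3.start, w3.end) == (1198, 1220)
        assert (w5.start, w5.end) == (994, 1002)

    @pytest.mark.parametrize("start,end,strand", [
        (50, 52, "+"), (1000, 1002, "-"), (123456, 200000, "+"),
    ])
    def test_window_lengths_fixed(self, start, end, strand):
        w3, w5 = splice_site_windows(internal("chr1", start, end, strand))
        assert w3.length == 23 and w5.length == 9

    def test_off_chromosome_start_rejected(self):
        with pytest.raises(ValueError):
            splice_site_windows(internal("chr1", 10, 100, "+"))


class TestPsi:
    def test_balanced_inclusion(self):
        psi, psi3, psi5 = compute_psi(JunctionCounts(5, 5, 5))
        assert psi == pytest.approx(0.5)

    def test_no_skipping_gives_one(self):
        psi, psi3, psi5 = compute_psi(JunctionCounts(4, 6, 0))
        assert psi == psi3 == psi5 == 1.0

    def test_three_prime_psi(self):
        _, psi3, _ = compute_psi(JunctionCounts(4, 0, 2))
        assert psi3 == pytest.approx(4 / 6)

    def test_all_zero_counts_undefined(self):
        assert compute_psi(JunctionCounts(0, 0, 0)) == (None, None, None)

    def test_bounds_and_monotonicity_in_skipping(self, rng):
        for _ in range(50):
            i3, i5 = map(int, rng.integers(0, 20, 2))
            previous = None
            for e in range(0, 15):
                psi, _, _ = compute_psi(JunctionCounts(i3, i5, e))
                if psi is None:
                    continue
                assert 0.0 <= psi <= 1.0
                assert psi == 1.0 if e == 0 else psi < 1.0
                if previous is not None:
                    assert psi <= previous
                previous = psi


class TestReproduciblePeaks:
    def test_overlap_exactly_half_of_smaller_kept(self):
        a = [GenomicInterval("chr1", 100, 199)]       # 100 nt
        b = [GenomicInterval("chr1", 150, 309)]       # overlap 50 nt
        kept = reproducible_peaks(a, b)
        assert len(kept) == 1 and kept[0].center == 150

    def test_overlap_below_half_dropped(self):
        a = [GenomicInterval("chr1", 100, 199)]
        b = [GenomicInterval("chr1", 151, 309)]       # overlap 49 nt
        assert reproducible_peaks(a, b) == []

    def test_identical_replicates_identity(self):
        a = [GenomicInterval("chr1", s, s + 120) for s in (100, 1000, 5000)]
        kept = reproducible_peaks(a, list(a))
        assert [p.interval for p in kept] == a


class TestAssignFlankingPeaks:
    exon_plus = internal("chr1", 2000, 2100, "+")
    exon_minus = internal("chr1", 2000, 2100, "-")

    def peak(self, center):
        return CenteredPeak(GenomicInterval("chr1", center - 10, center + 10),
                            center)

    def test_plus_strand_downstream(self):
        (a,) = assign_flanking_peaks([self.peak(2600)], [self.exon_plus])
        assert (a.side, a.d) == ("DS", 500)

    def test_just_outside_window_unassigned(self):
        assert assign_flanking_peaks([self.peak(3101)], [self.exon_plus]) == []

    def test_minus_strand_downstream_is_lower_coordinates(self):
        (a,) = assign_flanking_peaks([self.peak(1700)], [self.exon_minus])
        assert (a.side, a.d) == ("DS", 300)

    def test_upstream_boundaries(self):
        (a,) = assign_flanking_peaks([self.peak(1999)], [self.exon_plus])
        assert (a.side, a.d) == ("US", 1)
        (b,) = assign_flanking_peaks([self.peak(1000)], [self.exon_plus])
        assert (b.side, b.d) == ("US", 1000)

    def test_peak_may_serve_multiple_exons(self):
        exons = [internal("chr1", 2000, 2100, "+", "tA"),
                 internal("chr1", 3000, 3100, "+", "tB")]
        assigned = assign_flanking_peaks([self.peak(2600)], exons)
        assert {(a.exon.transcript_id, a.side) for a in assigned} == {
            ("tA", "DS"), ("tB", "US")
        }


class TestPairControlExons:
    def setup_assignment(self, exon):
        peak = CenteredPeak(GenomicInterval("chr1", 2590, 2610), 2600)
        return FlankAssignment(exon=exon, peak=peak, side="DS", d=500)

    def test_closest_length_wins(self):
        test_exon = internal("chr1", 2000, 2099, "+", "t")  # length 100
        c120 = internal("chr1", 8000, 8119, "+", "t")
        c90 = internal("chr1", 12000, 12089, "+", "t")
        pairs = pair_control_exons(
            [self.setup_assignment(test_exon)],
            {"t": [test_exon, c120, c90]},
        )
        assert pairs[0].control_exon == c90

    def test_tie_breaks_to_smaller_start(self):
        test_exon = internal("chr1", 2000, 2099, "+", "t")
        c_a = internal("chr1", 8000, 8109, "+", "t")   # length 110
        c_b = internal("chr1", 12000, 12089, "+", "t")  # length 90
        pairs = pair_control_exons(
            [self.setup_assignment(test_exon)],
            {"t": [test_exon, c_b, c_a]},
        )
        assert pairs[0].control_exon == c_a

    def test_no_candidate_drops_exon(self):
        test_exon = internal("chr1", 2000, 2099, "+", "t")
        assert pair_control_exons(
            [self.setup_assignment(test_exon)], {"t": [test_exon]}
        ) == []

    def test_distance_preserved_on_control_side(self):
        test_exon = internal("chr1", 2000, 2099, "+", "t")
        control = internal("chr1", 12000, 12089, "+", "t")
        (pair,) = pair_control_exons(
            [self.setup_assignment(test_exon)], {"t": [test_exon, control]}
        )
        assert pair.control_position.position == control.ss5 + 500

    def test_distance_preserved_exactly_for_all_pairs(self, annotation_fixture):
        exons = annotation_fixture.internal_exons
        assignments = assign_flanking_peaks(annotation_fixture.peaks, exons)
        tx_map = defaultdict(list)
        for e in exons:
            tx_map[e.transcript_id].append(e)
        for pair in pair_control_exons(assignments, tx_map):
            side = pair.assignment.side
            ce = pair.control_exon
            ss = ce.ss5 if side == "DS" else ce.ss3
            assert abs(pair.control_position.position - ss) == pair.assignment.d


class TestMatchControlsByWilcoxon:
    def attributes(self, n, rng, shift=0.0):
        return {
            "ss_score": rng.normal(8 + shift, 2, n),
            "length": rng.integers(80, 300, n).astype(float),
            "gc_up": rng.uniform(0.3, 0.6, n),
            "gc_body": rng.uniform(0.4, 0.7, n),
            "gc_down": rng.uniform(0.3, 0.6, n),
        }

    def test_pool_equal_to_test_accepts_immediately(self, rng):
        attrs = self.attributes(30, rng)
        counts = rng.integers(0, 10, size=(30, 12)).astype(float)
        profile, diag = match_controls_by_wilcoxon(
            attrs, attrs, profile_source=lambda idx: counts[idx].sum(axis=0),
            p_cutoff=0.5, max_iterations=5, seed=0,
        )
        assert diag["accepted"] == 5
        # a sample of the whole pool is the pool itself
        np.testing.assert_allclose(profile, counts.sum(axis=0))

    def test_median_equals_brute_force_median(self, rng):
        test_attrs = self.attributes(20, rng)
        pool_attrs = self.attributes(200, rng)
        counts = rng.integers(0, 10, size=(200, 8)).astype(float)
        collected = []

        def source(idx):
            row = counts[idx].sum(axis=0)
            collected.append(row)
            return row

        profile, diag = match_controls_by_wilcoxon(
            test_attrs, pool_attrs, profile_source=source,
            p_cutoff=0.3, max_iterations=5, seed=1,
        )
        assert diag["accepted"] == 5
        np.testing.assert_allclose(profile,
                                   np.median(np.vstack(collected), axis=0))

    def test_pool_trimmed_to_test_score_range(self, rng):
        test_attrs = self.attributes(10, rng)
        pool_attrs = self.attributes(100, rng, shift=50)  # all out of range
        with pytest.raises(ValueError, match="score range"):
            match_controls_by_wilcoxon(
                test_attrs, pool_attrs, profile_source=lambda i: np.zeros(3),
                seed=0,
            )

    def test_impossible_cutoff_errors(self, rng):
        test_attrs = self.attributes(15, rng)
        pool_attrs = self.attributes(60, rng, shift=3.5)
        with pytest.raises(RuntimeError, match="rank-sum"):
            match_controls_by_wilcoxon(
                test_attrs, pool_attrs, profile_source=lambda i: np.zeros(3),
                p_cutoff=0.999999, max_iterations=3, seed=0, max_attempts=50,
            )


def make_pair(test_chrom_pos, control_chrom_pos, tid="t", side="DS", d=100):
    exon = internal("chr1", 2000, 2099, "+", tid)
    control_exon = internal("chr1", 50000, 50099, "+", tid)
    peak = CenteredPeak(
        GenomicInterval(test_chrom_pos[0],
                        max(1, test_chrom_pos[1] - 10), test_chrom_pos[1] + 10),
        test_chrom_pos[1],
    )
    assignment = FlankAssignment(exon=exon, peak=peak, side=side, d=d)
    control_position = ReferencePoint(
        f"ctrl{test_chrom_pos[1]}_{control_chrom_pos[1]}",
        control_chrom_pos[0], control_chrom_pos[1], "+",
    )
    return ControlPair(assignment=assignment, control_exon=control_exon,
                       control_position=control_position)


class TestMatchTssDistance:
    TSS = [("chr1", 100000)]

    def pair_with_distances(self, dt, dc):
        return make_pair(("chr1", 100000 - dt), ("chr1", 100000 + dc))

    def test_large_discrepancy_removed_in_phase_one(self):
        pairs = [self.pair_with_distances(14000, 2000),
                 self.pair_with_distances(3000, 3100)]
        kept, _ = match_tss_distance(pairs, self.TSS)
        assert kept == [pairs[1]]

    def test_too_close_to_tss_removed(self):
        pairs = [self.pair_with_distances(900, 2000),
                 self.pair_with_distances(3000, 3100)]
        kept, _ = match_tss_distance(pairs, self.TSS)
        assert kept == [pairs[1]]

    def test_no_phase_two_removal_below_target(self):
        # discrepancies +900, -300, +100: total 700 < 800
        pairs = [self.pair_with_distances(3000, 2100),
                 self.pair_with_distances(2000, 2300),
                 self.pair_with_distances(2200, 2100)]
        kept, _ = match_tss_distance(pairs, self.TSS)
        assert len(kept) == 3

    def test_greedy_removal_of_largest_discrepancy(self):
        # discrepancies +900, +300: total 1200 -> drop the 900 pair
        pairs = [self.pair_with_distances(3000, 2100),
                 self.pair_with_distances(2500, 2200)]
        kept, _ = match_tss_distance(pairs, self.TSS)
        assert kept == [pairs[1]]

    def test_all_pairs_removed_flagged_empty(self):
        pairs = [self.pair_with_distances(900, 950)]
        kept, p = match_tss_distance(pairs, self.TSS)
        assert kept == [] and p is None


class TestChiapetTables:
    def peak_at(self, center, chrom="chr1"):
        return CenteredPeak(GenomicInterval(chrom, center - 5, center + 5),
                            center)

    def interaction(self, lo1, hi1, lo2, hi2, rep="r1"):
        return InteractionPair(GenomicInterval("chr1", lo1, hi1),
                               GenomicInterval("chr1", lo2, hi2), rep)

    def assignment_for(self, pk):
        exon = internal("chr1", pk.center - 500, pk.center - 400, "+")
        return FlankAssignment(exon=exon, peak=pk, side="DS",
                               d=pk.center - (pk.center - 400))

    def test_counts_partition_rows(self):
        flank_peaks = [self.peak_at(1000 * i) for i in range(1, 11)]
        other_peaks = [self.peak_at(100000 + 1000 * i) for i in range(90)]
        # interactions covering 4 flank peaks and 9 others
        interactions = [
            [self.interaction(p.center - 2, p.center + 2, 500000, 500100)
             for p in flank_peaks[:4] + other_peaks[:9]]
        ]
        table = chiapet_tables(
            flank_peaks + other_peaks, interactions,
            [self.assignment_for(p) for p in flank_peaks],
            min_interactions_per_replicate=1,
        )
        assert (table.n11, table.n12, table.n21, table.n22) == (4, 6, 9, 81)
        assert table.n11 + table.n12 == 10
        assert table.n21 + table.n22 == 90

    def test_no_interactions_gives_empty_first_column(self):
        peaks = [self.peak_at(1000), self.peak_at(5000)]
        table = chiapet_tables(peaks, [[]], [],
                               min_interactions_per_replicate=0)
        assert table.n11 == 0 and table.n21 == 0

    def test_small_replicates_dropped(self):
        peaks = [self.peak_at(1000)]
        small_rep = [self.interaction(998, 1002, 99000, 99100)]
        table = chiapet_tables(peaks, [small_rep], [],
                               min_interactions_per_replicate=10000)
        # replicate dropped -> no retained replicate -> nothing overlaps
        assert table.n21 == 0 and table.n22 == 1

    def test_overlap_required_in_every_replicate(self):
        pk = self.peak_at(1000)
        rep1 = [self.interaction(998, 1002, 99000, 99100, "r1")]
        rep2 = [self.interaction(50000, 50100, 99000, 99100, "r2")]
        table = chiapet_tables([pk], [rep1, rep2], [],
                               min_interactions_per_replicate=1)
        assert table.n21 == 0 and table.n22 == 1
        both = chiapet_tables([pk], [rep1, rep1], [],
                              min_interactions_per_replicate=1)
        assert both.n21 == 1

    def test_tss_kind_splits_on_other_half(self):
        pk_near = self.peak_at(1000)
        pk_far = self.peak_at(5000)
        interactions = [[
            self.interaction(998, 1002, 200000, 200100),   # near a TSS
            self.interaction(4998, 5002, 300000, 300100),  # far from TSS
        ]]
        table = chiapet_tables(
            [pk_near, pk_far], interactions, [],
            tss=[("chr1", 200050)], table_kind="tss",
            min_interactions_per_replicate=1,
        )
        assert (table.n21, table.n22) == (1, 1)

    def test_empty_peak_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            chiapet_tables([], [[]], [])


def test_gc_content_basic():
    assert gc_content("GGCC") == 1.0
    assert gc_content("ATAT") == 0.0
    assert gc_content("ACGT") == 0.5
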