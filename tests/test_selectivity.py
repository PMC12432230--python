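import random

import numpy as np
import pytest

from l1select.io_formats import GenomicInterval, RepeatAnnotation
from l1select.selectivity import (
    NON_LINE1,
    OTHER_LINE1,
    assign_interval,
    build_annotation_tracks,
    complement_intervals,
    copy_number,
    merge_intervals,
    selectivity_report,
)

LINEAGE = ["L1HS", "L1PA2", "L1PA3"]


def ann(chrom, start, end, name, strand="+"):
    return RepeatAnnotation(
        GenomicInterval(chrom, start, end, strand=strand, name=name),
        name,
        "LINE",
        "L1",
    )


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand=strand)


class TestAssignInterval:
    def test_fully_inside(self):
        anns = [ann("chr1", 100, 6000, "L1HS")]
        assert assign_interval(iv("chr1", 200, 350), anns, LINEAGE) == "L1HS"

    def test_majority_overlap_wins(self):
        anns = [ann("chr1", 0, 220, "L1HS"), ann("chr1", 220, 400, "L1PA2")]
        # overlaps L1HS by 120 bp and L1PA2 by 30 bp
        assert assign_interval(iv("chr1", 100, 250), anns, LINEAGE) == "L1HS"

    def test_no_overlap_is_non_line1(self):
        anns = [ann("chr1", 0, 100, "L1HS")]
        assert assign_interval(iv("chr1", 5000, 5100), anns, LINEAGE) == NON_LINE1

    def test_line1_outside_lineage_is_other_line1(self):
        anns = [ann("chr1", 0, 500, "L1PA17")]
        assert assign_interval(iv("chr1", 100, 200), anns, LINEAGE) == OTHER_LINE1

    def test_non_line1_repeat_maps_to_non_line1(self):
        alu = RepeatAnnotation(
            GenomicInterval("chr1", 0, 300, name="AluY"), "AluY", "SINE", "Alu"
        )
        assert assign_interval(iv("chr1", 100, 200), [alu], LINEAGE) == NON_LINE1

    def test_tie_broken_by_longer_annotation_then_name(self):
        a = ann("chr1", 0, 200, "L1PA2")
        b = ann("chr1", 100, 400, "L1PA3")  # same 100 bp overlap, longer copy
        assert assign_interval(iv("chr1", 100, 200), [a, b], LINEAGE) == "L1PA3"
        c = ann("chr1", 100, 400, "L1PA2")
        d = ann("chr1", 100, 400, "L1PA3")  # full tie -> lexicographic
        assert assign_interval(iv("chr1", 150, 250), [c, d], LINEAGE) == "L1PA2"

    def test_order_invariance(self):
        rng = random.Random(3)
        anns = [
            ann("chr1", s, s + ln, name)
            for s, ln, name in [
                (0, 150, "L1HS"),
                (100, 150, "L1PA2"),
                (120, 300, "L1PA3"),
                (200, 100, "L1PA17"),
            ]
        ]
        probe = iv("chr1", 90, 260)
        ref = assign_interval(probe, anns, LINEAGE)
        for _ in range(10):
            rng.shuffle(anns)
            assert assign_interval(probe, anns, LINEAGE) == ref

    def test_strand_matched_restricts_candidates(self):
        anns = [ann("chr1", 0, 500, "L1HS", strand="-")]
        frag = iv("chr1", 100, 200, strand="+")
        assert assign_interval(frag, anns, LINEAGE, strand_matched=True) == NON_LINE1
        assert assign_interval(frag, anns, LINEAGE, strand_matched=False) == "L1HS"


class TestSelectivityReport:
    def test_direct_count_example(self):
        anns = [
            ann("chr1", 0, 1000, "L1HS"),
            ann("chr1", 2000, 3000, "L1PA2"),
        ]
        amps = (
            [iv("chr1", 10 + i, 150 + i) for i in range(7)]
            + [iv("chr1", 2100, 2250), iv("chr1", 2300, 2450)]
            + [iv("chr1", 9000, 9150)]
        )
        rep = selectivity_report(amps, anns, LINEAGE)
        assert rep.total == 10
        assert rep.per_category["L1HS"] == (7, 70.0)
        assert rep.per_category["L1PA2"] == (2, 20.0)
        assert rep.per_category[NON_LINE1] == (1, 10.0)
        assert rep.top2_share == 90.0

    def test_single_category_is_100(self):
        anns = [ann("chr1", 0, 1000, "L1HS")]
        amps = [iv("chr1", 10, 150)] * 4
        rep = selectivity_report(amps, anns, LINEAGE)
        assert rep.per_category["L1HS"] == (4, 100.0)

    def test_zero_amplicons_gives_empty_report(self):
        rep = selectivity_report([], [ann("chr1", 0, 100, "L1HS")], LINEAGE)
        assert rep.total == 0 and rep.top2_share == 0.0

    def test_counts_conserve_and_percents_sum(self, rng):
        anns = [ann("chr1", i * 1000, i * 1000 + 600, n) for i, n in enumerate(LINEAGE)]
        amps = [
            iv("chr1", int(s), int(s) + 120)
            for s in rng.integers(0, 4000, size=57)
        ]
        rep = selectivity_report(amps, anns, LINEAGE)
        assert sum(c for c, _ in rep.per_category.values()) == 57
        assert abs(sum(p for _, p in rep.per_category.values()) - 100.0) <= 0.1


class TestTracks:
    SIZES = {"chr1": 50_000}

    def test_full_length_rule(self):
        anns = [ann("chr1", 0, 6500, "L1HS"), ann("chr1", 10_000, 10_300, "L1PA2")]
        tracks = build_annotation_tracks(anns, self.SIZES)
        assert [(t.start, t.end) for t in tracks.full_length] == [(0, 6500)]

    def test_partition_of_genome(self):
        anns = [ann("chr1", 100, 6500, "L1HS"), ann("chr1", 6000, 9000, "L1PA2")]
        tracks = build_annotation_tracks(anns, self.SIZES)
        covered = sum(t.length for t in tracks.all_line1) + sum(
            t.length for t in tracks.non_line1
        )
        assert covered == self.SIZES["chr1"]

    def test_empty_intact_set(self):
        anns = [ann("chr1", 0, 6500, "L1HS")]
        tracks = build_annotation_tracks(anns, self.SIZES, intact_loci=())
        assert tracks.full_length_intact == ()

    def test_intact_subset(self):
        anns = [ann("chr1", 0, 6500, "L1HS"), ann("chr1", 10_000, 17_000, "L1PA2")]
        tracks = build_annotation_tracks(
            anns, self.SIZES, intact_loci=[iv("chr1", 10_500, 11_000)]
        )
        assert [(t.start, t.end) for t in tracks.full_length_intact] == [(10_000, 17_000)]

    def test_unknown_chrom_rejected(self):
        with pytest.raises(ValueError, match="chrom_sizes"):
            build_annotation_tracks([ann("chrZ", 0, 100, "L1HS")], self.SIZES)

    def test_random_sets_satisfy_track_algebra(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 15))
            anns = []
            for _i in range(n):
                start = int(rng.integers(0, 40_000))
                length = int(rng.integers(50, 9000))
                anns.append(ann("chr1", start, start + length, "L1HS"))
            tracks = build_annotation_tracks(anns, self.SIZES)
            fl = set(tracks.full_length)
            fli = set(tracks.full_length_intact)
            assert fli <= fl
            merged = merge_intervals([t for t in fl])
            for m in merged:
                assert any(
                    a.start <= m.start and m.end <= a.end for a in tracks.all_line1
                )
            total = sum(t.length for t in tracks.all_line1) + sum(
                t.length for t in tracks.non_line1
            )
            assert total == 50_000
            for a in tracks.all_line1:
                assert all(a.overlap(b) == 0 for b in tracks.non_line1)


class TestCopyNumber:
    def test_counts(self):
        anns = [ann("chr1", i * 100, i * 100 + 60, "L1HS") for i in range(3)]
        anns.append(ann("chr1", 900, 950, "L1PA2"))
        assert copy_number(anns, "L1HS") == 3
        assert copy_number(anns, "L1HS", min_len=100) == 0
        assert copy_number(anns, "L1PA9") == 0

    def test_simulated_counts_match_parameters(self, tiny_params, tiny_genome, tiny_lineage):
        _, anns, _ = tiny_genome
        for name in tiny_lineage.names:
            assert copy_number(anns, name) == tiny_params.copies_per_subfamily


def test_complement_covers_unannotated_chroms():
    out = complement_intervals([iv("chr1", 10, 20)], {"chr1": 30, "chr2": 15})
    assert out == [iv("chr1", 0, 10), iv("chr1", 20, 30), iv("chr2", 0, 15)]
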