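import itertools

import numpy as np
import pytest

from l1select.diagnostics import (
    Alignment,
    ConsensusSet,
    accept_external_msa,
    diagnose,
    enumerate_candidate_regions,
    find_discriminating_columns,
    progressive_align,
)
from l1select.io_formats import FormatError


def brute_force_best_score(a, b, match=1, mismatch=-1, gap=-2):
    """Optimal global alignment score by exhaustive recursion over all
    monotone alignment paths (independent of any DP implementation)."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = -1e9
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def pairwise_alignment_score(alignment, match=1, mismatch=-1, gap=-2):
    (_, r1), (_, r2) = alignment.rows
    score = 0
    for x, y in zip(r1, r2):
        if x == "-" or y == "-":
            score += gap
        else:
            score += match if x == y else mismatch
    return score


class TestProgressiveAlign:
    def test_identical_pair_has_no_gaps(self):
        cs = ConsensusSet([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        aln = progressive_align(cs)
        assert aln.n_columns == 8
        assert "-" not in aln.row("a") + aln.row("b")

    def test_single_deletion(self):
        cs = ConsensusSet([("a", "ACGT"), ("b", "ACT")])
        aln = progressive_align(cs)
        assert aln.n_columns == 4
        assert aln.degapped("a") == "ACGT" and aln.degapped("b") == "ACT"

    def test_degapping_recovers_all_inputs(self, rng):
        seqs = {}
        base = "".join(rng.choice(list("ACGT"), 60))
        seqs["s1"] = base
        for k in range(2, 5):
            # random substitutions plus a deletion or insertion
            s = list(base)
            for i in rng.choice(60, 5, replace=False):
                s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
            cut = int(rng.integers(0, 50))
            s = s[:cut] + s[cut + int(rng.integers(0, 4)) :]
            seqs[f"s{k}"] = "".join(s)
        aln = progressive_align(ConsensusSet(seqs.items()))
        for name, seq in seqs.items():
            assert aln.degapped(name) == seq

    @pytest.mark.parametrize("trial", range(10))
    def test_pairwise_score_is_optimal_on_short_pairs(self, trial):
        rng = np.random.default_rng(100 + trial)
        a = "".join(rng.choice(list("ACGT"), int(rng.integers(3, 9))))
        b = "".join(rng.choice(list("ACGT"), int(rng.integers(3, 9))))
        aln = progressive_align(ConsensusSet([("a", a), ("b", b)]))
        assert pairwise_alignment_score(aln) == brute_force_best_score(a, b)

    def test_deterministic(self):
        cs = ConsensusSet([("a", "ACGTTGCA"), ("b", "AGTTGA"), ("c", "ACGTGCA")])
        assert progressive_align(cs).rows == progressive_align(cs).rows


class TestAcceptExternalMsa:
    def test_aligned_fasta_roundtrip(self, tmp_path):
        path = tmp_path / "m.fa"
        path.write_text(">a\nAC-T\n>b\nACGT\n")
        aln = accept_external_msa(str(path))
        assert aln.n_columns == 4 and aln.degapped("a") == "ACT"

    def test_ragged_rejected(self, tmp_path):
        path = tmp_path / "m.fa"
        path.write_text(">a\nAC-T\n>b\nACGTT\n")
        with pytest.raises(FormatError, match="ragged"):
            accept_external_msa(str(path))

    def test_roundtrip_with_progressive_output(self, tmp_path):
        cs = ConsensusSet([("a", "ACGTTGCA"), ("b", "AGTTGA")])
        aln = progressive_align(cs)
        path = tmp_path / "m.fa"
        path.write_text("".join(f">{n}\n{s}\n" for n, s in aln.rows))
        assert accept_external_msa(str(path)) == aln


class TestFindDiscriminatingColumns:
    def test_hand_checked_example(self):
        aln = Alignment((("S1", "ACGT"), ("S2", "ACAT"), ("S3", "ACAT")))
        cols = find_discriminating_columns(aln, "S1")
        assert len(cols) == 1
        col = cols[0]
        assert col.column_index == 2
        assert col.residues == {"S1": "G", "S2": "A", "S3": "A"}
        assert col.target_consensus_pos["S1"] == 2
        assert "S1" in col.discriminates

    def test_identical_rows_give_nothing(self):
        aln = Alignment((("a", "ACGT"), ("b", "ACGT")))
        assert find_discriminating_columns(aln, "a") == []

    def test_target_gap_never_discriminates(self):
        aln = Alignment((("a", "A-GT"), ("b", "ACGT"), ("c", "ATGT")))
        cols = find_discriminating_columns(aln, "a")
        assert [c.column_index for c in cols] == []

    def test_nontarget_gap_counts_as_different(self):
        aln = Alignment((("a", "ACGT"), ("b", "A-GT"), ("c", "A-GT")))
        cols = find_discriminating_columns(aln, "a")
        assert [c.column_index for c in cols] == [1]
        # ungapped coordinate on the target is carried along
        assert cols[0].target_consensus_pos["a"] == 1

    def test_unknown_target_rejected(self):
        aln = Alignment((("a", "AC"), ("b", "AC")))
        with pytest.raises(KeyError):
            find_discriminating_columns(aln, "zz")

    def test_comparison_subset_matches_manual_restriction(self):
        aln = Alignment((("a", "AAAA"), ("b", "ACAA"), ("c", "AAGA")))
        # vs both: column 1 (A vs C vs A -> a not unique: a==c) -> no columns
        assert find_discriminating_columns(aln, "a") == []
        # vs b only: column 1 discriminates
        cols = find_discriminating_columns(aln, "a", comparison=["b"])
        assert [c.column_index for c in cols] == [1]

    def test_adding_a_subfamily_never_adds_columns(self, rng):
        def random_alignment(names):
            base = rng.choice(list("ACGT"), 40)
            rows = []
            for name in names:
                row = base.copy()
                for i in rng.choice(40, 6, replace=False):
                    row[i] = rng.choice(list("ACGT"))
                rows.append((name, "".join(row)))
            return rows

        rows = random_alignment(["t", "u", "v", "w"])
        small = Alignment(tuple(rows[:3]))
        big = Alignment(tuple(rows))
        cols_small = {c.column_index for c in find_discriminating_columns(small, "t")}
        cols_big = {c.column_index for c in find_discriminating_columns(big, "t")}
        assert cols_big <= cols_small


class TestEnumerateCandidateRegions:
    def test_two_positions_within_reach(self):
        regions = enumerate_candidate_regions([10, 150], footprint_len_range=(20, 22))
        assert regions, "expected at least one region spanning both positions"
        for r in regions:
            assert r.length <= 200
            assert any(r.left_footprint[0] <= d < r.left_footprint[1] for d in r.left_diag)
            assert any(r.right_footprint[0] <= d < r.right_footprint[1] for d in r.right_diag)

    def test_positions_too_far_apart(self):
        assert enumerate_candidate_regions([10, 400]) == []

    def test_single_position_gives_nothing(self):
        assert enumerate_candidate_regions([10]) == []

    def test_positions_too_close_for_two_footprints(self):
        assert enumerate_candidate_regions([10, 20], footprint_len_range=(18, 22)) == []

    def test_exhaustive_small_instance(self):
        # positions {0, 40, 80}, footprints >= 18: viable pairs are exactly
        # those with q - p >= 35 and span <= max: (0,40), (0,80), (40,80)
        regions = enumerate_candidate_regions([0, 40, 80], max_region_len=100)
        spans = sorted(r.region for r in regions)
        assert spans == [(0, 41), (0, 81), (40, 81)]

    def test_sorted_and_deduplicated(self):
        regions = enumerate_candidate_regions([5, 60, 61, 120])
        keys = [(r.region, r.left_footprint, r.right_footprint) for r in regions]
        assert keys == sorted(set(keys))


class TestDiagnoseOnSimulatedLineage:
    def test_columns_match_planted_substitution_history(self, tiny_lineage):
        # substitutions only -> alignment is gapless and diagnostic columns
        # are exactly the positions where the target differs from everyone
        target = tiny_lineage.names[0]
        cols, _ = diagnose(tiny_lineage, target)
        seqs = dict(tiny_lineage.items())
        expected = {
            i
            for i in range(len(seqs[target]))
            if all(
                seqs[target][i] != seqs[n][i] for n in tiny_lineage.names if n != target
            )
        }
        got = {c.target_consensus_pos[target] for c in cols}
        assert got == expected
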