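import numpy as np
import pytest

from l1select.insilico_pcr import (
    brute_force_pcr_oracle,
    find_binding_sites,
    predict_amplicons,
)
from l1select.io_formats import SequenceRecord
from l1select.primer_design import pair_from_sequences, reverse_complement


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def mutate_at(seq, pos):
    other = {"A": "C", "C": "G", "G": "T", "T": "A"}
    return seq[:pos] + other[seq[pos]] + seq[pos + 1 :]


PRIMER = "GACATCTACACCGAAAACCC"  # 20-mer


class TestFindBindingSites:
    def embed(self, rng, insert, at=4000, n=10_000):
        g = random_dna(rng, n)
        return g[:at] + insert + g[at + len(insert) :]

    def test_exact_forward_site(self, rng):
        g = self.embed(rng, PRIMER)
        sites = find_binding_sites(g, PRIMER, max_mismatch=0)
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].interval.start, plus[0].mismatches) == (4000, 0)

    def test_mismatch_outside_anchor_found_inside_anchor_not(self, rng):
        # one substitution 8 nt from the 3' end: tolerated at max_mismatch=1
        away = mutate_at(PRIMER, len(PRIMER) - 8)
        g = self.embed(rng, away)
        sites = find_binding_sites(g, PRIMER, max_mismatch=1, anchor_len=5)
        assert any(s.interval.start == 4000 and s.mismatches == 1 for s in sites)
        # the same substitution within the 3' anchor: rejected
        inside = mutate_at(PRIMER, len(PRIMER) - 2)
        g2 = self.embed(rng, inside)
        sites2 = find_binding_sites(g2, PRIMER, max_mismatch=1, anchor_len=5)
        assert not any(s.interval.start == 4000 for s in sites2)

    def test_reverse_complement_gives_minus_site(self, rng):
        g = self.embed(rng, reverse_complement(PRIMER))
        sites = find_binding_sites(g, PRIMER, max_mismatch=0)
        minus = [s for s in sites if s.strand == "-"]
        assert len(minus) == 1 and minus[0].interval.start == 4000

    def test_primer_not_longer_than_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            find_binding_sites("ACGT" * 100, "ACGTA", anchor_len=5)

    def test_n_in_genome_never_matches(self, rng):
        g = self.embed(rng, PRIMER[:-1] + "N")
        sites = find_binding_sites(g, PRIMER, max_mismatch=2, anchor_len=5)
        assert not any(s.interval.start == 4000 and s.strand == "+" for s in sites)

    def test_sites_sorted(self, rng):
        g = self.embed(rng, PRIMER, at=8000)
        g = g[:1000] + PRIMER + g[1000 + len(PRIMER):]
        sites = find_binding_sites(g, PRIMER, max_mismatch=2)
        keys = [(s.interval.chrom, s.interval.start, s.strand) for s in sites]
        assert keys == sorted(keys)


class TestPredictAmplicons:
    PAIR = pair_from_sequences(
        "GACATCTACACCGAAAACCC", "TCGTCAAAATCATTCTCCATCC", name="Primer1"
    )

    def test_constructed_template_product_length(self, rng):
        spacer = random_dna(rng, 110)
        template = (
            self.PAIR.forward.seq + spacer + reverse_complement(self.PAIR.reverse.seq)
        )
        genome = SequenceRecord("chrT", random_dna(rng, 300) + template + random_dna(rng, 300))
        amps = predict_amplicons(genome, self.PAIR)
        assert len(amps) == 1
        assert amps[0].product_len == 152  # 20 + 110 + 22
        assert amps[0].seq.startswith(self.PAIR.forward.seq)
        assert amps[0].seq.endswith(reverse_complement(self.PAIR.reverse.seq))

    def test_forward_site_alone_yields_nothing(self, rng):
        genome = random_dna(rng, 500) + self.PAIR.forward.seq + random_dna(rng, 500)
        assert predict_amplicons(genome, self.PAIR, max_mismatch=0) == []

    def test_product_beyond_max_product_dropped(self, rng):
        spacer = random_dna(rng, 2000)
        genome = (
            self.PAIR.forward.seq + spacer + reverse_complement(self.PAIR.reverse.seq)
        )
        assert predict_amplicons(genome, self.PAIR, max_product=1000, max_mismatch=0) == []

    def test_reverse_orientation_template_detected(self, rng):
        spacer = random_dna(rng, 110)
        template = (
            self.PAIR.forward.seq + spacer + reverse_complement(self.PAIR.reverse.seq)
        )
        genome = random_dna(rng, 200) + reverse_complement(template) + random_dna(rng, 200)
        amps = predict_amplicons(genome, self.PAIR)
        assert len(amps) == 1 and amps[0].product_len == 152

    def test_strand_symmetry(self, rng):
        g = random_dna(rng, 3000)
        spacer = random_dna(rng, 90)
        template = (
            self.PAIR.forward.seq + spacer + reverse_complement(self.PAIR.reverse.seq)
        )
        g = g[:1500] + template + g[1500:]
        amps = predict_amplicons(g, self.PAIR)
        mirror = predict_amplicons(reverse_complement(g), self.PAIR)
        n = len(g)
        got = sorted((n - a.interval.end, n - a.interval.start) for a in mirror)
        want = sorted((a.interval.start, a.interval.end) for a in amps)
        assert got == want


def plant_cases(rng, genome, pair, max_mismatch, anchor_len):
    """Plant primer sites with mismatch counts straddling the thresholds."""
    g = list(genome)
    flen, rlen = len(pair.forward.seq), len(pair.reverse.seq)
    slots = rng.choice(len(genome) - 400, size=6, replace=False)
    for k, at in enumerate(sorted(slots)):
        n_mut = int(rng.integers(0, max_mismatch + 2))
        f = pair.forward.seq
        r = reverse_complement(pair.reverse.seq)
        for _ in range(n_mut):
            pos = int(rng.integers(0, flen))  # may fall inside the anchor
            f = mutate_at(f, pos)
        spacer_len = int(rng.integers(20, 200))
        template = f + random_dna(rng, spacer_len) + r
        if k % 2:
            template = reverse_complement(template)
        g[at : at + len(template)] = template
    return "".join(g)


class TestOracleEquivalence:
    def as_key(self, amp):
        return (
            amp.interval.start,
            amp.interval.end,
            amp.f_site.strand,
            amp.f_site.mismatches,
            amp.r_site.mismatches,
            amp.product_len,
        )

    @pytest.mark.parametrize("case", range(30))
    def test_fast_path_equals_oracle(self, case):
        rng = np.random.default_rng(9000 + case)
        settings_grid = [(0, 3), (0, 5), (1, 3), (1, 5), (2, 3), (2, 5)]
        max_mismatch, anchor_len = settings_grid[case % 6]
        fseq = random_dna(rng, int(rng.integers(18, 25)))
        rseq = random_dna(rng, int(rng.integers(18, 25)))
        pair = pair_from_sequences(fseq, rseq)
        genome = plant_cases(
            rng, random_dna(rng, 10_000), pair, max_mismatch, anchor_len
        )
        fast = predict_amplicons(
            genome, pair, max_mismatch=max_mismatch, anchor_len=anchor_len
        )
        slow = brute_force_pcr_oracle(
            genome, pair, max_mismatch=max_mismatch, anchor_len=anchor_len
        )
        assert [self.as_key(a) for a in fast] == [self.as_key(a) for a in slow]
        for amp in fast:
            assert amp.seq == genome[amp.interval.start : amp.interval.end]

    def test_empty_genome(self):
        pair = pair_from_sequences(PRIMER, "TCGTCAAAATCATTCTCCATCC")
        assert brute_force_pcr_oracle("", pair) == []

    def test_duplicate_templates_give_two_amplicons(self, rng):
        pair = pair_from_sequences(PRIMER, "TCGTCAAAATCATTCTCCATCC")
        template = (
            pair.forward.seq + random_dna(rng, 80) + reverse_complement(pair.reverse.seq)
        )
        # copies far enough apart that the cross-copy product exceeds max_product
        genome = template + random_dna(rng, 1500) + template
        amps = brute_force_pcr_oracle(genome, pair, max_mismatch=0)
        assert len(amps) == 2
        assert predict_amplicons(genome, pair, max_mismatch=0)[0].product_len == amps[0].product_len

    def test_oracle_refuses_large_genome(self):
        pair = pair_from_sequences(PRIMER, "TCGTCAAAATCATTCTCCATCC")
        with pytest.raises(ValueError, match="100 kb"):
            brute_force_pcr_oracle("A" * 100_001, pair)
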