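"""Primer-pair construction from candidate regions.

Turns candidate regions (windows on a target consensus with subfamily-
discriminating bases near both ends) into concrete forward/reverse primer
pairs subject to length, %GC and melting-temperature constraints, ranked
deterministically. Also houses the sequence arithmetic (%GC, Tm, reverse
complement) used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .diagnostics import CandidateRegion
from .io_formats import PRIMER_ALPHABET, SequenceRecord, read_fasta

__all__ = [
    "Primer",
    "PrimerPair",
    "DesignConstraints",
    "gc_percent",
    "melting_temperature",
    "reverse_complement",
    "design_pairs",
    "load_reference_primers",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _check_primer_seq(seq: str) -> None:
    if not seq:
        raise ValueError("empty primer sequence")
    bad = set(seq) - PRIMER_ALPHABET
    if bad:
        raise ValueError(f"primer sequence contains non-ACGT characters: {sorted(bad)}")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 decimal rounds to 0.1)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_percent(seq: str) -> float:
    """Percent G+C of a primer, rounded half-up to one decimal.

    100*(#G + #C)/length; N is rejected (primers must be fully specified).
    """
    _check_primer_seq(seq)
    gc = seq.count("G") + seq.count("C")
    return round_half_up(100.0 * gc / len(seq), 1)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    bad = set(seq.upper()) - frozenset("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def melting_temperature(
    seq: str,
    method: str = "wallace",
    na_mM: float = 50.0,
    primer_nM: float = 500.0,
) -> float:
    """Primer melting temperature in degrees Celsius.

    ``wallace``: the 2-4 rule, 2*(#A+#T) + 4*(#G+#C) — the quick rule of
    thumb for short oligos. ``nn_santalucia``: nearest-neighbour dH/dS with
    the SantaLucia & Hicks unified parameter set at the stated monovalent
    salt (default 50 mM Na+) and primer concentration (default 500 nM).
    Commercial design tools use proprietary variants, so absolute values
    differ between tools; both methods here are standard and documented.
    """
    _check_primer_seq(seq)
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return float(2 * at + 4 * gc)
    if method == "nn_santalucia":
        return float(
            _mt.Tm_NN(
                seq,
                nn_table=_mt.DNA_NN4,  # SantaLucia & Hicks 2004 unified
                Na=na_mM,
                dnac1=primer_nM,
                dnac2=0,
            )
        )
    raise ValueError(f"unknown Tm method {method!r}")


@dataclass(frozen=True)
class Primer:
    """A PCR primer written 5'->3'.

    ``footprint`` is the template region on the target consensus (0-based
    half-open); for a reverse primer the sequence is the reverse complement
    of that template region, so its 3' end sits at ``footprint[0]``.
    """

    name: str
    seq: str
    orientation: str  # "F" or "R"
    footprint: tuple[int, int]
    gc: float
    tm_c: float

    def __post_init__(self) -> None:
        _check_primer_seq(self.seq)
        if not 15 <= len(self.seq) <= 35:
            raise ValueError(f"primer length {len(self.seq)} outside [15, 35]")
        if self.orientation not in ("F", "R"):
            raise ValueError(f"orientation must be F or R, got {self.orientation!r}")
        if self.footprint[1] - self.footprint[0] != len(self.seq):
            raise ValueError("footprint length must equal primer length")
        if gc_percent(self.seq) != self.gc:
            raise ValueError("stored %GC does not match sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    target_subfamily: str

    def __post_init__(self) -> None:
        if self.forward.footprint[1] > self.reverse.footprint[0]:
            raise ValueError("forward footprint may touch but not overlap reverse")

    @property
    def expected_product_len(self) -> int:
        return self.reverse.footprint[1] - self.forward.footprint[0]


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable primer constraints; defaults follow common qPCR practice
    (18-22 nt, 35-60 %GC)."""

    len_range: tuple[int, int] = (18, 22)
    gc_range: tuple[float, float] = (35.0, 60.0)
    tm_method: str = "wallace"
    tm_range: Optional[tuple[float, float]] = None
    require_diag_in_3prime_k: Optional[int] = None
    min_diag_per_footprint: int = 1

    def __post_init__(self) -> None:
        if self.len_range[0] > self.len_range[1]:
            raise ValueError("empty primer length range")
        if self.gc_range[0] > self.gc_range[1]:
            raise ValueError("empty %GC range")
        if self.min_diag_per_footprint < 1:
            raise ValueError("min_diag_per_footprint must be >=1")


def _candidate_footprints(
    region_bounds: tuple[int, int],
    diag: Sequence[int],
    constraints: DesignConstraints,
    consensus_len: int,
):
    """All footprint placements inside the region covering >= min_diag
    discriminating positions, as (start, end) tuples."""
    lo, hi = region_bounds
    seen: set[tuple[int, int]] = set()
    diag_sorted = sorted(diag)
    for length in range(constraints.len_range[0], constraints.len_range[1] + 1):
        for d in diag_sorted:
            for start in range(max(lo, d - length + 1), min(d, hi - length) + 1):
                end = start + length
                if end > hi or end > consensus_len or start < 0:
                    continue
                fp = (start, end)
                if fp in seen:
                    continue
                covered = [x for x in diag_sorted if start <= x < end]
                if len(covered) >= constraints.min_diag_per_footprint:
                    seen.add(fp)
                    yield fp, covered


def design_pairs(
    region: CandidateRegion,
    target_consensus: str,
    constraints: DesignConstraints = DesignConstraints(),
    max_pairs: Optional[int] = None,
) -> list[PrimerPair]:
    """Enumerate and rank primer pairs for one candidate region.

    Forward primers are verbatim consensus substrings near the region's left
    end; reverse primers are reverse complements of substrings near the
    right end. Every emitted pair covers at least one discriminating
    position per footprint (``min_diag_per_footprint`` raises the bar;
    ``require_diag_in_3prime_k`` additionally demands a discriminating base
    within k nt of the primer's 3' terminus, the classic allele-specific
    placement). Ranking: smallest forward/reverse Tm difference, then
    combined %GC closeness to 50, then leftmost placement — deterministic.
    """
    rs, re_ = region.region
    if re_ > len(target_consensus):
        raise ValueError("region extends past consensus end")

    def primer_ok(seq: str) -> Optional[tuple[float, float]]:
        if "N" in seq:
            return None
        gc = gc_percent(seq)
        if not constraints.gc_range[0] <= gc <= constraints.gc_range[1]:
            return None
        tm = melting_temperature(seq, constraints.tm_method)
        if constraints.tm_range is not None and not (
            constraints.tm_range[0] <= tm <= constraints.tm_range[1]
        ):
            return None
        return gc, tm

    fwd: list[tuple[tuple[int, int], list[int], float, float]] = []
    for fp, covered in _candidate_footprints(
        (rs, re_), region.left_diag, constraints, len(target_consensus)
    ):
        seq = target_consensus[fp[0] : fp[1]]
        k = constraints.require_diag_in_3prime_k
        if k is not None and not any(fp[1] - k <= x < fp[1] for x in covered):
            continue  # forward 3' end is the footprint's right edge
        res = primer_ok(seq)
        if res is not None:
            fwd.append((fp, covered, *res))

    rev: list[tuple[tuple[int, int], list[int], float, float]] = []
    for fp, covered in _candidate_footprints(
        (rs, re_), region.right_diag, constraints, len(target_consensus)
    ):
        seq = reverse_complement(target_consensus[fp[0] : fp[1]])
        k = constraints.require_diag_in_3prime_k
        if k is not None and not any(fp[0] <= x < fp[0] + k for x in covered):
            continue  # reverse 3' end is the footprint's left edge
        res = primer_ok(seq)
        if res is not None:
            rev.append((fp, covered, *res))

    pairs: list[tuple[tuple, PrimerPair]] = []
    for ffp, _, fgc, ftm in fwd:
        for rfp, _, rgc, rtm in rev:
            if ffp[1] > rfp[0]:
                continue  # footprints must not overlap
            forward = Primer(
                name=f"{region.target_subfamily or 'target'}_F_{ffp[0]}",
                seq=target_consensus[ffp[0] : ffp[1]],
                orientation="F",
                footprint=ffp,
                gc=fgc,
                tm_c=ftm,
            )
            reverse = Primer(
                name=f"{region.target_subfamily or 'target'}_R_{rfp[0]}",
                seq=reverse_complement(target_consensus[rfp[0] : rfp[1]]),
                orientation="R",
                footprint=rfp,
                gc=rgc,
                tm_c=rtm,
            )
            pair = PrimerPair(forward, reverse, region.target_subfamily)
            key = (
                abs(ftm - rtm),
                abs(fgc - 50.0) + abs(rgc - 50.0),
                ffp[0],
                rfp[0],
            )
            pairs.append((key, pair))

    pairs.sort(key=lambda kp: kp[0])
    ranked = [p for _, p in pairs]
    return ranked[:max_pairs] if max_pairs is not None else ranked


def pair_from_sequences(
    forward_seq: str,
    reverse_seq: str,
    name: str = "pair",
    target_subfamily: str = "",
    tm_method: str = "wallace",
) -> PrimerPair:
    """Build a consistent PrimerPair from two raw 5'->3' sequences.

    Footprints are placed back-to-back at the origin (they matter for
    product-length bookkeeping on a consensus, not for genome scanning), so
    this is the convenient constructor when only the sequences are known —
    e.g. published primers to be run through in-silico PCR.
    """
    f_len, r_len = len(forward_seq), len(reverse_seq)
    forward = Primer(
        name=f"{name}_F",
        seq=forward_seq.upper(),
        orientation="F",
        footprint=(0, f_len),
        gc=gc_percent(forward_seq.upper()),
        tm_c=melting_temperature(forward_seq.upper(), tm_method),
    )
    reverse = Primer(
        name=f"{name}_R",
        seq=reverse_seq.upper(),
        orientation="R",
        footprint=(f_len, f_len + r_len),
        gc=gc_percent(reverse_seq.upper()),
        tm_c=melting_temperature(reverse_seq.upper(), tm_method),
    )
    return PrimerPair(forward, reverse, target_subfamily)


def load_reference_primers() -> list[SequenceRecord]:
    """The six published L1PA subfamily-selective primer pairs (12 oligos).

    Records are named ``Primer<i>_<F|R>``; descriptions are not preserved.
    """
    with resources.as_file(
        resources.files("l1select").joinpath("data/table1_primers.fa")
    ) as path:
        return read_fasta(path)
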