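"""Mismatch-tolerant, 3'-anchored in-silico PCR.

A primer binding site is a genomic window of primer length whose Hamming
distance to the primer (on the appropriate strand) is at most
``max_mismatch`` AND whose 3'-terminal ``anchor_len`` bases match exactly —
polymerase extension requires a matched 3' end, so mismatches there abolish
amplification. Indels are not modelled. Predicted amplicons pair a
plus-strand forward-primer site with a downstream minus-strand
reverse-primer site (and symmetrically with the primer roles swapped, since
a repeat copy can sit on either genomic strand) within a product-size
window.

The fast path seeds on an exact-match index of the 3' anchors and verifies
candidates in full; :func:`brute_force_pcr_oracle` re-derives the same
answer position by position with no indexing and guards correctness in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenomicInterval, SequenceRecord
from .primer_design import PrimerPair, reverse_complement

__all__ = [
    "BindingSite",
    "Amplicon",
    "find_binding_sites",
    "predict_amplicons",
    "brute_force_pcr_oracle",
]

_ENCODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
# N encodes to 4 and never equals a primer base (primers are ACGT only).


@dataclass(frozen=True)
class BindingSite:
    """One primer hybridization site on the genome.

    On the ``+`` strand the primer reads left-to-right and its 3' end is at
    ``interval.end``; on the ``-`` strand the primer matches the reverse
    complement of the window and its 3' end is at ``interval.start``.
    """

    interval: GenomicInterval
    strand: str
    mismatches: int
    primer_name: str


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, forward site start to reverse site end."""

    interval: GenomicInterval
    f_site: BindingSite
    r_site: BindingSite
    product_len: int
    seq: str

    def __post_init__(self) -> None:
        if self.product_len != self.interval.length:
            raise ValueError("product_len must equal interval length")


def _as_seq(genome) -> tuple[str, str]:
    if isinstance(genome, SequenceRecord):
        return genome.id, genome.seq
    return "genome", str(genome).upper()


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan(garr: np.ndarray, pattern: str, anchor_slice: slice, max_mismatch: int):
    """Start positions and mismatch counts of windows matching ``pattern``
    with an exact match over ``anchor_slice`` and <= max_mismatch overall."""
    L = len(pattern)
    n = garr.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    parr = _encode(pattern)
    anchor = parr[anchor_slice]
    a0 = anchor_slice.start or 0
    # exact anchor match first (cheap), then full verification of survivors
    cand = np.flatnonzero(garr[a0 : a0 + n] == anchor[0])
    for j in range(1, anchor.size):
        if cand.size == 0:
            break
        cand = cand[garr[cand + a0 + j] == anchor[j]]
    if cand.size == 0:
        return cand, cand
    windows = garr[cand[:, None] + np.arange(L)]
    mm = (windows != parr).sum(axis=1)
    keep = mm <= max_mismatch
    return cand[keep], mm[keep]


def find_binding_sites(
    genome,
    primer,
    max_mismatch: int = 2,
    anchor_len: int = 5,
    primer_name: str | None = None,
) -> list[BindingSite]:
    """All binding sites of one primer on both strands of a genome.

    ``genome`` is a :class:`SequenceRecord` or plain string; ``primer`` a
    :class:`~l1select.primer_design.Primer` or plain 5'->3' sequence. N in
    the genome never matches. Output is sorted by (chrom, start, strand).
    """
    chrom, gseq = _as_seq(genome)
    pseq = primer.seq if hasattr(primer, "seq") else str(primer).upper()
    name = primer_name or (primer.name if hasattr(primer, "name") else "primer")
    if anchor_len < 1:
        raise ValueError("anchor_len must be >=1")
    if len(pseq) <= anchor_len:
        raise ValueError(
            f"primer length {len(pseq)} must exceed anchor_len {anchor_len}"
        )
    garr = _encode(gseq)
    L = len(pseq)
    sites: list[BindingSite] = []
    # + strand: genome window == primer; 3' anchor = last anchor_len bases
    pos, mm = _scan(garr, pseq, slice(L - anchor_len, L), max_mismatch)
    for p, m in zip(pos, mm):
        sites.append(
            BindingSite(
                GenomicInterval(chrom, int(p), int(p) + L, strand="+", name=name),
                "+",
                int(m),
                name,
            )
        )
    # - strand: window == revcomp(primer); primer 3' end maps to window start
    rc = reverse_complement(pseq)
    pos, mm = _scan(garr, rc, slice(0, anchor_len), max_mismatch)
    for p, m in zip(pos, mm):
        sites.append(
            BindingSite(
                GenomicInterval(chrom, int(p), int(p) + L, strand="-", name=name),
                "-",
                int(m),
                name,
            )
        )
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.strand))
    return sites


def _pair_sites(
    chrom: str,
    gseq: str,
    plus_sites: list[BindingSite],
    minus_sites: list[BindingSite],
    min_product: int,
    max_product: int,
) -> list[Amplicon]:
    out: list[Amplicon] = []
    minus_sorted = sorted(minus_sites, key=lambda s: s.interval.start)
    starts = np.array([s.interval.start for s in minus_sorted], dtype=np.intp)
    for f in plus_sites:
        lo = np.searchsorted(starts, f.interval.end, side="left")
        for r in minus_sorted[lo:]:
            product = r.interval.end - f.interval.start
            if product > max_product:
                break
            if product < min_product:
                continue
            interval = GenomicInterval(chrom, f.interval.start, r.interval.end)
            out.append(
                Amplicon(
                    interval=interval,
                    f_site=f,
                    r_site=r,
                    product_len=product,
                    seq=gseq[interval.start : interval.end],
                )
            )
    return out


def predict_amplicons(
    genome,
    pair: PrimerPair,
    max_product: int = 1000,
    min_product: int = 40,
    max_mismatch: int = 2,
    anchor_len: int = 5,
) -> list[Amplicon]:
    """Predicted PCR products of a primer pair on a genome.

    Forward-orientation products pair a forward-primer ``+`` site with a
    downstream reverse-primer ``-`` site; reverse-orientation products (the
    template copy on the minus strand) pair a reverse-primer ``+`` site with
    a downstream forward-primer ``-`` site. Primer sites must not overlap
    (product spans both primers entirely). Duplicate intervals are removed;
    output is sorted by (chrom, start, end).
    """
    chrom, gseq = _as_seq(genome)
    f_sites = find_binding_sites(genome, pair.forward, max_mismatch, anchor_len)
    r_sites = find_binding_sites(genome, pair.reverse, max_mismatch, anchor_len)
    fwd_products = _pair_sites(
        chrom,
        gseq,
        [s for s in f_sites if s.strand == "+"],
        [s for s in r_sites if s.strand == "-"],
        min_product,
        max_product,
    )
    rev_products = _pair_sites(
        chrom,
        gseq,
        [s for s in r_sites if s.strand == "+"],
        [s for s in f_sites if s.strand == "-"],
        min_product,
        max_product,
    )
    seen: set[tuple[str, int, int]] = set()
    out: list[Amplicon] = []
    for amp in sorted(
        fwd_products + rev_products,
        key=lambda a: (a.interval.chrom, a.interval.start, a.interval.end),
    ):
        key = (amp.interval.chrom, amp.interval.start, amp.interval.end)
        if key not in seen:
            seen.add(key)
            out.append(amp)
    return out


def _oracle_sites(gseq: str, chrom: str, pseq: str, name: str, max_mismatch: int, anchor_len: int):
    """Shortcut-free site scan: every window, both strands, counted in full."""
    L = len(pseq)
    rc = reverse_complement(pseq)
    plus: list[BindingSite] = []
    minus: list[BindingSite] = []
    for i in range(len(gseq) - L + 1):
        window = gseq[i : i + L]
        # N never equals a primer base: it fails the anchor comparison and
        # counts as an ordinary mismatch elsewhere.
        if window[L - anchor_len :] == pseq[L - anchor_len :]:
            mm = sum(1 for a, b in zip(window, pseq) if a != b)
            if mm <= max_mismatch:
                plus.append(
                    BindingSite(
                        GenomicInterval(chrom, i, i + L, strand="+", name=name),
                        "+",
                        mm,
                        name,
                    )
                )
        if window[:anchor_len] == rc[:anchor_len]:
            mm = sum(1 for a, b in zip(window, rc) if a != b)
            if mm <= max_mismatch:
                minus.append(
                    BindingSite(
                        GenomicInterval(chrom, i, i + L, strand="-", name=name),
                        "-",
                        mm,
                        name,
                    )
                )
    return plus, minus


def brute_force_pcr_oracle(
    genome,
    pair: PrimerPair,
    max_product: int = 1000,
    min_product: int = 40,
    max_mismatch: int = 2,
    anchor_len: int = 5,
) -> list[Amplicon]:
    """Exhaustive position-by-position reference implementation.

    Applies the same match rules as :func:`predict_amplicons` with no
    anchor index or vectorization; quadratic site pairing. Intended as an
    independent correctness check on small genomes (refuses > 100 kb).
    """
    chrom, gseq = _as_seq(genome)
    if len(gseq) > 100_000:
        raise ValueError("oracle refuses genomes longer than 100 kb")
    if len(gseq) == 0:
        return []
    f_plus, f_minus = _oracle_sites(
        gseq, chrom, pair.forward.seq, pair.forward.name, max_mismatch, anchor_len
    )
    r_plus, r_minus = _oracle_sites(
        gseq, chrom, pair.reverse.seq, pair.reverse.name, max_mismatch, anchor_len
    )
    products: list[Amplicon] = []
    for plus_sites, minus_sites in ((f_plus, r_minus), (r_plus, f_minus)):
        for f in plus_sites:
            for r in minus_sites:
                if r.interval.start < f.interval.end:
                    continue
                product = r.interval.end - f.interval.start
                if not (min_product <= product <= max_product):
                    continue
                interval = GenomicInterval(chrom, f.interval.start, r.interval.end)
                products.append(
                    Amplicon(interval, f, r, product, gseq[interval.start : interval.end])
                )
    seen: set[tuple[str, int, int]] = set()
    out: list[Amplicon] = []
    for amp in sorted(
        products, key=lambda a: (a.interval.chrom, a.interval.start, a.interval.end)
    ):
        key = (amp.interval.chrom, amp.interval.start, amp.interval.end)
        if key not in seen:
            seen.add(key)
            out.append(amp)
    return out
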