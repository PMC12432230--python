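"""Subfamily-discriminating base discovery on consensus alignments.

The L1PA lineage is a series of LINE1 subfamilies of increasing evolutionary
age. Because each subfamily's consensus accumulated its own substitutions, an
alignment column where one subfamily's base differs from every other compared
subfamily is *discriminating* for it: a primer overlapping such a column can
hybridize preferentially to copies of that subfamily. This module aligns the
consensuses, scans for discriminating columns, and enumerates candidate
amplicon regions (bounded length, discriminating bases near both ends) that
the primer-design stage turns into concrete primer pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align

from .io_formats import FormatError, SequenceRecord, normalize_sequence

__all__ = [
    "ConsensusSet",
    "Alignment",
    "DiagnosticColumn",
    "CandidateRegion",
    "progressive_align",
    "accept_external_msa",
    "find_discriminating_columns",
    "enumerate_candidate_regions",
]

_ALIGNED_ALPHABET = frozenset("ACGTN-")


class ConsensusSet:
    """Ordered map subfamily name -> ungapped DNA consensus.

    Order is meaningful: the first member is the youngest subfamily, the
    last the oldest (L1HS -> L1PA17 in the real lineage).
    """

    def __init__(self, members: Iterable[tuple[str, str]]):
        members = list(members)
        if len(members) < 2:
            raise ValueError("a consensus set needs at least 2 subfamilies")
        names = [name for name, _ in members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate subfamily names in consensus set")
        self._names = names
        self._seqs = {name: seq.upper() for name, seq in members}
        for name, seq in self._seqs.items():
            if not seq:
                raise ValueError(f"empty consensus for {name!r}")

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "ConsensusSet":
        return cls((rec.id, rec.seq) for rec in records)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._names)

    def items(self) -> list[tuple[str, str]]:
        return [(n, self._seqs[n]) for n in self._names]

    def to_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(n, s) for n, s in self.items()]


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment over {A,C,G,T,N,-}."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("alignment needs at least 2 rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows, lengths {sorted(lengths)}")
        for name, seq in self.rows:
            bad = set(seq) - _ALIGNED_ALPHABET
            if bad:
                raise FormatError(f"row {name!r} has illegal characters {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.rows]

    def row(self, name: str) -> str:
        for n, seq in self.rows:
            if n == name:
                return seq
        raise KeyError(name)

    def degapped(self, name: str) -> str:
        return self.row(name).replace("-", "")


@dataclass(frozen=True)
class DiagnosticColumn:
    """One alignment column together with the subfamilies it discriminates.

    A subfamily is discriminated by a column iff its residue is a base (not
    a gap) and differs from the residue of every other subfamily in the
    compared set. A gap in another row counts as "different" (a base versus
    an absent base is PCR-discriminating), but a gap in the subfamily's own
    row never discriminates: a primer must physically cover a base.
    """

    column_index: int
    residues: Mapping[str, str]
    discriminates: frozenset[str]
    target_consensus_pos: Mapping[str, int]


@dataclass(frozen=True)
class CandidateRegion:
    """A window on one target consensus able to host a selective primer pair.

    Both footprints (prospective primer binding windows at the region ends)
    cover at least one discriminating position. Coordinates are 0-based
    half-open on the target's ungapped consensus.
    """

    target_subfamily: str
    region: tuple[int, int]
    left_footprint: tuple[int, int]
    right_footprint: tuple[int, int]
    left_diag: tuple[int, ...]
    right_diag: tuple[int, ...]

    def __post_init__(self) -> None:
        rs, re = self.region
        ls, le = self.left_footprint
        qs, qe = self.right_footprint
        if not (rs <= ls < le <= qs < qe <= re):
            raise ValueError("footprints must be ordered, disjoint, inside region")
        if not self.left_diag or not self.right_diag:
            raise ValueError("both footprints need >=1 discriminating position")

    @property
    def length(self) -> int:
        return self.region[1] - self.region[0]


def _pairwise_global(a: str, b: str, match: float, mismatch: float, gap: float):
    """Optimal global pairwise alignment, Needleman-Wunsch with linear gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), aln.score


def progressive_align(
    consensuses: ConsensusSet,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Alignment:
    """Star-progressive multiple alignment seeded on the first sequence.

    Each later sequence is aligned globally against the first (youngest)
    consensus; the pairwise alignments are then merged onto a shared column
    structure (insertions relative to the centre are left-justified and
    padded to the maximum insertion length observed at that point).
    De-gapping any row recovers the corresponding input exactly. The
    procedure is deterministic.

    The scoring scheme is a simple linear-gap match/mismatch model; for real
    consensus sets an externally computed MSA (e.g. Clustal Omega, MAFFT)
    can be supplied through :func:`accept_external_msa` instead.
    """
    items = consensuses.items()
    center_name, center = items[0]
    if any(not seq for _, seq in items):
        raise ValueError("cannot align empty sequences")

    # per sequence: insertions[p] = bases of seq inserted before center pos p,
    # matched[p] = the row character aligned to center base p.
    per_seq: list[tuple[str, list[str], list[str]]] = []
    for name, seq in items[1:]:
        gapped_c, gapped_s, _ = _pairwise_global(center, seq, match, mismatch, gap)
        insertions: list[str] = [""] * (len(center) + 1)
        matched: list[str] = []
        p = 0
        for cc, sc in zip(gapped_c, gapped_s):
            if cc == "-":
                insertions[p] += sc
            else:
                matched.append(sc)
                p += 1
        per_seq.append((name, insertions, matched))

    max_ins = [0] * (len(center) + 1)
    for _, insertions, _ in per_seq:
        for p, ins in enumerate(insertions):
            max_ins[p] = max(max_ins[p], len(ins))

    def build_row(insertions: list[str], matched: list[str]) -> str:
        parts: list[str] = []
        for p in range(len(center) + 1):
            ins = insertions[p]
            parts.append(ins + "-" * (max_ins[p] - len(ins)))
            if p < len(center):
                parts.append(matched[p])
        return "".join(parts)

    rows = [(center_name, build_row([""] * (len(center) + 1), list(center)))]
    for name, insertions, matched in per_seq:
        rows.append((name, build_row(insertions, matched)))
    return Alignment(tuple(rows))


def accept_external_msa(records: Sequence[SequenceRecord] | str) -> Alignment:
    """Validate an externally computed MSA (aligned FASTA) as an Alignment.

    Accepts either a path to an aligned FASTA file or already-parsed
    records. Aligned sequences may contain ``-``; the de-gapped sequences
    must be DNA.
    """
    if isinstance(records, (str, bytes)) or hasattr(records, "__fspath__"):
        rows = _read_aligned_fasta(records)  # type: ignore[arg-type]
    else:
        rows = [(rec.id, rec.seq) for rec in records]
    return Alignment(tuple(rows))


def _read_aligned_fasta(path) -> list[tuple[str, str]]:
    # SequenceRecord forbids "-", so aligned FASTA is parsed directly.
    rows: list[tuple[str, str]] = []
    name: Optional[str] = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    rows.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        rows.append((name, "".join(chunks)))
    if not rows:
        raise FormatError(f"no aligned records in {path}")
    return rows


def find_discriminating_columns(
    alignment: Alignment,
    target: str,
    comparison: Optional[Sequence[str]] = None,
) -> list[DiagnosticColumn]:
    """Columns where the target's base differs from every compared subfamily.

    ``comparison`` restricts the compared set (default: all other rows in
    the alignment), mirroring the practice of running separate comparisons
    for young (L1HS vs L1PA2-6) and old (L1PA14-17) lineage ends.
    """
    names = alignment.names
    if target not in names:
        raise KeyError(f"unknown target subfamily {target!r}")
    if comparison is None:
        comparison = [n for n in names if n != target]
    else:
        comparison = list(comparison)
        unknown = set(comparison) - set(names)
        if unknown:
            raise KeyError(f"comparison subfamilies not in alignment: {sorted(unknown)}")
        comparison = [n for n in comparison if n != target]
        if not comparison:
            raise ValueError("comparison set must contain a non-target subfamily")

    members = [target] + comparison
    seqs = {n: alignment.row(n) for n in members}

    # ungapped coordinate per column, per member
    pos_counter = {n: 0 for n in members}
    columns: list[DiagnosticColumn] = []
    for col in range(alignment.n_columns):
        residues = {n: seqs[n][col] for n in members}
        consensus_pos: dict[str, int] = {}
        for n in members:
            if residues[n] != "-":
                consensus_pos[n] = pos_counter[n]
                pos_counter[n] += 1
        discriminates = frozenset(
            n
            for n in members
            if residues[n] in "ACGT"
            and all(residues[m] != residues[n] for m in members if m != n)
        )
        if target in discriminates:
            columns.append(
                DiagnosticColumn(
                    column_index=col,
                    residues=residues,
                    discriminates=discriminates,
                    target_consensus_pos=consensus_pos,
                )
            )
    return columns


def enumerate_candidate_regions(
    diag_positions: Sequence[int],
    max_region_len: int = 200,
    footprint_len_range: tuple[int, int] = (18, 22),
    consensus_length: Optional[int] = None,
) -> list[CandidateRegion]:
    """Enumerate regions with discriminating positions near both ends.

    For every ordered pair (p, q) of discriminating positions that fits two
    non-overlapping minimum-length footprints inside ``max_region_len``, one
    canonical region [p, q+1) is emitted: the left footprint starts at p,
    the right footprint ends at q+1, both at the minimum footprint length
    (primer design slides and resizes footprints within the region later).
    Output is deduplicated and sorted by (start, end).
    """
    fl_min = footprint_len_range[0]
    if fl_min < 1:
        raise ValueError("minimum footprint length must be >=1")
    positions = sorted(set(diag_positions))
    regions: list[CandidateRegion] = []
    for i, p in enumerate(positions):
        for q in positions[i + 1 :]:
            span = q + 1 - p
            if span > max_region_len:
                break
            if q - p < 2 * fl_min - 1:
                continue  # footprints would overlap
            if consensus_length is not None and q >= consensus_length:
                continue
            left = (p, p + fl_min)
            right = (q + 1 - fl_min, q + 1)
            left_diag = tuple(d for d in positions if left[0] <= d < left[1])
            right_diag = tuple(d for d in positions if right[0] <= d < right[1])
            regions.append(
                CandidateRegion(
                    target_subfamily="",
                    region=(p, q + 1),
                    left_footprint=left,
                    right_footprint=right,
                    left_diag=left_diag,
                    right_diag=right_diag,
                )
            )
    regions.sort(key=lambda r: (r.region, r.left_footprint, r.right_footprint))
    return regions


def diagnose(
    consensuses: ConsensusSet,
    target: str,
    comparison: Optional[Sequence[str]] = None,
    msa: Optional[Alignment] = None,
    max_region_len: int = 200,
    footprint_len_range: tuple[int, int] = (18, 22),
) -> tuple[list[DiagnosticColumn], list[CandidateRegion]]:
    """Convenience wrapper: align (unless given), scan, enumerate regions."""
    alignment = msa if msa is not None else progressive_align(consensuses)
    columns = find_discriminating_columns(alignment, target, comparison)
    diag_positions = [c.target_consensus_pos[target] for c in columns]
    regions = enumerate_candidate_regions(
        diag_positions,
        max_region_len=max_region_len,
        footprint_len_range=footprint_len_range,
        consensus_length=len(consensuses[target]) if target in consensuses else None,
    )
    regions = [
        CandidateRegion(
            target_subfamily=target,
            region=r.region,
            left_footprint=r.left_footprint,
            right_footprint=r.right_footprint,
            left_diag=r.left_diag,
            right_diag=r.right_diag,
        )
        for r in regions
    ]
    return columns, regions
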