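"""Seeded synthetic repeat-lineage generator.

Emulates the structure of the L1PA lineage so the whole primer-design and
validation pipeline is testable without external downloads: a chain of
consensus sequences in which each subfamily derives from the previous one by
i.i.d. substitutions (youngest first, mirroring how older subfamilies carry
progressively more lineage mutations), a background genome with planted,
individually diverged and optionally 5'-truncated copies on random strands,
a matching annotation, and weighted fragment sets emulating amplicon-seq
input. Everything is a pure function of the seed.

Deliberate simplifications (v1): substitutions only (no indels), uniform
substitution matrix, no target-site duplications or poly-A tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostics import ConsensusSet
from .io_formats import GenomicInterval, RepeatAnnotation, SequenceRecord
from .primer_design import reverse_complement

__all__ = [
    "SimParams",
    "SimulationError",
    "simulate_lineage",
    "plant_copies",
    "simulate_fragments",
]

_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    """Raised when planted copies cannot be placed."""


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic lineage.

    Defaults describe a desk-scale L1PA-like lineage: six subfamilies of a
    7 kb element (full-length LINE1 is ~6 kb), 2% divergence added per
    lineage step (adjacent real L1PA consensuses differ by a few percent),
    30 copies per subfamily each carrying 3% private divergence, and half
    of the copies 5'-truncated — real genomic LINE1 copies are predominantly
    5'-truncated.
    """

    n_subfamilies: int = 6
    consensus_length: int = 7000
    step_substitution_rate: float = 0.02
    copies_per_subfamily: int = 30
    copy_divergence: float = 0.03
    truncation_prob: float = 0.5
    truncation_range: tuple[float, float] = (0.1, 0.9)
    genome_length: int = 500_000
    seed: int = 0
    name_prefix: str = "L1SIM"

    def __post_init__(self) -> None:
        if self.n_subfamilies < 2:
            raise ValueError("need at least 2 subfamilies")
        if self.consensus_length < 100:
            raise ValueError("consensus too short to host primer pairs (<100 bp)")
        for rate in (
            self.step_substitution_rate,
            self.copy_divergence,
            self.truncation_prob,
            *self.truncation_range,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.truncation_range[0] > self.truncation_range[1]:
            raise ValueError("empty truncation range")
        if self.copies_per_subfamily < 0 or self.genome_length < 1:
            raise ValueError("copies_per_subfamily >=0 and genome_length >=1 required")

    def subfamily_names(self) -> list[str]:
        # youngest (index 1) to oldest
        return [f"{self.name_prefix}{i+1}" for i in range(self.n_subfamilies)]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute each site independently with probability ``rate``; a
    substituted site always changes to a different base."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    n_mut = int(mask.sum())
    if n_mut:
        idx = np.flatnonzero(mask)
        codes = {ord(b): i for i, b in enumerate("ACGT")}
        lut = np.zeros(256, dtype=np.uint8)
        for o, c in codes.items():
            lut[o] = c
        current = lut[arr[idx]]
        shift = rng.integers(1, 4, size=n_mut)
        arr[idx] = np.frombuffer("ACGT".encode(), dtype=np.uint8)[
            (current + shift) % 4
        ]
    return arr.tobytes().decode("ascii"), n_mut


def simulate_lineage(params: SimParams) -> ConsensusSet:
    """Generate the chain of subfamily consensuses, youngest first.

    Subfamily i+1 derives from subfamily i by i.i.d. substitutions at
    ``step_substitution_rate`` per site. Deterministic given the seed.
    """
    rng = np.random.default_rng([params.seed, 0])
    names = params.subfamily_names()
    seqs = [_random_dna(rng, params.consensus_length)]
    for _ in range(1, params.n_subfamilies):
        mutated, _ = _mutate(rng, seqs[-1], params.step_substitution_rate)
        seqs.append(mutated)
    return ConsensusSet(zip(names, seqs))


def plant_copies(
    params: SimParams, consensuses: ConsensusSet
) -> tuple[SequenceRecord, list[RepeatAnnotation], pd.DataFrame]:
    """Insert diverged, optionally 5'-truncated copies into a random genome.

    Returns the genome, the exact annotation of every planted interval
    (strand-aware; extracting a ``-`` interval and reverse-complementing it
    reproduces the planted element), and a per-copy truth table with the
    realized substitution count and truncated fraction.

    Copies are inserted between background bases at distinct offsets, so the
    final genome is longer than ``genome_length``; planted copies never
    overlap each other.
    """
    rng = np.random.default_rng([params.seed, 1])
    background = _random_dna(rng, params.genome_length)
    chrom = "chrSim"

    placements = []  # (offset_in_background, subfamily, copy_seq, strand, row)
    n_total = params.n_subfamilies * params.copies_per_subfamily
    used_offsets: set[int] = set()
    copy_idx = 0
    for name, consensus in consensuses.items():
        for _ in range(params.copies_per_subfamily):
            mutated, n_mut = _mutate(rng, consensus, params.copy_divergence)
            trunc_frac = 0.0
            if rng.random() < params.truncation_prob:
                lo, hi = params.truncation_range
                trunc_frac = float(rng.uniform(lo, hi))
                cut = int(round(trunc_frac * len(mutated)))
                cut = min(cut, len(mutated) - 1)  # keep >=1 base
                mutated = mutated[cut:]
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = mutated if strand == "+" else reverse_complement(mutated)
            offset = None
            for _attempt in range(1000):
                cand = int(rng.integers(0, params.genome_length + 1))
                if cand not in used_offsets:
                    offset = cand
                    break
            if offset is None:
                raise SimulationError(
                    f"could not place copy {copy_idx} of {n_total} without overlap"
                )
            used_offsets.add(offset)
            placements.append(
                (
                    offset,
                    name,
                    inserted,
                    strand,
                    {
                        "copy_id": f"{name}_c{copy_idx}",
                        "subfamily": name,
                        "strand": strand,
                        "n_substitutions": n_mut,
                        "divergence": n_mut / len(consensus),
                        "truncated_fraction": trunc_frac,
                        "copy_length": len(inserted),
                        "full_length": len(inserted) >= 0.9 * len(consensus),
                    },
                )
            )
            copy_idx += 1

    placements.sort(key=lambda p: p[0])
    pieces: list[str] = []
    annotations: list[RepeatAnnotation] = []
    rows: list[dict] = []
    prev = 0
    shift = 0
    for offset, name, inserted, strand, row in placements:
        pieces.append(background[prev:offset])
        start = offset + shift
        end = start + len(inserted)
        pieces.append(inserted)
        interval = GenomicInterval(chrom, start, end, strand=strand, name=name)
        annotations.append(
            RepeatAnnotation(interval, name, repeat_class="LINE", repeat_family="L1")
        )
        row = dict(row, start=start, end=end)
        rows.append(row)
        shift += len(inserted)
        prev = offset
    pieces.append(background[prev:])
    genome = SequenceRecord(chrom, "".join(pieces))
    truth = pd.DataFrame(rows)
    return genome, annotations, truth


def simulate_fragments(
    annotation: Sequence[RepeatAnnotation],
    weights: Mapping[str, float],
    n_fragments: int,
    frag_len: int = 200,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Draw sequencing-fragment intervals concentrated on weighted loci.

    ``weights`` maps annotation category (repeat_name) to a sampling
    weight; each locus of a category carries that category's weight, and
    fragments are placed uniformly within the chosen locus (clipped to the
    locus when it is shorter than ``frag_len``). Deterministic given seed.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >=0")
    if frag_len < 1:
        raise ValueError("frag_len must be >=1")
    loci = [a for a in annotation if weights.get(a.repeat_name, 0.0) > 0]
    w = np.array([weights[a.repeat_name] for a in loci], dtype=float)
    if not loci:
        if n_fragments == 0:
            return []
        raise ValueError("all weights are zero; cannot sample fragments")
    rng = np.random.default_rng(seed)
    probs = w / w.sum()
    choices = rng.choice(len(loci), size=n_fragments, p=probs)
    fragments: list[GenomicInterval] = []
    for i, li in enumerate(choices):
        locus = loci[li].interval
        if locus.length <= frag_len:
            start, end = locus.start, locus.end
        else:
            start = int(rng.integers(locus.start, locus.end - frag_len + 1))
            end = start + frag_len
        fragments.append(
            GenomicInterval(locus.chrom, start, end, strand=".", name=f"frag{i}")
        )
    return fragments
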