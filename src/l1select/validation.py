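"""Amplicon-seq / RNA-seq readout analytics.

Consumes fragment intervals (the outer template interval of a properly
paired read pair, supplied as BED — read mapping and unique-alignment
filtering happen upstream with standard tools) and provides: per-category
fragment fractions, amplified-locus calling (merged intervals supported by
at least ``min_support`` fragments), intersection of called loci with the
four annotation tracks, and per-subfamily FPKM summation.

A fragment BED can be produced from a coordinate-sorted BAM with, e.g.::

    samtools view -bf 0x2 aln.bam | bedtools bamtobed -bedpe -i - \
        | awk -v OFS='\t' '{print $1, ($2<$5?$2:$5), ($3>$6?$3:$6)}'
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io_formats import GenomicInterval, RepeatAnnotation
from .selectivity import (
    AnnotationIndex,
    AnnotationTracks,
    CategoryReport,
    _make_report,
    assign_interval,
)

__all__ = [
    "AmplifiedLocus",
    "ExpressionTable",
    "count_fragments_by_category",
    "call_amplified_loci",
    "union_loci",
    "intersect_loci_with_tracks",
    "fpkm_per_subfamily",
]


@dataclass(frozen=True)
class AmplifiedLocus:
    """A merged genomic interval supported by >= min_support fragments."""

    interval: GenomicInterval
    support: int


@dataclass(frozen=True)
class ExpressionTable:
    """Per-locus and per-subfamily FPKM.

    FPKM = 1e9 * count / (locus_length * total_counted_fragments); the
    per-subfamily value is the sum over member loci. (Fragments are what is
    counted here, so the quantity is an FPKM; with single-end reads the
    identical formula is conventionally called RPKM.)
    """

    per_locus: pd.DataFrame  # columns: locus, subfamily, length, count, fpkm
    per_subfamily: pd.Series


def count_fragments_by_category(
    fragments: Sequence[GenomicInterval],
    annotations: Sequence[RepeatAnnotation] | AnnotationIndex,
    lineage_names: Sequence[str],
    strand_matched: bool = False,
) -> CategoryReport:
    """Assign every fragment to its majority-overlap category and report.

    ``strand_matched=True`` counts only annotations on the fragment's
    strand (RNA-seq mode); the default suits amplicon DNA, where both
    strands are amplified.
    """
    index = (
        annotations
        if isinstance(annotations, AnnotationIndex)
        else AnnotationIndex(annotations)
    )
    assignments = (
        assign_interval(f, index, lineage_names, strand_matched=strand_matched)
        for f in fragments
    )
    return _make_report(assignments, lineage_names)


def call_amplified_loci(
    fragments: Sequence[GenomicInterval], min_support: int = 3
) -> list[AmplifiedLocus]:
    """Merge overlapping fragments and keep intervals with enough support.

    Fragments sharing at least one base are merged into maximal intervals
    (bookended fragments are not merged); an interval is retained iff at
    least ``min_support`` fragments overlap it ("at least three fragments"
    is the conventional threshold, boundary inclusive). Sorted by
    coordinate.
    """
    if min_support < 1:
        raise ValueError("min_support must be >=1")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    loci: list[AmplifiedLocus] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end, count = ivs[0].start, ivs[0].end, 1
        for iv in ivs[1:]:
            if iv.start < cur_end:  # strict overlap
                cur_end = max(cur_end, iv.end)
                count += 1
            else:
                if count >= min_support:
                    loci.append(
                        AmplifiedLocus(GenomicInterval(chrom, cur_start, cur_end), count)
                    )
                cur_start, cur_end, count = iv.start, iv.end, 1
        if count >= min_support:
            loci.append(
                AmplifiedLocus(GenomicInterval(chrom, cur_start, cur_end), count)
            )
    return loci


def union_loci(
    a: Sequence[AmplifiedLocus], b: Sequence[AmplifiedLocus]
) -> list[AmplifiedLocus]:
    """Union of two amplified-locus calls (e.g. from unique-filtered and
    unfiltered alignments): overlapping loci merge, supports add."""
    by_chrom: dict[str, list[AmplifiedLocus]] = {}
    for locus in list(a) + list(b):
        by_chrom.setdefault(locus.interval.chrom, []).append(locus)
    out: list[AmplifiedLocus] = []
    for chrom in sorted(by_chrom):
        loci = sorted(by_chrom[chrom], key=lambda l: (l.interval.start, l.interval.end))
        cur = loci[0]
        cur_start, cur_end, support = cur.interval.start, cur.interval.end, cur.support
        for locus in loci[1:]:
            if locus.interval.start < cur_end:
                cur_end = max(cur_end, locus.interval.end)
                support += locus.support
            else:
                out.append(AmplifiedLocus(GenomicInterval(chrom, cur_start, cur_end), support))
                cur_start, cur_end = locus.interval.start, locus.interval.end
                support = locus.support
        out.append(AmplifiedLocus(GenomicInterval(chrom, cur_start, cur_end), support))
    return out


def intersect_loci_with_tracks(
    loci: Sequence[AmplifiedLocus], tracks: AnnotationTracks
) -> dict[str, int]:
    """Per-track count of amplified loci with >=1 bp overlap.

    A locus may count in several tracks (the tracks are nested/overlapping
    by construction).
    """
    counts: dict[str, int] = {}
    for name, intervals in tracks.as_dict().items():
        counts[name] = sum(
            1
            for locus in loci
            if any(locus.interval.overlap(iv) > 0 for iv in intervals)
        )
    return counts


def fpkm_per_subfamily(
    per_locus_counts: Mapping[str, int],
    locus_lengths: Mapping[str, int],
    subfamily_of_locus: Mapping[str, str],
    total_fragments: Optional[int] = None,
) -> ExpressionTable:
    """Per-locus FPKM and per-subfamily sums.

    ``total_fragments`` defaults to the sum of the supplied counts; pass it
    explicitly when the counted library is larger than the loci tabulated.
    """
    loci = list(per_locus_counts)
    missing = [l for l in loci if l not in locus_lengths or l not in subfamily_of_locus]
    if missing:
        raise KeyError(f"loci missing length or subfamily: {missing[:5]}")
    total = (
        int(total_fragments)
        if total_fragments is not None
        else int(sum(per_locus_counts.values()))
    )
    if total <= 0:
        raise ValueError("total counted fragments must be positive")
    rows = []
    for locus in loci:
        length = locus_lengths[locus]
        if length <= 0:
            raise ValueError(f"locus {locus!r} has non-positive length")
        count = per_locus_counts[locus]
        fpkm = 1e9 * count / (length * total)
        rows.append(
            {
                "locus": locus,
                "subfamily": subfamily_of_locus[locus],
                "length": length,
                "count": count,
                "fpkm": fpkm,
            }
        )
    per_locus = pd.DataFrame(
        rows, columns=["locus", "subfamily", "length", "count", "fpkm"]
    )
    per_subfamily = per_locus.groupby("subfamily")["fpkm"].sum()
    return ExpressionTable(per_locus, per_subfamily)
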