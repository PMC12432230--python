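"""Scoring predicted amplicons against a repeat annotation.

Assigns each amplicon (or sequenced fragment) to the annotation category it
overlaps most, summarizes per-subfamily on/off-target fractions, builds the
four standard annotation tracks (all LINE1, non-LINE1 complement,
full-length LINE1, full-length-and-intact LINE1), and counts subfamily copy
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .io_formats import GenomicInterval, RepeatAnnotation
from .primer_design import round_half_up

__all__ = [
    "OTHER_LINE1",
    "NON_LINE1",
    "CategoryReport",
    "AnnotationTracks",
    "AnnotationIndex",
    "assign_interval",
    "selectivity_report",
    "build_annotation_tracks",
    "copy_number",
    "is_line1",
]

OTHER_LINE1 = "other_LINE1"
NON_LINE1 = "non_LINE1"


def is_line1(annotation: RepeatAnnotation) -> bool:
    """Heuristic LINE1 test: class LINE/family L1, or an L1* repeat name."""
    return (
        annotation.repeat_family == "L1"
        or annotation.repeat_class.upper().startswith("LINE")
        and annotation.repeat_family in ("", "L1")
        or annotation.repeat_name.upper().startswith("L1")
    )


@dataclass(frozen=True)
class CategoryReport:
    """Per-category counts and percentages of amplicons or fragments.

    Categories are every configured lineage subfamily plus ``other_LINE1``
    (a LINE1 outside the lineage) and ``non_LINE1``. ``top2_share`` is the
    combined percentage of the two most-hit lineage subfamilies — the
    statistic behind "predominantly amplifies two closely related
    subfamilies".
    """

    total: int
    per_category: Mapping[str, tuple[int, float]]
    top2_share: float

    def count(self, category: str) -> int:
        return self.per_category.get(category, (0, 0.0))[0]

    def percent(self, category: str) -> float:
        return self.per_category.get(category, (0, 0.0))[1]


@dataclass(frozen=True)
class AnnotationTracks:
    """The four annotation tracks used to characterize amplified loci."""

    all_line1: tuple[GenomicInterval, ...]
    non_line1: tuple[GenomicInterval, ...]
    full_length: tuple[GenomicInterval, ...]
    full_length_intact: tuple[GenomicInterval, ...]

    def as_dict(self) -> dict[str, tuple[GenomicInterval, ...]]:
        return {
            "all_line1": self.all_line1,
            "non_line1": self.non_line1,
            "full_length": self.full_length,
            "full_length_intact": self.full_length_intact,
        }


class AnnotationIndex:
    """Interval-tree index over annotation records for overlap queries."""

    def __init__(self, annotations: Sequence[RepeatAnnotation]):
        self._trees: dict[str, IntervalTree] = {}
        for ann in annotations:
            iv = ann.interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, ann
            )

    def overlapping(
        self, interval: GenomicInterval, strand: Optional[str] = None
    ) -> list[RepeatAnnotation]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(interval.start, interval.end)]
        if strand is not None:
            hits = [a for a in hits if a.interval.strand == strand]
        return hits


def assign_interval(
    interval: GenomicInterval,
    annotations: Sequence[RepeatAnnotation] | AnnotationIndex,
    lineage_names: Optional[Sequence[str]] = None,
    strand_matched: bool = False,
) -> str:
    """Category of the annotation with the largest base-pair overlap.

    Ties break toward the longer annotation, then the lexicographically
    smaller repeat name, making the result independent of annotation order.
    No overlap, or best overlap with a non-LINE1 repeat, gives
    ``non_LINE1``; best overlap with a LINE1 outside ``lineage_names``
    gives ``other_LINE1`` (when a lineage is configured).
    ``strand_matched`` restricts candidate annotations to the fragment's
    strand (RNA-seq mode).
    """
    index = (
        annotations
        if isinstance(annotations, AnnotationIndex)
        else AnnotationIndex(annotations)
    )
    strand = interval.strand if strand_matched else None
    hits = index.overlapping(interval, strand=strand)
    if not hits:
        return NON_LINE1
    best = max(
        hits,
        key=lambda a: (interval.overlap(a.interval), a.length, _neg_name(a.repeat_name)),
    )
    if lineage_names is not None and best.repeat_name in lineage_names:
        return best.repeat_name
    if is_line1(best):
        return best.repeat_name if lineage_names is None else OTHER_LINE1
    return NON_LINE1


class _neg_name:
    """Order helper: larger key = lexicographically smaller name."""

    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name

    def __lt__(self, other: "_neg_name") -> bool:
        return self.name > other.name

    def __eq__(self, other) -> bool:
        return self.name == other.name


def _make_report(
    assignments: Iterable[str], lineage_names: Sequence[str]
) -> CategoryReport:
    counts: dict[str, int] = {name: 0 for name in lineage_names}
    counts[OTHER_LINE1] = 0
    counts[NON_LINE1] = 0
    total = 0
    for cat in assignments:
        counts[cat] = counts.get(cat, 0) + 1
        total += 1
    if total == 0:
        return CategoryReport(0, {k: (0, 0.0) for k in counts}, 0.0)
    per_category = {
        k: (c, round_half_up(100.0 * c / total, 1)) for k, c in counts.items()
    }
    lineage_pcts = sorted(
        (per_category[name][1] for name in lineage_names), reverse=True
    )
    top2 = round_half_up(sum(lineage_pcts[:2]), 1)
    return CategoryReport(total, per_category, top2)


def selectivity_report(
    amplicons: Sequence,
    annotations: Sequence[RepeatAnnotation] | AnnotationIndex,
    lineage_names: Sequence[str],
    strand_matched: bool = False,
) -> CategoryReport:
    """Per-category report over predicted amplicons (or plain intervals).

    Accepts :class:`~l1select.insilico_pcr.Amplicon` objects or
    :class:`GenomicInterval`; an empty input yields an explicit empty
    report (total=0), never a division by zero.
    """
    index = (
        annotations
        if isinstance(annotations, AnnotationIndex)
        else AnnotationIndex(annotations)
    )
    intervals = [getattr(a, "interval", a) for a in amplicons]
    assignments = (
        assign_interval(iv, index, lineage_names, strand_matched=strand_matched)
        for iv in intervals
    )
    return _make_report(assignments, lineage_names)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or bookended intervals are merged."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def complement_intervals(
    intervals: Sequence[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> list[GenomicInterval]:
    """Genomic complement of a merged interval set within ``chrom_sizes``."""
    merged = merge_intervals(intervals)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        pos = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < size:
            out.append(GenomicInterval(chrom, pos, size))
    return out


def build_annotation_tracks(
    annotations: Sequence[RepeatAnnotation],
    chrom_sizes: Mapping[str, int],
    intact_loci: Sequence[GenomicInterval] = (),
    full_length_min: int = 6000,
) -> AnnotationTracks:
    """Build the four annotation tracks.

    ``all_line1``: merged LINE1 intervals; ``non_line1``: their genomic
    complement; ``full_length``: LINE1 records longer than
    ``full_length_min`` (default >6 kb, the conventional full-length LINE1
    threshold); ``full_length_intact``: full-length records overlapping the
    supplied externally curated intact-locus set.
    """
    line1 = [a for a in annotations if is_line1(a)]
    for a in line1:
        if a.interval.chrom not in chrom_sizes:
            raise ValueError(
                f"annotation chrom {a.interval.chrom!r} absent from chrom_sizes"
            )
    all_line1 = merge_intervals([a.interval for a in line1])
    non_line1 = complement_intervals(all_line1, chrom_sizes)
    full = sorted(
        (a.interval for a in line1 if a.length > full_length_min),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    intact = list(intact_loci)
    full_intact = [
        iv for iv in full if any(iv.overlap(x) > 0 for x in intact)
    ]
    return AnnotationTracks(
        tuple(all_line1), tuple(non_line1), tuple(full), tuple(full_intact)
    )


def copy_number(
    annotations: Sequence[RepeatAnnotation], subfamily: str, min_len: int = 0
) -> int:
    """Number of annotated copies of a subfamily with length >= min_len."""
    return sum(
        1
        for a in annotations
        if a.repeat_name == subfamily and a.length >= min_len
    )


def plot_category_report(report: CategoryReport, ax=None, title: str = ""):
    """Plain bar chart of a category report (percent per category)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    cats = list(report.per_category)
    pcts = [report.per_category[c][1] for c in cats]
    ax.bar(range(len(cats)), pcts)
    ax.set_xticks(range(len(cats)))
    ax.set_xticklabels(cats, rotation=45, ha="right")
    ax.set_ylabel("% of amplified fragments")
    if title:
        ax.set_title(title)
    return ax
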