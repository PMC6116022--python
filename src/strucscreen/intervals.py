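"""Genomic intervals and elementary interval-set arithmetic.

All coordinates in this package are 0-based, half-open, on the forward
strand.  Interval *sets* are represented as plain lists of
:class:`GenomicInterval`; the helpers below (merge, intersect, subtract,
overlap counting) operate per chromosome on sorted endpoint arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections import defaultdict
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on the forward strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0
    attributes: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def with_fields(self, **kw) -> "GenomicInterval":
        return replace(self, **kw)


def by_chrom(intervals: Iterable[GenomicInterval]) -> dict:
    out: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        out[iv.chrom].append(iv)
    for ivs in out.values():
        ivs.sort(key=lambda x: (x.start, x.end))
    return dict(out)


def merge_intervals(
    intervals: Iterable[GenomicInterval], book_ended: bool = True
) -> list[GenomicInterval]:
    """Union of intervals; adjacent (end == start) intervals merge iff
    *book_ended*.  Strand/name/score of merged output are dropped."""
    out: list[GenomicInterval] = []
    for chrom, ivs in sorted(by_chrom(intervals).items()):
        cur_s, cur_e = None, None
        for iv in ivs:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start < cur_e or (book_ended and iv.start == cur_e):
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


def intersect(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of the merged footprints of *a* and *b*."""
    am, bm = by_chrom(merge_intervals(a)), by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for chrom in sorted(set(am) & set(bm)):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i].end < ys[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Merged footprint of *a* minus the footprint of *b*."""
    am, bm = by_chrom(merge_intervals(a)), by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for chrom, xs in sorted(am.items()):
        ys = bm.get(chrom, [])
        j = 0
        for x in xs:
            s = x.start
            while j < len(ys) and ys[j].end <= s:
                j += 1
            k = j
            while k < len(ys) and ys[k].start < x.end:
                if ys[k].start > s:
                    out.append(GenomicInterval(chrom, s, ys[k].start))
                s = max(s, ys[k].end)
                k += 1
            if s < x.end:
                out.append(GenomicInterval(chrom, s, x.end))
    return out


def overlap_nt(a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]) -> int:
    """Number of nucleotides in the footprint intersection of *a* and *b*."""
    return total_length(intersect(a, b))


def complement(
    intervals: Iterable[GenomicInterval], chrom_sizes: dict[str, int]
) -> list[GenomicInterval]:
    m = by_chrom(merge_intervals(intervals))
    out: list[GenomicInterval] = []
    for chrom, size in sorted(chrom_sizes.items()):
        pos = 0
        for iv in m.get(chrom, []):
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < size:
            out.append(GenomicInterval(chrom, pos, size))
    return out


def covered_fraction(
    query: GenomicInterval, covers: Sequence[GenomicInterval]
) -> float:
    """Fraction of *query* nucleotides inside the footprint of *covers*."""
    nt = overlap_nt([query], covers)
    return nt / len(query)
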