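"""Genomic interval primitives shared across the pipeline.

All coordinates are 0-based, half-open ``[start, end)`` on a named
chromosome. File writers that emit 1-based formats (GFF3) convert at the
boundary; everything in memory stays half-open.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "merge_intervals",
    "union_length",
    "containing_interval",
    "contains_point",
    "covers_span",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or negative interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def _as_pairs(intervals: Iterable) -> list[tuple[int, int]]:
    """Normalise tuples / GenomicIntervals / objects with start+end to pairs."""
    out = []
    for iv in intervals:
        if hasattr(iv, "start"):
            out.append((int(iv.start), int(iv.end)))
        else:
            s, e = iv
            out.append((int(s), int(e)))
    return out


def merge_intervals(intervals: Iterable, join_abutting: bool = True) -> list[tuple[int, int]]:
    """Merge overlapping (and, by default, abutting) intervals.

    Returns the minimal sorted list of disjoint ``(start, end)`` pairs with
    the same union as the input.
    """
    pairs = sorted(_as_pairs(intervals))
    if not pairs:
        return []
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        last = merged[-1]
        if s < last[1] or (join_abutting and s == last[1]):
            last[1] = max(last[1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def union_length(intervals: Iterable) -> int:
    """Total number of bases covered by the union of the intervals."""
    return sum(e - s for s, e in merge_intervals(intervals))


def _starts_ends(sorted_disjoint: Sequence[tuple[int, int]]):
    starts = [s for s, _ in sorted_disjoint]
    ends = [e for _, e in sorted_disjoint]
    return starts, ends


def containing_interval(sorted_disjoint: Sequence[tuple[int, int]], pos: int) -> int | None:
    """Index of the interval containing ``pos``, or None.

    ``sorted_disjoint`` must be sorted and non-overlapping (e.g. the output
    of :func:`merge_intervals`).
    """
    starts, ends = _starts_ends(sorted_disjoint)
    i = bisect_right(starts, pos) - 1
    if i >= 0 and pos < ends[i]:
        return i
    return None


def contains_point(sorted_disjoint: Sequence[tuple[int, int]], pos: int) -> bool:
    return containing_interval(sorted_disjoint, pos) is not None


class covers_span:
    """Containment queries against a set of cover intervals.

    Answers "is ``[start, end)`` fully inside at least one cover?" in
    O(log n) per query via a prefix maximum of cover ends over covers
    sorted by start. Covers need not be disjoint.
    """

    def __init__(self, covers: Iterable):
        pairs = sorted(_as_pairs(covers))
        self._starts = np.array([s for s, _ in pairs], dtype=np.int64)
        ends = np.array([e for _, e in pairs], dtype=np.int64)
        self._prefix_max_end = np.maximum.accumulate(ends) if len(ends) else ends

    def __call__(self, start: int, end: int) -> bool:
        i = int(np.searchsorted(self._starts, start, side="right")) - 1
        return i >= 0 and int(self._prefix_max_end[i]) >= end
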