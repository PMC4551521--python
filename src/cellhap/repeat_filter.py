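"""Scaffold–repeat overlap classification and the random-placement null.

Scaffolds whose whole span lies inside one repeat element are strongly
enriched in real dilution data relative to random placement and are mostly
read-mapping artifacts, so they are removed before phasing; contigs inside
repeats are retained for scaffold construction.

Classification tests the first and last base of a scaffold (``start`` and
``end - 1`` under half-open coordinates) against a merged, disjoint repeat
track: *whole_within* when one repeat contains the span, *two_ends_different*
when the ends fall in two distinct repeats, *one_end* when exactly one end is
inside a repeat, else *neither_end*. The four categories partition any
scaffold set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import containing_interval, merge_intervals

__all__ = [
    "CATEGORIES",
    "RepeatOverlapTable",
    "classify_scaffold",
    "overlap_table",
    "random_placement_null",
    "compare_observed_random",
    "drop_whole_within",
]

CATEGORIES = ("neither_end", "one_end", "two_ends_different", "whole_within")


@dataclass
class RepeatOverlapTable:
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    mean_lengths: dict[str, float] = field(default_factory=lambda: {c: float("nan") for c in CATEGORIES})

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _prepare_repeats(repeats) -> list[tuple[int, int]]:
    return merge_intervals(repeats)


def classify_scaffold(scaffold, repeats, merged: bool = False) -> str:
    """Category of one scaffold span against a repeat track.

    ``scaffold`` may be anything with ``start``/``end`` or a (start, end)
    pair. ``repeats`` is merged (overlaps collapsed) unless ``merged=True``
    promises it already is.
    """
    if hasattr(scaffold, "start"):
        start, end = scaffold.start, scaffold.end
    else:
        start, end = scaffold
    reps = repeats if merged else _prepare_repeats(repeats)
    i = containing_interval(reps, start)
    j = containing_interval(reps, end - 1)
    if i is not None and i == j:
        # merged repeats are intervals, so same repeat at both ends implies
        # full containment
        return "whole_within"
    if i is not None and j is not None:
        return "two_ends_different"
    if i is not None or j is not None:
        return "one_end"
    return "neither_end"


def _table_from_spans(spans: list[tuple[int, int]], reps: list[tuple[int, int]]) -> RepeatOverlapTable:
    table = RepeatOverlapTable()
    lengths: dict[str, list[int]] = {c: [] for c in CATEGORIES}
    for s, e in spans:
        cat = classify_scaffold((s, e), reps, merged=True)
        table.counts[cat] += 1
        lengths[cat].append(e - s)
    for c in CATEGORIES:
        table.mean_lengths[c] = float(np.mean(lengths[c])) if lengths[c] else float("nan")
    return table


def overlap_table(scaffolds, repeats) -> RepeatOverlapTable:
    """Observed category counts and mean lengths for a scaffold set."""
    reps = _prepare_repeats(repeats)
    spans = [(sc.start, sc.end) if hasattr(sc, "start") else tuple(sc) for sc in scaffolds]
    return _table_from_spans(spans, reps)


def random_placement_null(
    scaffold_lengths,
    chrom_length: int,
    repeats,
    seed: int = 0,
) -> RepeatOverlapTable:
    """Null overlap table: each scaffold length placed uniformly at random.

    Placements are constrained to lie fully on the chromosome (start uniform
    on [0, chrom_length − length]). Identical seed gives an identical table.
    """
    lengths = np.asarray(scaffold_lengths, dtype=np.int64)
    if np.any(lengths > chrom_length):
        raise ValueError("scaffold length exceeds chrom_length")
    rng = np.random.default_rng(seed)
    reps = _prepare_repeats(repeats)
    starts = rng.integers(0, chrom_length - lengths + 1)
    spans = [(int(s), int(s + ln)) for s, ln in zip(starts, lengths)]
    return _table_from_spans(spans, reps)


def compare_observed_random(observed: RepeatOverlapTable, random: RepeatOverlapTable) -> dict:
    """Observed/random count and mean-length ratios per category."""
    out = {}
    for c in CATEGORIES:
        rc = random.counts[c]
        rl = random.mean_lengths[c]
        out[c] = {
            "observed_count": observed.counts[c],
            "random_count": rc,
            "count_ratio": observed.counts[c] / rc if rc else float("nan"),
            "observed_mean_length": observed.mean_lengths[c],
            "random_mean_length": rl,
            "length_ratio": observed.mean_lengths[c] / rl if rl and rl == rl else float("nan"),
        }
    return out


def drop_whole_within(scaffolds, repeats) -> tuple[list, list]:
    """Split scaffolds into (retained, removed-as-wholly-within-repeat).

    Only whole scaffolds inside one repeat are removed; all other categories
    are retained. This rule applies to scaffolds, never to contigs.
    """
    reps = _prepare_repeats(repeats)
    retained, removed = [], []
    for sc in scaffolds:
        if classify_scaffold(sc, reps, merged=True) == "whole_within":
            removed.append(sc)
        else:
            retained.append(sc)
    return retained, removed
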