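"""Contig construction from mapped-read intervals and scaffold joining.

A *contig* here is a maximal run of overlapping (or abutting) mapped reads
from one library on one chromosome — the smallest unit of observed template.
Nearby contigs are inferred to derive from one amplified chromosome fragment
and are chained into *scaffolds* when the gap between them falls strictly
below a threshold. Two joining strategies are provided: a fixed or adaptive
(mean + k·sd of sub-ceiling gaps) gap threshold, and a windowed read-depth
run finder of the kind used for fosmid clone pools (contiguous 1 kb windows,
runs of 25–45 kb with at least two-thirds of windows above background).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Contig",
    "Scaffold",
    "GapStats",
    "build_contigs",
    "contig_gaps",
    "join_contigs",
    "adaptive_gap_threshold",
    "gap_statistics",
    "coverage_histogram",
    "windowed_run_scaffolds",
    "length_summary",
]


@dataclass
class Contig:
    chrom: str
    start: int
    end: int
    read_count: int = 1
    mean_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("contig must have end > start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Scaffold:
    chrom: str
    start: int
    end: int
    library_id: str = ""
    member_contigs: list[Contig] = field(default_factory=list)
    internal_gaps: list[int] = field(default_factory=list)
    flags: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GapStats:
    gaps: np.ndarray
    bin_width: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    per_bin_mean: np.ndarray
    per_bin_sd: np.ndarray
    global_mean: float
    global_sd: float
    expected_exponential_counts: np.ndarray


def build_contigs(
    read_intervals,
    chrom: str = "",
    min_reads: int = 1,
) -> list[Contig]:
    """Merge sorted read intervals into maximal contigs.

    Abutting reads (gap 0) merge: no gap exists to threshold. ``mean_depth``
    is total read bases over contig span. Intervals must be sorted by start
    and non-empty; contigs with fewer than ``min_reads`` reads are dropped.
    """
    ivs = [(int(s), int(e)) for s, e in read_intervals]
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"negative or zero-length read interval [{s}, {e})")
    if any(ivs[i][0] > ivs[i + 1][0] for i in range(len(ivs) - 1)):
        raise ValueError("read intervals must be sorted by start")
    contigs: list[Contig] = []
    cur_s = cur_e = None
    n = 0
    bases = 0
    for s, e in ivs:
        if cur_s is None:
            cur_s, cur_e, n, bases = s, e, 1, e - s
        elif s <= cur_e:  # overlap or abut
            cur_e = max(cur_e, e)
            n += 1
            bases += e - s
        else:
            contigs.append(Contig(chrom, cur_s, cur_e, n, bases / (cur_e - cur_s)))
            cur_s, cur_e, n, bases = s, e, 1, e - s
    if cur_s is not None:
        contigs.append(Contig(chrom, cur_s, cur_e, n, bases / (cur_e - cur_s)))
    return [c for c in contigs if c.read_count >= min_reads]


def contig_gaps(contigs: list[Contig]) -> np.ndarray:
    """Gaps (bp) between consecutive disjoint sorted contigs."""
    if len(contigs) < 2:
        return np.array([], dtype=np.int64)
    starts = np.array([c.start for c in contigs])
    ends = np.array([c.end for c in contigs])
    gaps = starts[1:] - ends[:-1]
    if np.any(gaps < 0):
        raise ValueError("contigs must be sorted and disjoint")
    return gaps


def join_contigs(contigs: list[Contig], max_gap: int, library_id: str = "") -> list[Scaffold]:
    """Join adjacent contigs into scaffolds when the gap is strictly < max_gap.

    ``max_gap = 0`` returns one scaffold per contig (identity).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    scaffolds: list[Scaffold] = []
    members: list[Contig] = []
    gaps: list[int] = []
    for c in contigs:
        if not members:
            members = [c]
            continue
        gap = c.start - members[-1].end
        if gap < 0:
            raise ValueError("contigs must be sorted and disjoint")
        if gap < max_gap:
            gaps.append(gap)
            members.append(c)
        else:
            scaffolds.append(
                Scaffold(c.chrom, members[0].start, members[-1].end, library_id, members, gaps)
            )
            members, gaps = [c], []
    if members:
        scaffolds.append(
            Scaffold(members[0].chrom, members[0].start, members[-1].end, library_id, members, gaps)
        )
    return scaffolds


def adaptive_gap_threshold(gaps, k: float = 3.0, ceiling: int | None = 1000) -> float:
    """Gap-joining threshold mu + k·sigma over gaps below a ceiling.

    Gaps under ~1 kb are the within-amplicon population, so the default
    restricts the statistics to that regime; ``ceiling=None`` uses all gaps.
    Accepts a gap array or a :class:`GapStats`.
    """
    if isinstance(gaps, GapStats):
        gaps = gaps.gaps
    g = np.asarray(gaps, dtype=float)
    if ceiling is not None:
        g = g[g < ceiling]
    if len(g) == 0:
        raise ValueError("no gaps below ceiling")
    mu = float(np.mean(g))
    sd = float(np.std(g, ddof=1)) if len(g) > 1 else 0.0
    return mu + k * sd


def gap_statistics(
    contigs_or_gaps,
    bin_width: int = 1000,
    exponential_mean: float | None = None,
) -> GapStats:
    """Binned gap-length statistics with an exponential-expectation overlay.

    Expected count in bin [a, b) under an exponential with the given mean is
    N·(e^(−a/mean) − e^(−b/mean)); by default the mean is the observed global
    mean gap length.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(contigs_or_gaps) and isinstance(contigs_or_gaps[0], Contig):
        gaps = contig_gaps(contigs_or_gaps)
    else:
        gaps = np.asarray(contigs_or_gaps, dtype=np.int64)
    if len(gaps) == 0:
        raise ValueError("need at least one gap")
    mu = float(np.mean(gaps))
    sd = float(np.std(gaps, ddof=1)) if len(gaps) > 1 else 0.0
    mean = exponential_mean if exponential_mean is not None else mu
    n_bins = int(np.max(gaps) // bin_width) + 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum(gaps // bin_width, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    per_mean = np.full(n_bins, np.nan)
    per_sd = np.full(n_bins, np.nan)
    for b in range(n_bins):
        in_bin = gaps[idx == b]
        if len(in_bin):
            per_mean[b] = float(np.mean(in_bin))
            per_sd[b] = float(np.std(in_bin, ddof=1)) if len(in_bin) > 1 else 0.0
    expected = len(gaps) * (np.exp(-edges[:-1] / mean) - np.exp(-edges[1:] / mean))
    return GapStats(gaps, bin_width, edges, counts, per_mean, per_sd, mu, sd, expected)


def coverage_histogram(depths, max_depth: int = 29):
    """Observed depth histogram with the matching-mean Poisson expectation.

    Returns a dict with ``depth`` (0..max_depth), observed ``counts``,
    Poisson ``expected`` counts at the observed mean, and the observed and
    expected ``overflow`` mass above ``max_depth``.
    """
    d = np.asarray(depths)
    if d.size == 0:
        raise ValueError("empty depth track")
    if np.any(d < 0):
        raise ValueError("depths must be non-negative")
    lam = float(np.mean(d))
    bins = np.arange(max_depth + 1)
    counts = np.bincount(np.minimum(d.astype(np.int64), max_depth + 1), minlength=max_depth + 2)
    observed = counts[: max_depth + 1]
    overflow = int(counts[max_depth + 1])
    pmf = stats.poisson.pmf(bins, lam)
    expected = pmf * d.size
    expected_overflow = float(d.size * stats.poisson.sf(max_depth, lam))
    return {
        "depth": bins,
        "counts": observed,
        "expected": expected,
        "mean": lam,
        "overflow": overflow,
        "expected_overflow": expected_overflow,
        "n": int(d.size),
    }


def windowed_run_scaffolds(
    depth_windows,
    background: float,
    window_fraction: float = 2 / 3,
    run_min: int = 25_000,
    run_max: int = 45_000,
    window_size: int = 1000,
    chrom: str = "",
    library_id: str = "",
) -> list[Scaffold]:
    """Scaffolds as runs of depth windows above a background level.

    Scans contiguous fixed-width windows and reports maximal runs that start
    and end on an above-background window and keep at least
    ``window_fraction`` of their windows above background. Runs shorter than
    ``run_min`` are dropped; runs longer than ``run_max`` are retained but
    flagged ``"over_run_max"``.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    above = np.asarray(depth_windows, dtype=float) > background
    n = len(above)
    scaffolds: list[Scaffold] = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        # greedy extension: jump to each next above-background window while
        # the run fraction stays >= window_fraction
        start = i
        end = i + 1  # exclusive, currently ends on an above window
        n_above = 1
        j = end
        while j < n:
            if not above[j]:
                j += 1
                continue
            if (n_above + 1) / (j + 1 - start) >= window_fraction:
                n_above += 1
                end = j + 1
                j += 1
            else:
                break
        length = (end - start) * window_size
        if length >= run_min:
            flags = ("over_run_max",) if length > run_max else ()
            scaffolds.append(
                Scaffold(chrom, start * window_size, end * window_size, library_id, flags=flags)
            )
        i = end
    return scaffolds


def length_summary(lengths) -> dict:
    """Mean / N50 / max / total / count of a set of element lengths.

    N50 is the length of the element at which the descending cumulative
    length first reaches at least half the total.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty length list")
    if np.any(arr <= 0):
        raise ValueError("lengths must be positive")
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    n50 = float(desc[np.searchsorted(cum, cum[-1] / 2.0)])
    return {
        "mean": float(arr.mean()),
        "N50": n50,
        "max": float(arr.max()),
        "total": float(arr.sum()),
        "count": int(arr.size),
    }
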