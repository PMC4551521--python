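"""Consistency metrics for haplotype scaffolds and phased blocks.

Two allele vectors over shared loci that derive from the haplotypes of one
individual should be either entirely identical or entirely complementary, so
phase labels are arbitrary and *consistency* is the greater of the fraction
of positions that agree or disagree.

Reconstruction errors, however, come in two kinds: an isolated locus out of
phase with its neighbours on both sides (a point error), and a run of two or
more adjacent out-of-phase loci (a *switch error*, where the comparison
changes haplotype mid-stream). *Switch consistency* disregards switch events
and counts only isolated interior errors, so it is never below raw
consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .intervals import covers_span
from .phase_prep import ALT, REF, ScaffoldCall

__all__ = [
    "ConsistencyReport",
    "pairwise_consistency",
    "all_pairs_consistency",
    "compare_to_reference",
    "feature_containment",
    "pair_phasing_rate",
]


@dataclass
class ConsistencyReport:
    n_shared_loci: int
    consistency: float
    switch_consistency: float
    n_isolated_errors: int
    n_switch_events: int
    defined: bool = True

    @classmethod
    def undefined(cls) -> "ConsistencyReport":
        return cls(0, float("nan"), float("nan"), 0, 0, defined=False)


def _minority_runs(minority: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of True values."""
    runs = []
    i = 0
    n = len(minority)
    while i < n:
        if minority[i]:
            j = i
            while j < n and minority[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def pairwise_consistency(vec_a, vec_b) -> ConsistencyReport:
    """Consistency and switch consistency of two binary allele vectors.

    Vectors must be equal-length binary arrays over the same ordered loci
    (drop missing positions first). The majority agreement state defines the
    in-phase relation (exact 50/50 ties resolve to "agree"); minority runs of
    length >= 2 are switch events, as are minority runs touching either
    boundary (a boundary locus has no neighbour on one side, so "out of phase
    on both sides" cannot apply). Only isolated interior minority loci count
    as errors: switch_consistency = 1 − errors / n.
    """
    a = np.asarray(vec_a, dtype=np.int8)
    b = np.asarray(vec_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    n = len(a)
    if n == 0:
        return ConsistencyReport.undefined()
    agree = a == b
    n_agree = int(np.sum(agree))
    # integer arithmetic keeps the metric exactly symmetric under complement
    consistency = max(n_agree, n - n_agree) / n
    minority = ~agree if 2 * n_agree >= n else agree
    errors = 0
    switches = 0
    for start, length in _minority_runs(minority):
        interior = start > 0 and start + length < n
        if length == 1 and interior:
            errors += 1
        else:
            switches += 1
    return ConsistencyReport(
        n_shared_loci=n,
        consistency=consistency,
        switch_consistency=1.0 - errors / n,
        n_isolated_errors=errors,
        n_switch_events=switches,
    )


def _shared_called(call_a: ScaffoldCall, call_b: ScaffoldCall):
    """Allele vectors of two scaffold calls over jointly called loci."""
    da = {int(i): int(x) for i, x in zip(call_a.locus_indices, call_a.alleles) if x in (REF, ALT)}
    db = {int(i): int(x) for i, x in zip(call_b.locus_indices, call_b.alleles) if x in (REF, ALT)}
    shared = sorted(da.keys() & db.keys())
    return np.array([da[i] for i in shared], dtype=np.int8), np.array([db[i] for i in shared], dtype=np.int8)


def all_pairs_consistency(calls: list[ScaffoldCall], min_shared: int = 2):
    """Locus-weighted aggregate consistency over all cross-library pairs.

    Every pair of scaffold calls from different libraries sharing at least
    ``min_shared`` jointly called loci is compared. Returns the aggregate
    :class:`ConsistencyReport` (locus-weighted means) and the per-pair list
    ``(id_a, id_b, report)``.
    """
    per_pair = []
    total = 0
    w_cons = 0.0
    w_switch = 0.0
    errors = 0
    switches = 0
    for ca, cb in combinations(calls, 2):
        if ca.library_id == cb.library_id:
            continue
        va, vb = _shared_called(ca, cb)
        if len(va) < min_shared:
            continue
        rep = pairwise_consistency(va, vb)
        per_pair.append((ca.library_id, cb.library_id, rep))
        total += rep.n_shared_loci
        w_cons += rep.consistency * rep.n_shared_loci
        w_switch += rep.switch_consistency * rep.n_shared_loci
        errors += rep.n_isolated_errors
        switches += rep.n_switch_events
    if total == 0:
        return ConsistencyReport.undefined(), per_pair
    agg = ConsistencyReport(total, w_cons / total, w_switch / total, errors, switches)
    return agg, per_pair


def compare_to_reference(blocks_or_calls, reference_phase: dict[int, int]) -> ConsistencyReport:
    """Compare blocks/scaffold calls to a reference haplotype assignment.

    ``reference_phase`` maps locus index to the reference hap0 allele. Each
    block (``hap0`` over ``locus_indices``) or scaffold call is restricted to
    shared loci and scored with :func:`pairwise_consistency`; the aggregate
    is locus-weighted. Complementary labelling scores 1.0 by construction.
    """
    total = 0
    w_cons = 0.0
    w_switch = 0.0
    errors = 0
    switches = 0
    for item in blocks_or_calls:
        if hasattr(item, "hap0"):
            pairs = [(int(i), int(a)) for i, a in zip(item.locus_indices, item.hap0)]
        else:
            pairs = [
                (int(i), int(a))
                for i, a in zip(item.locus_indices, item.alleles)
                if a in (REF, ALT)
            ]
        shared = [(i, a) for i, a in pairs if i in reference_phase]
        if not shared:
            continue
        va = np.array([a for _, a in shared], dtype=np.int8)
        vb = np.array([reference_phase[i] for i, _ in shared], dtype=np.int8)
        rep = pairwise_consistency(va, vb)
        total += rep.n_shared_loci
        w_cons += rep.consistency * rep.n_shared_loci
        w_switch += rep.switch_consistency * rep.n_shared_loci
        errors += rep.n_isolated_errors
        switches += rep.n_switch_events
    if total == 0:
        return ConsistencyReport.undefined()
    return ConsistencyReport(total, w_cons / total, w_switch / total, errors, switches)


def feature_containment(features, covers) -> float:
    """Percentage of features lying entirely within at least one cover.

    A feature straddling two covers does not count. Returns NaN when the
    feature list is empty (undefined denominator).
    """
    feats = [(f.start, f.end) if hasattr(f, "start") else tuple(f) for f in features]
    if not feats:
        return float("nan")
    contained = covers_span(covers)
    n = sum(1 for s, e in feats if contained(s, e))
    return 100.0 * n / len(feats)


def pair_phasing_rate(marked_loci_by_gene: dict, covers) -> float:
    """Percentage of within-gene locus pairs jointly inside one cover.

    ``marked_loci_by_gene`` maps a gene id to the positions of its marked
    (e.g. missense) loci; every unordered pair within a gene is tested for
    containment of both positions in a single cover interval. Returns NaN
    when no gene contributes a pair.
    """
    contained = covers_span(covers)
    n_pairs = 0
    n_phased = 0
    for positions in marked_loci_by_gene.values():
        pos = sorted(positions)
        for p, q in combinations(pos, 2):
            n_pairs += 1
            if contained(p, q + 1):  # both positions inside one cover
                n_phased += 1
    if n_pairs == 0:
        return float("nan")
    return 100.0 * n_phased / n_pairs
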