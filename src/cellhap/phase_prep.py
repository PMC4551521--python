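"""Prepare single-individual-haplotyping input from scaffolds and pileups.

Stages, in pipeline order:

1. :func:`select_informative_loci` — keep loci heterozygous in the bulk
   sample with both alleles seen somewhere across the dilution libraries;
   only these can join scaffolds into haplotypes.
2. :func:`call_scaffold_alleles` — distil per-library pileups into one
   allele call (0 / 1 / het / missing) per informative locus per scaffold.
3. :func:`filter_het_scaffolds` — scaffolds with too many heterozygous
   calls derive from both homologous chromosomes (or CNV/repeats) and are
   removed; surviving het positions are masked to missing.
4. :func:`two_snp_haplotype_filter` — adjacent locus pairs showing more
   than two distinct two-locus allele combinations across libraries signal
   collapsed copy-number artifacts; both loci are dropped, scaffolds kept.
5. :func:`write_sih_input` — emit the fragment (``frag``) and locus
   (``allvars``) files consumed by the haplotype assembler.

Allele coding is global: 0 = bulk REF, 1 = bulk ALT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "REF",
    "ALT",
    "HET",
    "MISSING",
    "SnpLocus",
    "ScaffoldCall",
    "TwoSnpHaplotypeCount",
    "select_informative_loci",
    "call_scaffold_alleles",
    "filter_het_scaffolds",
    "two_snp_haplotype_filter",
    "expected_diploid_fraction",
    "expected_screen_positive_loci",
    "het_coverage_diagnostics",
    "write_sih_input",
]

# allele codes in ScaffoldCall.alleles
REF: int = 0
ALT: int = 1
HET: int = 2
MISSING: int = -1


@dataclass(frozen=True)
class SnpLocus:
    """A candidate SNP (1-based ``pos``, VCF convention)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    bulk_genotype: str = "het"  # {"het", "hom_ref", "hom_alt"}
    bulk_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class ScaffoldCall:
    """Allele calls of one scaffold at the informative loci it spans."""

    scaffold: object
    library_id: str
    locus_indices: np.ndarray  # indices into the global informative-locus list
    alleles: np.ndarray  # values in {REF, ALT, HET, MISSING}

    def __post_init__(self) -> None:
        self.locus_indices = np.asarray(self.locus_indices, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)

    @property
    def het_count(self) -> int:
        return int(np.sum(self.alleles == HET))

    @property
    def n_called(self) -> int:
        return int(np.sum(self.alleles != MISSING))

    @property
    def het_fraction(self) -> float:
        n = self.n_called
        return self.het_count / n if n else 0.0


@dataclass
class TwoSnpHaplotypeCount:
    """Distinct allele combinations observed at one adjacent locus pair."""

    locus_pair: tuple[int, int]
    observed_haplotypes: set[tuple[int, int]] = field(default_factory=set)

    @property
    def allele_count(self) -> int:
        return len(self.observed_haplotypes)


def select_informative_loci(bulk_records, pileups_by_library: dict) -> list[SnpLocus]:
    """Informative loci: bulk-het with both alleles seen across libraries.

    ``bulk_records`` yields ``(chrom, pos, ref, alt, genotype, depth)`` tuples
    (``alt`` may be a list for multi-allelic records, which are skipped with a
    warning). ``pileups_by_library`` maps library id to a mapping
    ``(chrom, pos) -> (ref_count, alt_count)``.
    """
    loci: list[SnpLocus] = []
    for rec in bulk_records:
        chrom, pos, ref, alt, genotype, depth = rec
        if isinstance(alt, (list, tuple)):
            if len(alt) != 1:
                logger.warning("skipping multi-allelic record %s:%s", chrom, pos)
                continue
            alt = alt[0]
        if genotype != "het":
            continue
        ref_seen = alt_seen = False
        for counts in pileups_by_library.values():
            rc, ac = counts.get((chrom, pos), (0, 0))
            ref_seen = ref_seen or rc > 0
            alt_seen = alt_seen or ac > 0
            if ref_seen and alt_seen:
                break
        if ref_seen and alt_seen:
            loci.append(SnpLocus(chrom, pos, ref, alt, "het", depth))
    return loci


def call_scaffold_alleles(
    scaffold,
    pileup: dict,
    loci: list[SnpLocus],
    library_id: str = "",
    min_reads: int = 2,
    het_min_each: int = 2,
    locus_positions: np.ndarray | None = None,
) -> ScaffoldCall:
    """Call one allele per informative locus inside a scaffold span.

    A locus is called het when both alleles have at least ``het_min_each``
    reads; 0 or 1 when one allele has at least ``min_reads`` and the other is
    below ``het_min_each``; missing otherwise. ``pileup`` maps
    ``(chrom, pos) -> (ref_count, alt_count)`` for this library.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if locus_positions is None:
        locus_positions = np.array([l.pos for l in loci], dtype=np.int64)
    # scaffold is half-open 0-based; loci are 1-based, so base i (0-based)
    # has pos i+1: inside iff start < pos <= end
    lo = int(np.searchsorted(locus_positions, scaffold.start, side="right"))
    hi = int(np.searchsorted(locus_positions, scaffold.end, side="right"))
    idx = np.arange(lo, hi, dtype=np.int64)
    alleles = np.full(len(idx), MISSING, dtype=np.int8)
    for k, i in enumerate(idx):
        locus = loci[i]
        rc, ac = pileup.get((locus.chrom, locus.pos), (0, 0))
        if rc >= het_min_each and ac >= het_min_each:
            alleles[k] = HET
        elif rc >= min_reads and ac < het_min_each:
            alleles[k] = REF
        elif ac >= min_reads and rc < het_min_each:
            alleles[k] = ALT
    return ScaffoldCall(scaffold, library_id, idx, alleles)


def filter_het_scaffolds(
    calls: list[ScaffoldCall],
    max_het_count: int = 3,
    max_het_fraction: float = 0.2,
) -> tuple[list[ScaffoldCall], list[ScaffoldCall]]:
    """Remove heterozygote-excess scaffolds; mask residual het positions.

    A scaffold is removed iff het_count > ``max_het_count`` OR het_fraction >
    ``max_het_fraction`` (both strict). Retained scaffolds have their het
    positions set to missing. ``max_het_count=0`` is the strict mode in which
    any het-containing scaffold is dropped.
    """
    if max_het_count < 0 or max_het_fraction < 0:
        raise ValueError("thresholds must be >= 0")
    retained, removed = [], []
    for call in calls:
        if call.het_count > max_het_count or call.het_fraction > max_het_fraction:
            removed.append(call)
        else:
            masked = call.alleles.copy()
            masked[masked == HET] = MISSING
            retained.append(ScaffoldCall(call.scaffold, call.library_id, call.locus_indices, masked))
    return retained, removed


def two_snp_haplotype_filter(
    calls: list[ScaffoldCall],
    n_loci: int,
) -> tuple[set[int], list[TwoSnpHaplotypeCount]]:
    """Drop adjacent locus pairs showing more than two two-locus haplotypes.

    For every originally adjacent pair (i, i+1), the distinct (allele_i,
    allele_{i+1}) combinations over scaffolds calling both loci are counted;
    a true diploid allows at most two. Pairs exceeding that mark *both* loci
    removed. Single pass over the original adjacency — pairs that become
    adjacent after removal are not re-tested — and scaffolds are retained.

    Returns the set of removed locus indices and the per-pair count table
    (pairs with at least one observed combination).
    """
    pair_sets: dict[int, set[tuple[int, int]]] = {}
    for call in calls:
        idx = call.locus_indices
        a = call.alleles
        for k in range(len(idx) - 1):
            if idx[k + 1] == idx[k] + 1 and a[k] in (REF, ALT) and a[k + 1] in (REF, ALT):
                pair_sets.setdefault(int(idx[k]), set()).add((int(a[k]), int(a[k + 1])))
    removed: set[int] = set()
    table = []
    for i in sorted(pair_sets):
        combos = pair_sets[i]
        table.append(TwoSnpHaplotypeCount((i, i + 1), combos))
        if len(combos) > 2:
            removed.update((i, i + 1))
    _ = n_loci  # adjacency is defined on the original locus indexing
    return removed, table


def expected_diploid_fraction(fraction: float, method: str = "exact") -> float:
    """Expected fraction of a library's sequence that is heterozygous.

    With each homologue independently sampled at per-haplotype fraction
    ``f``, the genome fraction present on both homologues is f²; relative to
    the library content (union, 2f − f²) that is

    * ``exact``:  f² / (2f − f²)  — e.g. f = 1/6 gives ~9.1 %.

    For fosmid pools specified by total library coverage ``c`` split evenly
    between homologues, the conventional estimator is

    * ``paper_approx``:  ((c/2)²) / c = c / 4  — e.g. c = 0.24 gives 6 %.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if method == "exact":
        f = fraction
        return f * f / (2 * f - f * f)
    if method == "paper_approx":
        return fraction / 4.0
    raise ValueError(f"unknown method {method!r}")


def expected_screen_positive_loci(
    n_loci: int,
    aliquot_fraction: float,
    method: str = "paper_approx",
) -> float:
    """Expected PCR-positive count when screening loci on one aliquot.

    An aliquot holds fraction ``f`` of each of the two chromosome copies.

    * ``paper_approx``: 2·f·n — the linear screening estimate (2 × 1/6 × 24
      = 8 positive reactions for the standard design).
    * ``exact``: (2f − f²)·n — inclusion–exclusion over the two copies.
    """
    if not 0 < aliquot_fraction <= 1:
        raise ValueError("aliquot_fraction must be in (0, 1]")
    f = aliquot_fraction
    if method == "paper_approx":
        return 2 * f * n_loci
    if method == "exact":
        return (2 * f - f * f) * n_loci
    raise ValueError(f"unknown method {method!r}")


def het_coverage_diagnostics(bulk_depths, library_het_counts) -> dict:
    """Regress bulk read depth on the number of het-calling libraries.

    A strong positive slope indicates copy-number-driven artifact
    heterozygotes: extra genomic copies both inflate bulk depth and let more
    libraries sample the locus. Returns OLS slope/intercept/r² plus a mean
    depth profile per library-count stratum.
    """
    y = np.asarray(bulk_depths, dtype=float)
    x = np.asarray(library_het_counts, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    profile = {}
    for v in np.unique(x):
        profile[int(v)] = float(np.mean(y[x == v]))
    if np.all(x == x[0]):
        return {"slope": None, "intercept": None, "r2": None, "degenerate": True, "profile": profile}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "degenerate": False,
        "profile": profile,
    }


def _fragment_blocks(call: ScaffoldCall, index_map: dict[int, int]) -> list[tuple[int, str]]:
    """Contiguous (start_index_1based, allele_string) blocks of one fragment.

    ``index_map`` maps original locus index to the 1-based retained-locus
    index; calls at removed loci are dropped first.
    """
    kept = [
        (index_map[int(i)], int(a))
        for i, a in zip(call.locus_indices, call.alleles)
        if a in (REF, ALT) and int(i) in index_map
    ]
    kept.sort()
    blocks: list[tuple[int, str]] = []
    for idx, a in kept:
        if blocks and idx == blocks[-1][0] + len(blocks[-1][1]):
            blocks[-1] = (blocks[-1][0], blocks[-1][1] + str(a))
        else:
            blocks.append((idx, str(a)))
    return blocks


def write_sih_input(
    calls: list[ScaffoldCall],
    loci: list[SnpLocus],
    removed_loci: set[int] | None = None,
    frag_path=None,
    allvars_path=None,
) -> tuple[list[str], list[str]]:
    """Emit fragment (``frag``) and locus (``allvars``) files for phasing.

    Removed loci are excluded from allvars and any calls at them silently
    dropped; fragments with fewer than two remaining called loci are omitted
    as uninformative. The frag dialect is whitespace-delimited
    ``B id s1 a1 s2 a2 ...`` with ``B`` contiguous blocks, ``s_i`` the
    1-based allvars index of the block's first locus and ``a_i`` a 0/1 allele
    string. allvars is TSV ``index chrom pos ref alt``.

    Returns (frag_lines, allvars_lines); optionally writes them to paths.
    """
    removed = removed_loci or set()
    retained = [i for i in range(len(loci)) if i not in removed]
    index_map = {orig: k + 1 for k, orig in enumerate(retained)}

    allvars_lines = [
        f"{index_map[i]}\t{loci[i].chrom}\t{loci[i].pos}\t{loci[i].ref_allele}\t{loci[i].alt_allele}"
        for i in retained
    ]
    frag_lines = []
    for call in calls:
        blocks = _fragment_blocks(call, index_map)
        if sum(len(b[1]) for b in blocks) < 2:
            continue
        fid = f"{call.library_id}:{getattr(call.scaffold, 'start', 0)}" if call.library_id else f"frag{len(frag_lines)}"
        parts = [str(len(blocks)), fid]
        for s, a in blocks:
            parts.extend([str(s), a])
        frag_lines.append(" ".join(parts))

    if frag_path is not None:
        with open(frag_path, "w") as fh:
            fh.write("\n".join(frag_lines) + ("\n" if frag_lines else ""))
    if allvars_path is not None:
        with open(allvars_path, "w") as fh:
            fh.write("\n".join(allvars_lines) + ("\n" if allvars_lines else ""))
    return frag_lines, allvars_lines
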