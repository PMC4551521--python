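"""Ground-truth diploid genomes and the dilution-library structures built on them.

The generators emulate the sample types of a direct-haplotyping experiment:

* a diploid chromosome carrying heterozygous SNPs (two complementary allele
  vectors over known positions), with repeat and copy-number tracks;
* *subcell* libraries — a single cell's lysate split into aliquots so each
  library holds a random ~1/6 fraction of each chromosome copy, whole-genome
  amplified with phi29-style highly skewed per-amplicon depth;
* *fosmid pool* libraries — a fixed number of 30–45 kb clones, each drawn
  from one haplotype.

Every generator is driven by a single :class:`numpy.random.Generator` seeded
per call, so an identical seed reproduces an identical realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import merge_intervals, union_length

__all__ = [
    "SimulationTruth",
    "LibraryRealization",
    "simulate_diploid_genome",
    "simulate_subcell_libraries",
    "simulate_fosmid_pools",
    "expected_fosmid_coverage",
]


@dataclass
class SimulationTruth:
    """Ground truth for one simulated diploid chromosome.

    ``hap0``/``hap1`` are binary allele vectors (0 = ref, 1 = alt) over
    ``snp_positions``; every simulated SNP is heterozygous in the bulk
    individual, so ``hap1 = 1 - hap0`` everywhere.
    """

    chrom_name: str
    chrom_length: int
    snp_positions: np.ndarray
    hap0: np.ndarray
    hap1: np.ndarray
    repeat_track: list[tuple[int, int]] = field(default_factory=list)
    cnv_track: list[tuple[int, int, int]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.snp_positions, dtype=np.int64)
        if len(pos) and (np.any(np.diff(pos) <= 0) or pos[-1] >= self.chrom_length or pos[0] < 0):
            raise ValueError("snp_positions must be strictly increasing and < chrom_length")
        if len(self.hap0) != len(pos) or len(self.hap1) != len(pos):
            raise ValueError("haplotype vectors must match snp_positions")
        if np.any(np.asarray(self.hap0) == np.asarray(self.hap1)):
            raise ValueError("all simulated SNPs must be heterozygous (hap0 != hap1)")
        self.snp_positions = pos
        self.hap0 = np.asarray(self.hap0, dtype=np.int8)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)


@dataclass
class LibraryRealization:
    """One sequencing library: template segments, read footprint, pileups.

    ``covered_segments`` maps haplotype index (0/1) to the merged intervals of
    template actually present in the library; ``read_intervals`` is the mapped
    read footprint; ``pileups`` holds per-SNP ref/alt read counts (arrays
    aligned with the truth's ``snp_positions``).
    """

    library_id: str
    source: str  # {"subcell", "sperm", "fosmid_pool"}
    covered_segments: dict[int, list[tuple[int, int]]]
    read_intervals: list[tuple[int, int]]
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    seed: int | None = None

    @property
    def covered_fraction_numerator(self) -> int:
        """Bases covered by the union of both haplotypes' template segments."""
        return union_length(self.covered_segments.get(0, []) + self.covered_segments.get(1, []))


def _random_track(
    rng: np.random.Generator,
    chrom_length: int,
    target_fraction: float,
    mean_len: float,
) -> list[tuple[int, int]]:
    """Random interval track whose merged length approximates a target fraction.

    Exponential lengths, uniform starts; intervals are added until the merged
    union first reaches the target. The overshoot is at most one interval, so
    the realized fraction tracks the target closely when mean_len << length.
    """
    target = target_fraction * chrom_length
    track: list[tuple[int, int]] = []
    covered = 0
    while covered < target:
        n = max(16, int((target - covered) / max(mean_len, 1.0)))
        lens = np.maximum(1, rng.exponential(mean_len, size=n).astype(np.int64))
        starts = rng.integers(0, chrom_length, size=n)
        for s, ln in zip(starts, lens):
            track.append((int(s), int(min(s + ln, chrom_length))))
            covered += min(int(ln), chrom_length - int(s))
            if covered >= target:
                break
        track = merge_intervals(track)
        covered = sum(e - s for s, e in track)
    return track


def simulate_diploid_genome(
    chrom_length: int,
    n_snps: int,
    repeat_fraction: float = 0.0,
    seed: int = 0,
    *,
    chrom_name: str = "chrSim",
    repeat_mean_len: float = 229.0,
    cnv_fraction: float = 0.0,
    cnv_mean_len: float = 30_000.0,
    cnv_copies: int = 3,
) -> SimulationTruth:
    """Simulate one diploid chromosome with fully heterozygous SNP truth.

    Parameters
    ----------
    chrom_length : int
        Chromosome size in bp.
    n_snps : int
        Number of heterozygous SNP loci to place (uniform without replacement).
    repeat_fraction : float
        Target fraction of the chromosome in the repeat track, in ``[0, 1)``.
        The default repeat element mean length (229 bp) matches typical
        RepeatMasker element sizes in mammalian genomes.
    cnv_fraction : float, keyword-only
        Fraction of the chromosome inside multi-copy (CNV) regions; loci in
        these regions later pick up reads from collapsed paralogous copies.
    seed : int
        Reproducibility seed; identical seeds give bit-identical truths.
    """
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    if n_snps > chrom_length:
        raise ValueError("n_snps cannot exceed chrom_length")
    if not 0 <= repeat_fraction < 1:
        raise ValueError("repeat_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    positions = np.sort(rng.choice(chrom_length, size=n_snps, replace=False)) if n_snps else np.array([], dtype=np.int64)
    hap0 = rng.integers(0, 2, size=n_snps).astype(np.int8)
    hap1 = (1 - hap0).astype(np.int8)

    repeat_track = (
        _random_track(rng, chrom_length, repeat_fraction, repeat_mean_len) if repeat_fraction > 0 else []
    )
    cnv_track = []
    if cnv_fraction > 0:
        cnv_track = [
            (s, e, cnv_copies) for s, e in _random_track(rng, chrom_length, cnv_fraction, cnv_mean_len)
        ]

    return SimulationTruth(
        chrom_name=chrom_name,
        chrom_length=int(chrom_length),
        snp_positions=positions.astype(np.int64),
        hap0=hap0,
        hap1=hap1,
        repeat_track=repeat_track,
        cnv_track=cnv_track,
        seed=seed,
    )


def _fragment_chromosome(rng: np.random.Generator, chrom_length: int, mean_len: float) -> list[tuple[int, int]]:
    """Cut [0, chrom_length) at Poisson breakpoints (exponential piece lengths)."""
    cuts = [0]
    pos = 0.0
    while True:
        pos += rng.exponential(mean_len)
        if pos >= chrom_length:
            break
        cuts.append(int(pos))
    cuts.append(chrom_length)
    return [(a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]


def _pileup_from_reads(
    truth: SimulationTruth,
    reads_by_hap: dict[int, np.ndarray],
    rng: np.random.Generator,
    error_rate: float,
    cnv_boost: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ref/alt counts implied by per-haplotype read start arrays.

    ``reads_by_hap[h]`` holds (start, end) rows of reads amplified from
    haplotype ``h``. With ``error_rate`` > 0 each covering read flips its
    allele independently. Loci inside CNV regions receive additional reads of
    the *other* haplotype's allele (collapsed paralogs mapping to one locus)
    at ``cnv_boost`` times the local depth.
    """
    n = truth.n_snps
    ref = np.zeros(n, dtype=np.int64)
    alt = np.zeros(n, dtype=np.int64)
    if n == 0:
        return ref, alt

    pos = truth.snp_positions
    depth_by_hap = {}
    for h, reads in reads_by_hap.items():
        if len(reads) == 0:
            depth_by_hap[h] = np.zeros(n, dtype=np.int64)
            continue
        starts = np.sort(reads[:, 0])
        ends = np.sort(reads[:, 1])
        # reads covering pos p: starts <= p < ends
        cov = np.searchsorted(starts, pos, side="right") - np.searchsorted(ends, pos, side="right")
        depth_by_hap[h] = cov.astype(np.int64)

    hap_alleles = {0: truth.hap0, 1: truth.hap1}
    counts_by_allele_source: dict[int, np.ndarray] = {}
    for h in (0, 1):
        cov = depth_by_hap.get(h, np.zeros(n, dtype=np.int64))
        counts_by_allele_source[h] = cov

    # CNV: paralogous copies contribute the opposite allele wherever covered
    if truth.cnv_track and cnv_boost > 0:
        in_cnv = np.zeros(n, dtype=bool)
        for s, e, _copies in truth.cnv_track:
            in_cnv |= (pos >= s) & (pos < e)
        for h in (0, 1):
            cov = counts_by_allele_source[h]
            extra = np.zeros(n, dtype=np.int64)
            mask = in_cnv & (cov > 0)
            extra[mask] = rng.poisson(np.maximum(cov[mask] * cnv_boost, 1.0))
            # extra reads carry the OTHER haplotype's allele
            other = 1 - h
            a_other = hap_alleles[other]
            ref += np.where(a_other == 0, extra, 0)
            alt += np.where(a_other == 1, extra, 0)

    for h in (0, 1):
        cov = counts_by_allele_source[h]
        a = hap_alleles[h]
        if error_rate > 0:
            flips = rng.binomial(cov, error_rate)
            keep = cov - flips
            ref += np.where(a == 0, keep, flips)
            alt += np.where(a == 1, keep, flips)
        else:
            ref += np.where(a == 0, cov, 0)
            alt += np.where(a == 1, cov, 0)
    return ref, alt


def _sample_reads(
    rng: np.random.Generator,
    segments: list[tuple[int, int]],
    depth_multipliers: np.ndarray,
    mean_depth: float,
    read_length: int,
) -> np.ndarray:
    """Fixed-length reads placed uniformly within each template segment."""
    rows = []
    for (s, e), mult in zip(segments, depth_multipliers):
        seg_len = e - s
        if seg_len < read_length:
            continue
        lam = mean_depth * mult * seg_len / read_length
        n_reads = rng.poisson(lam)
        if n_reads == 0:
            continue
        starts = rng.integers(s, e - read_length + 1, size=n_reads)
        rows.append(np.column_stack([starts, starts + read_length]))
    if not rows:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(rows).astype(np.int64)


def simulate_subcell_libraries(
    truth: SimulationTruth,
    n_cells: int,
    aliquots_per_cell: int = 6,
    aliquot_fraction: float = 1 / 6,
    amplicon_mean_len: float = 30_000.0,
    coverage_skew: float = 1.0,
    mean_depth: float = 10.0,
    seed: int = 0,
    *,
    read_length: int = 100,
    error_rate: float = 0.0,
    cnv_boost: float = 1.0,
) -> list[LibraryRealization]:
    """Simulate subcell (diluted single-cell) libraries.

    Each cell's two chromosome copies are fragmented at Poisson breakpoints
    into amplicons of mean length ``amplicon_mean_len`` (the lysis/phi29
    product scale), and each of ``aliquots_per_cell`` aliquots independently
    receives each amplicon with probability ``aliquot_fraction``. Amplified
    depth per amplicon is ``mean_depth`` times a log-normal multiplier with
    shape ``coverage_skew`` (unit mean), so the pooled coverage histogram is
    over-dispersed relative to a Poisson of the same mean; ``coverage_skew=0``
    recovers the unskewed limit.
    """
    if not 0 < aliquot_fraction <= 1:
        raise ValueError("aliquot_fraction must be in (0, 1]")
    if aliquots_per_cell < 1:
        raise ValueError("aliquots_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    libraries: list[LibraryRealization] = []

    for cell in range(n_cells):
        amplicons = {h: _fragment_chromosome(rng, truth.chrom_length, amplicon_mean_len) for h in (0, 1)}
        for aliquot in range(aliquots_per_cell):
            segs: dict[int, list[tuple[int, int]]] = {0: [], 1: []}
            reads_by_hap: dict[int, np.ndarray] = {}
            for h in (0, 1):
                present = rng.random(len(amplicons[h])) < aliquot_fraction
                chosen = [seg for seg, p in zip(amplicons[h], present) if p]
                segs[h] = merge_intervals(chosen)
                if coverage_skew > 0:
                    sigma = coverage_skew
                    mult = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(chosen))
                else:
                    mult = np.ones(len(chosen))
                reads_by_hap[h] = _sample_reads(rng, chosen, mult, mean_depth, read_length)
            all_reads = np.concatenate([reads_by_hap[0], reads_by_hap[1]]) if truth.chrom_length else np.empty((0, 2))
            all_reads = all_reads[np.lexsort((all_reads[:, 1], all_reads[:, 0]))]
            ref, alt = _pileup_from_reads(truth, reads_by_hap, rng, error_rate, cnv_boost)
            libraries.append(
                LibraryRealization(
                    library_id=f"cell{cell}_aliquot{aliquot}",
                    source="subcell",
                    covered_segments=segs,
                    read_intervals=[(int(s), int(e)) for s, e in all_reads],
                    ref_counts=ref,
                    alt_counts=alt,
                    seed=seed,
                )
            )
    return libraries


def simulate_fosmid_pools(
    truth: SimulationTruth,
    clones_per_library: int,
    insert_min: int = 30_000,
    insert_max: int = 45_000,
    mean_depth: float = 10.0,
    seed: int = 0,
    *,
    n_libraries: int = 1,
    read_length: int = 100,
    error_rate: float = 0.0,
) -> list[LibraryRealization]:
    """Simulate fosmid-pool libraries.

    Each clone is a single interval drawn from one randomly chosen haplotype
    with length uniform on ``[insert_min, insert_max]`` and uniform placement.
    Depth over clones is unskewed (cloned template, no phi29 amplification).
    """
    if insert_min > insert_max:
        raise ValueError("insert_min must be <= insert_max")
    rng = np.random.default_rng(seed)
    libraries = []
    for lib in range(n_libraries):
        segs: dict[int, list[tuple[int, int]]] = {0: [], 1: []}
        raw: dict[int, list[tuple[int, int]]] = {0: [], 1: []}
        for _ in range(clones_per_library):
            h = int(rng.integers(0, 2))
            ln = int(rng.integers(insert_min, insert_max + 1))
            ln = min(ln, truth.chrom_length)
            s = int(rng.integers(0, truth.chrom_length - ln + 1))
            raw[h].append((s, s + ln))
        reads_by_hap = {}
        for h in (0, 1):
            segs[h] = merge_intervals(raw[h])
            mult = np.ones(len(raw[h]))
            reads_by_hap[h] = _sample_reads(rng, raw[h], mult, mean_depth, read_length)
        all_reads = np.concatenate([reads_by_hap[0], reads_by_hap[1]])
        all_reads = all_reads[np.lexsort((all_reads[:, 1], all_reads[:, 0]))]
        ref, alt = _pileup_from_reads(truth, reads_by_hap, rng, error_rate, cnv_boost=0.0)
        libraries.append(
            LibraryRealization(
                library_id=f"fosmid_pool{lib}",
                source="fosmid_pool",
                covered_segments=segs,
                read_intervals=[(int(s), int(e)) for s, e in all_reads],
                ref_counts=ref,
                alt_counts=alt,
                seed=seed,
            )
        )
    return libraries


def expected_fosmid_coverage(clones_per_library: int, mean_insert_len: float, genome_length: float) -> float:
    """Expected haploid genome coverage of one fosmid pool: n·L̄ / G.

    This is the linear (non-overlap-corrected) expectation used when sizing
    pools, e.g. 18,000 clones of mean 40 kb on a 3 Gb genome -> 0.24.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return clones_per_library * mean_insert_len / genome_length
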