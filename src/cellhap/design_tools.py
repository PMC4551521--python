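"""Experimental-design tools: haplotype-coverage simulation and cost model.

The simulator answers the design question "what fraction of a population's
haplotypes would be captured whole by at least one sequencing scaffold?"
Population haplotype lengths are exponential (cattle-like mean 10 kb) and
tiled end-to-end across an average-size chromosome (86 Mb); scaffolds with
exponential lengths are placed uniformly until a target coverage depth is
reached, and a haplotype counts as captured only when a single scaffold
contains it entirely. The primary metric is length-weighted: the percentage
of the chromosome lying in fully covered haplotypes.

The cost model trades off library construction against sequencing reagents:
more dilute libraries carry less template each, so more libraries are needed
to reach a target scaffold coverage of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, exp

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "CoverageSimConfig",
    "CostModel",
    "simulate_haplotype_coverage",
    "analytic_haplotype_coverage",
    "coverage_table",
    "het_detection_probability",
    "project_cost",
]


@dataclass
class CoverageSimConfig:
    """Parameters of the haplotype-coverage simulation.

    Defaults: an 86 Mb chromosome (mean cattle autosome) tiled with
    haplotypes of exponential mean 10 kb (linkage-disequilibrium scale in
    cattle), 10 replicates.
    """

    chrom_length: int = 86_000_000
    hap_mean: float = 10_000.0
    scaffold_mean: float = 10_000.0
    coverage_depth: float = 10.0
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chrom_length, self.hap_mean, self.scaffold_mean, self.replicates) <= 0:
            raise ValueError("chrom_length, hap_mean, scaffold_mean, replicates must be positive")
        if self.coverage_depth < 0:
            raise ValueError("coverage_depth must be >= 0")


@dataclass
class CostModel:
    """Unit costs and targets for a dilution-haplotyping project."""

    library_cost: float = 75.0
    seq_cost_per_100Gb: float = 6000.0
    genome_size: float = 3.0e9
    genome_fraction_per_library: float = 1 / 3
    target_scaffold_coverage: float = 4.0
    target_read_depth_over_scaffolds: float = 4.0

    def __post_init__(self) -> None:
        if self.library_cost < 0 or self.seq_cost_per_100Gb < 0:
            raise ValueError("costs must be non-negative")
        if not 0 < self.genome_fraction_per_library <= 1:
            raise ValueError("genome_fraction_per_library must be in (0, 1]")


def _one_replicate(cfg: CoverageSimConfig, rng: np.random.Generator) -> float:
    C = cfg.chrom_length
    # tile haplotypes end to end; the final (truncated) one is excluded from
    # the denominator
    n_guess = int(C / cfg.hap_mean * 1.3) + 16
    lens = rng.exponential(cfg.hap_mean, size=n_guess)
    while lens.sum() < C:
        lens = np.concatenate([lens, rng.exponential(cfg.hap_mean, size=n_guess)])
    bounds = np.cumsum(lens)
    n_full = int(np.searchsorted(bounds, C))
    if n_full == 0 or cfg.coverage_depth == 0:
        return 0.0
    hap_ends = bounds[:n_full]
    hap_starts = np.concatenate([[0.0], hap_ends[:-1]])
    denom = float(hap_ends[-1])

    target = cfg.coverage_depth * C
    n_scaff = int(target / cfg.scaffold_mean) + 1
    slens = rng.exponential(cfg.scaffold_mean, size=n_scaff)
    short = target - slens.sum()
    while short > 0:
        extra = rng.exponential(cfg.scaffold_mean, size=max(16, int(short / cfg.scaffold_mean) + 1))
        slens = np.concatenate([slens, extra])
        short = target - slens.sum()
    cum = np.cumsum(slens)
    slens = slens[: int(np.searchsorted(cum, target)) + 1]
    slens = np.minimum(slens, C)
    starts = rng.uniform(0, C - slens)
    ends = starts + slens

    order = np.argsort(starts, kind="stable")
    sorted_starts = starts[order]
    prefix_max_end = np.maximum.accumulate(ends[order])
    # haplotype [a, b) covered iff some scaffold has start <= a and end >= b
    idx = np.searchsorted(sorted_starts, hap_starts, side="right") - 1
    ok = idx >= 0
    covered = np.zeros(n_full, dtype=bool)
    covered[ok] = prefix_max_end[idx[ok]] >= hap_ends[ok]
    return 100.0 * float(np.sum((hap_ends - hap_starts)[covered])) / float(denom)


def simulate_haplotype_coverage(config: CoverageSimConfig, return_replicates: bool = False):
    """Percent of chromosome length in haplotypes fully covered by a scaffold.

    Averaged over ``config.replicates`` independent realizations; seeded and
    deterministic. With ``return_replicates=True`` the per-replicate values
    are returned alongside the mean.
    """
    rng = np.random.default_rng(config.seed)
    vals = np.array([_one_replicate(config, rng) for _ in range(config.replicates)])
    if return_replicates:
        return float(vals.mean()), vals
    return float(vals.mean())


def analytic_haplotype_coverage(hap_mean: float, scaffold_mean: float, coverage_depth: float) -> float:
    """Closed-form expectation for the simulated percentage.

    A haplotype of length L is covered by one uniformly placed exponential
    scaffold with probability m·e^(−L/m)/C, so with total scaffold length
    c·C the chance at least one covers it is ≈ 1 − exp(−c·e^(−L/m)).
    Weighting by the length-biased haplotype density (L/h²)e^(−L/h) gives
    the expected percentage of chromosome length in covered haplotypes.
    """
    if coverage_depth == 0:
        return 0.0
    h, m, c = hap_mean, scaffold_mean, coverage_depth

    def integrand(L: float) -> float:
        return (L / h**2) * exp(-L / h) * (1.0 - exp(-c * exp(-L / m)))

    val, _err = integrate.quad(integrand, 0, 60 * max(h, m), limit=200)
    return 100.0 * val


def coverage_table(
    scaffold_means,
    coverages,
    config: CoverageSimConfig | None = None,
) -> pd.DataFrame:
    """Grid of simulated coverage percentages (rows: scaffold mean, cols: depth)."""
    if len(scaffold_means) == 0 or len(coverages) == 0:
        raise ValueError("grids must be non-empty")
    cfg = config or CoverageSimConfig()
    out = np.zeros((len(scaffold_means), len(coverages)))
    for i, m in enumerate(scaffold_means):
        for j, c in enumerate(coverages):
            cell_cfg = CoverageSimConfig(
                chrom_length=cfg.chrom_length,
                hap_mean=cfg.hap_mean,
                scaffold_mean=float(m),
                coverage_depth=float(c),
                replicates=cfg.replicates,
                # independent but reproducible stream per cell
                seed=cfg.seed + 100_003 * i + 101 * j,
            )
            out[i, j] = simulate_haplotype_coverage(cell_cfg)
    return pd.DataFrame(out, index=list(scaffold_means), columns=list(coverages))


def het_detection_probability(read_depth: float, model: str = "fixed_binomial_min1", k: int = 2) -> float:
    """Probability that uniform read depth reveals a heterozygous locus.

    * ``fixed_binomial_min1`` — exactly ``read_depth`` reads, each allele
      drawn fairly; detection requires both alleles seen at least once:
      1 − 2·(1/2)^depth. Integer depth only.
    * ``poisson_min_k`` — the minor allele receives Poisson(depth/2) reads
      and must be seen at least ``k`` times.
    """
    if read_depth < 0:
        raise ValueError("read_depth must be >= 0")
    if model == "fixed_binomial_min1":
        if read_depth != int(read_depth):
            raise ValueError("fixed_binomial_min1 requires integer depth")
        d = int(read_depth)
        if d == 0:
            return 0.0
        return 1.0 - 2.0 * 0.5**d
    if model == "poisson_min_k":
        return float(stats.poisson.sf(k - 1, read_depth / 2.0))
    raise ValueError(f"unknown model {model!r}")


def project_cost(model: CostModel) -> dict:
    """Library count, sequence yield and total cost for a target design.

    A library holding per-haplotype fraction f of the genome covers
    2f − f² of it with scaffolds, so n_libraries = ceil(target scaffold
    coverage / (2f − f²)). Total sequence is genome_size × read depth over
    scaffolds × scaffold coverage; both cost terms are linear.
    """
    f = model.genome_fraction_per_library
    per_library_coverage = 2 * f - f * f
    n_libraries = int(ceil(model.target_scaffold_coverage / per_library_coverage))
    total_gb = (
        model.genome_size
        * model.target_read_depth_over_scaffolds
        * model.target_scaffold_coverage
        / 1e9
    )
    library_cost_total = n_libraries * model.library_cost
    seq_cost_total = total_gb * model.seq_cost_per_100Gb / 100.0
    return {
        "n_libraries": n_libraries,
        "per_library_scaffold_coverage": per_library_coverage,
        "total_Gb": total_gb,
        "library_cost_total": library_cost_total,
        "seq_cost_total": seq_cost_total,
        "grand_total": library_cost_total + seq_cost_total,
    }
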