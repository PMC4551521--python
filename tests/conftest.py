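"""Shared fixtures: one clean and one CNV-contaminated simulated experiment.

The standard study conditions are 31 subcell libraries (six cells split into
six 1/6-aliquots each, first 31 kept), ~1 SNP per kb, phi29-style skewed
amplification at mean depth 10 over a 2 Mb chromosome. Session-scoped so the
end-to-end runs happen once.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellhap import pipeline, synthetic_data

CHROM_LEN = 2_000_000
N_SNPS = 2_000
N_LIBRARIES = 31


@pytest.fixture(scope="session")
def clean_truth():
    return synthetic_data.simulate_diploid_genome(CHROM_LEN, N_SNPS, seed=11)


@pytest.fixture(scope="session")
def clean_libraries(clean_truth):
    libs = synthetic_data.simulate_subcell_libraries(
        clean_truth, n_cells=6, aliquots_per_cell=6, aliquot_fraction=1 / 6,
        coverage_skew=1.0, mean_depth=10.0, seed=12,
    )
    return libs[:N_LIBRARIES]


@pytest.fixture(scope="session")
def clean_result(clean_truth, clean_libraries):
    return pipeline.run_pipeline(clean_truth, clean_libraries, seed=13)


@pytest.fixture(scope="session")
def cnv_truth():
    return synthetic_data.simulate_diploid_genome(
        CHROM_LEN, N_SNPS, seed=21, cnv_fraction=0.08, cnv_mean_len=30_000,
    )


@pytest.fixture(scope="session")
def cnv_libraries(cnv_truth):
    libs = synthetic_data.simulate_subcell_libraries(
        cnv_truth, n_cells=6, aliquots_per_cell=6, aliquot_fraction=1 / 6,
        coverage_skew=1.0, mean_depth=10.0, seed=22, cnv_boost=1.0,
    )
    return libs[:N_LIBRARIES]


@pytest.fixture(scope="session")
def cnv_result(cnv_truth, cnv_libraries):
    return pipeline.run_pipeline(cnv_truth, cnv_libraries, seed=23)


def called_locus_set(calls) -> set[int]:
    """Loci carrying at least one usable (0/1) allele call."""
    out: set[int] = set()
    for c in calls:
        for i, a in zip(c.locus_indices, c.alleles):
            if a in (0, 1):
                out.add(int(i))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
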