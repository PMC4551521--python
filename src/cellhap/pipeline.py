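"""End-to-end orchestration: simulated libraries -> scaffolds -> phased blocks.

Thin glue over the stage modules for the common whole-pipeline run; each
stage remains independently usable. Mirrors the CLI flow but works on
in-memory objects, which is what the test-bench and worked examples use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import phase_prep, phaser, scaffolding, validation
from .phase_prep import ScaffoldCall, SnpLocus
from .phaser import FragmentMatrix, HaplotypeBlock
from .synthetic_data import LibraryRealization, SimulationTruth

__all__ = ["PipelineResult", "informative_from_counts", "run_pipeline"]


@dataclass
class PipelineResult:
    loci: list[SnpLocus]
    informative_snp_indices: np.ndarray  # into truth.snp_positions
    calls: list[ScaffoldCall]
    retained_calls: list[ScaffoldCall]
    removed_calls: list[ScaffoldCall]
    removed_loci: set[int]
    fragment_matrix: FragmentMatrix | None
    blocks: list[HaplotypeBlock]
    retained_index_map: dict[int, int] = field(default_factory=dict)

    def reference_phase(self, truth: SimulationTruth) -> dict[int, int]:
        """Truth hap0 alleles keyed by retained 1-based locus index."""
        hap0 = truth.hap0[self.informative_snp_indices]
        return {k: int(hap0[orig]) for orig, k in self.retained_index_map.items()}


def informative_from_counts(libraries: list[LibraryRealization]) -> np.ndarray:
    """Boolean mask over truth loci: both alleles seen across libraries.

    All simulated truth loci are bulk-het, so informativeness reduces to
    both alleles being represented somewhere in the dilution libraries.
    """
    n = len(libraries[0].ref_counts)
    ref_any = np.zeros(n, dtype=bool)
    alt_any = np.zeros(n, dtype=bool)
    for lib in libraries:
        ref_any |= lib.ref_counts > 0
        alt_any |= lib.alt_counts > 0
    return ref_any & alt_any


def run_pipeline(
    truth: SimulationTruth,
    libraries: list[LibraryRealization],
    max_gap: int = 1000,
    max_het_count: int = 3,
    max_het_fraction: float = 0.2,
    min_reads: int = 2,
    het_min_each: int = 2,
    restarts: int = 20,
    seed: int = 0,
) -> PipelineResult:
    """Run contig building through haplotype assembly on simulated libraries."""
    informative = informative_from_counts(libraries)
    inf_idx = np.flatnonzero(informative)
    loci = [
        SnpLocus(truth.chrom_name, int(p) + 1, "A", "C")
        for p in truth.snp_positions[informative]
    ]
    positions = np.array([l.pos for l in loci], dtype=np.int64)

    calls: list[ScaffoldCall] = []
    for lib in libraries:
        pileup = {}
        for k, i in enumerate(inf_idx):
            rc, ac = int(lib.ref_counts[i]), int(lib.alt_counts[i])
            if rc or ac:
                pileup[(truth.chrom_name, int(truth.snp_positions[i]) + 1)] = (rc, ac)
        contigs = scaffolding.build_contigs(sorted(lib.read_intervals), chrom=truth.chrom_name)
        for scaf in scaffolding.join_contigs(contigs, max_gap, library_id=lib.library_id):
            call = phase_prep.call_scaffold_alleles(
                scaf, pileup, loci, library_id=lib.library_id,
                min_reads=min_reads, het_min_each=het_min_each,
                locus_positions=positions,
            )
            if call.n_called:
                calls.append(call)

    retained, removed = phase_prep.filter_het_scaffolds(calls, max_het_count, max_het_fraction)
    removed_loci, _table = phase_prep.two_snp_haplotype_filter(retained, len(loci))
    frag_lines, _allvars = phase_prep.write_sih_input(retained, loci, removed_loci)

    retained_orig = [i for i in range(len(loci)) if i not in removed_loci]
    index_map = {orig: k + 1 for k, orig in enumerate(retained_orig)}

    matrix = None
    blocks: list[HaplotypeBlock] = []
    if frag_lines:
        fragments = []
        for line in frag_lines:
            parts = line.split()
            n_blocks, fid = int(parts[0]), parts[1]
            fcalls: dict[int, int] = {}
            cursor = 2
            for _ in range(n_blocks):
                start, alleles = int(parts[cursor]), parts[cursor + 1]
                cursor += 2
                for off, ch in enumerate(alleles):
                    fcalls[start + off] = int(ch)
            fragments.append((fid, fcalls))
        matrix = FragmentMatrix(n_loci=len(retained_orig), fragments=fragments)
        blocks = phaser.phase(matrix, restarts=restarts, seed=seed)

    return PipelineResult(
        loci=loci,
        informative_snp_indices=inf_idx,
        calls=calls,
        retained_calls=retained,
        removed_calls=removed,
        removed_loci=removed_loci,
        fragment_matrix=matrix,
        blocks=blocks,
        retained_index_map=index_map,
    )
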