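# cellhap

Tools for **direct haplotype sequencing of diploid genomes** from diluted
single-cell (subcell) and fosmid-pool sequencing libraries.

Standard resequencing collapses the two copies of a diploid genome into one
composite consensus, losing the phase between heterozygous alleles. A cheap
way to recover phase is to split the lysate of a single cell into aliquots so
that each sequencing library contains a random fraction (~1/6) of each
chromosome copy: most genomic regions in a library then derive from only one
homologue, and overlapping libraries can be stitched into chromosome-scale
haplotypes. `cellhap` implements the data-analysis side of that experiment:

* **synthetic_data** — simulate a diploid chromosome with heterozygous SNPs,
  subcell aliquots with phi29-style (MDA) skewed amplification, fosmid pools,
  and repeat/CNV tracks, so the whole pipeline is testable without any
  external data;
* **scaffolding** — build contigs from mapped-read intervals, join nearby
  contigs into scaffolds (fixed or adaptive μ + kσ gap threshold, or a
  windowed read-depth run finder), gap and coverage-vs-Poisson diagnostics,
  N50/length summaries;
* **repeat_filter** — classify scaffolds by repeat overlap against a
  random-placement null and drop scaffolds wholly inside repeats;
* **phase_prep** — select informative SNPs (bulk-heterozygous, both alleles
  seen across libraries), call scaffold alleles from pileups, remove
  heterozygote-excess scaffolds and CNV-like adjacent locus pairs, and emit
  `frag`/`allvars` input for phasing;
* **phaser** — single-individual haplotype assembly: a max-cut style greedy
  bipartition of fragments with MEC (minimum error correction) polishing,
  plus an exhaustive small-instance solver used as an oracle;
* **validation** — consistency and switch-consistency metrics between
  scaffolds, against reference haplotypes, gene containment and
  missense-pair phasing rates;
* **design_tools** — experimental-design simulator (what fraction of
  population haplotypes is captured whole by scaffolds, for a given scaffold
  length and coverage) and a library-count/sequencing cost calculator.

## The core quantities

With each homologue independently present at fraction *f* in a library, the
genome fraction present on **both** homologues is *f*², which is
*f*²/(2*f* − *f*²) of the library content (*f* = 1/6 gives ~9% — the expected
rate of true heterozygous calls inside one library). Two scaffolds from the
same individual over shared heterozygous loci must agree everywhere or
disagree everywhere, so **consistency** is max(%same, %different); runs of
≥2 out-of-phase loci are **switch errors** and are disregarded by the
**switch consistency**, which counts only isolated interior discrepancies.
The phaser minimises **MEC**: the number of allele flips needed to make every
fragment consistent with one of two complementary haplotypes.

## Worked example

```python
import numpy as np
from cellhap import synthetic_data, pipeline, validation, phaser

truth = synthetic_data.simulate_diploid_genome(
    chrom_length=2_000_000, n_snps=2_000, seed=11)
libraries = synthetic_data.simulate_subcell_libraries(
    truth, n_cells=6, aliquots_per_cell=6, aliquot_fraction=1/6,
    coverage_skew=1.0, mean_depth=10.0, seed=12)[:31]

result = pipeline.run_pipeline(truth, libraries, seed=13)
agg, pairs = validation.all_pairs_consistency(result.retained_calls)
rep = validation.compare_to_reference(result.blocks, result.reference_phase(truth))
```

Output on this simulation (31 libraries of 1/6-aliquots, mean depth 10,
log-normal coverage skew σ = 1):

```
informative loci: 1940
scaffold calls: 449 (het-filtered: 68, loci dropped: 4)
scaffold self-consistency: 0.995 (switch: 0.999) over 1892 pairs
blocks: 1, total MEC: 196
vs truth: consistency 0.780, switch consistency 0.998
```

Reading: 1,940 of 2,000 simulated SNPs had both alleles observed across
libraries; overlapping scaffolds from different libraries agree at 99.5% of
shared loci. The phased block-vs-truth *switch* consistency is 0.998 — the
raw consistency is much lower because scaffolds that bridge amplicons from
different homologues introduce phase switches, which is exactly the error
mode the switch metric is designed to isolate. The experimental-design
simulator complements this: e.g. 30 kb scaffolds at 10× scaffold coverage
are expected to capture ~98% of 10 kb-scale population haplotypes whole.

A CLI mirrors the library:

```bash
cellhap simulate-data --config sim.yaml --seed 5 --outdir data/
cellhap scaffold --reads data/reads_cell0_aliquot0.bed --max-gap 1000 --out s.gff3
cellhap filter-repeats --scaffolds s.gff3 --repeats data/repeats.bed --seed 1 --out kept.gff3
cellhap prep-phase --vcf data/bulk.vcf --pileups data/pileups.tsv --scaffolds all.gff3 --outdir prep/
cellhap phase --frag prep/input.frag --allvars prep/input.allvars --seed 2 --out phased.tsv
cellhap validate --blocks phased.tsv --truth data/truth.tsv
cellhap simulate-coverage --scaffold-means 10000,30000 --coverages 2,10,20 --seed 3
cellhap cost
```

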