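# Methods

## The experiment being modelled

A single diploid cell is lysed and split into six aliquots, each expected to
contain ~1/6 of each of the two chromosome copies; each aliquot is whole
genome amplified with phi29 polymerase (multiple displacement amplification,
MDA) and sequenced as one library. Because any one region is usually present
in a library on at most one homologue, mapped reads cluster into
single-haplotype islands. The pipeline turns those islands into scaffolds,
calls one allele per informative SNP per scaffold, filters artifacts, and
assembles the scaffolds' allele vectors into two complementary haplotypes.
Fosmid pools (fixed clone counts of 30–45 kb inserts, each insert from one
homologue) are handled by the same machinery.

## Synthetic data generator

`synthetic_data` defines the study conditions used throughout the tests.

* **Truth.** One chromosome (default tests use 2 Mb with 2,000 SNPs — about
  one heterozygous SNP per kb, a cattle-like density). Every simulated SNP is
  heterozygous in the bulk individual; `hap1` is the complement of `hap0`.
* **Amplicon segmentation.** Each cell's chromosome copies are cut at
  Poisson breakpoints with mean segment length `amplicon_mean_len` = 30 kb.
  The experiment does not fix a fragment-length law (observed scaffold sizes
  reflect a mixture of shearing and polymerase product lengths); the
  exponential-piece model is the simplest memoryless choice and its mean is
  a tunable.
* **Aliquoting.** Each aliquot receives each amplicon independently with
  probability `aliquot_fraction` (default 1/6). Per base this gives coverage
  probability 2f − f² ≈ 0.306 for f = 1/6.
* **Coverage skew.** MDA from trace template is strongly over-dispersed but
  no parametric form is established; per-amplicon depth is `mean_depth`
  times a unit-mean log-normal multiplier with shape `coverage_skew`
  (default 1.0, giving the heavy left-and-right-tailed pooled histogram;
  0 recovers a Poisson profile). This is a stand-in, not a claim about phi29
  kinetics.
* **Reads.** Fixed-length reads (100 bp) placed uniformly within amplified
  segments, Poisson counts at the segment's target depth. Sequencing error
  is off by default and injectable as a per-read allele flip rate at SNPs.
* **CNV artifacts.** Loci inside CNV-track regions receive extra reads
  carrying the *other* homologue's allele wherever covered (collapsed
  paralogs mapping to one position), at `cnv_boost` times the local depth —
  the mechanism that produces artifact heterozygotes in many libraries at
  once.
* **Not modelled:** read-level sequences (FASTQ), mapping error, phi29
  chimeric products. Consequently, passing tests demonstrate the
  *algorithmic* behaviour of the pipeline under the stated sampling model,
  not robustness to alignment artifacts.

All generators draw from a single `numpy.random.Generator` seeded per call;
identical seeds give bit-identical outputs.

## Scaffolding

Contigs are maximal unions of overlapping **or abutting** read intervals
(an abutting pair has no gap to threshold). Adjacent contigs join into a
scaffold when their gap is **strictly** below `max_gap`; the default 1,000 bp
reflects the empirical observation that sub-kilobase gaps are the
within-amplicon population while larger gaps separate amplicons. The
adaptive alternative uses μ + kσ (default k = 3) computed over gaps below a
1 kb ceiling for the same reason. An alternative scaffolder finds runs of
25–45 kb in 1 kb depth windows with at least two thirds of windows above a
background level (the fosmid-insert heuristic); runs over the maximum are
retained but flagged, and the background defaults to an external estimate
(callers may use the per-library median window depth). Coordinates are
0-based half-open internally; GFF3 output is 1-based inclusive. N50 is the
element length at which the descending cumulative sum first reaches half the
total. The minimum read count per contig defaults to 1 (configurable).

## Repeat filtering

Repeat annotations are merged before classification so that the four
categories — neither end in a repeat, one end, two ends in two different
repeats, whole scaffold within one repeat — are mutually exclusive and
exhaustive. "End" means the first and last base (end − 1 under half-open
coordinates). The random-placement null re-places the observed scaffold
lengths uniformly with the constraint that placements lie fully on the
chromosome. Only scaffolds wholly within one repeat are removed, and only at
the scaffold stage: contigs in repeats still participate in scaffold
construction.

## Phasing preparation

Informative loci are heterozygous in the bulk sample **and** have both
alleles observed somewhere across the dilution libraries (possibly in
different libraries); everything else is dropped before consistency
calculations. Multi-allelic records are skipped with a warning.

Per-scaffold allele calls from pileups: heterozygous when both alleles have
≥ `het_min_each` (default 2) reads; 0/1 when one allele has ≥ `min_reads`
(default 2) and the other falls below `het_min_each`; missing otherwise.
Scaffolds with more than 3 heterozygous calls **or** a heterozygous fraction
above 0.2 (both strict) are removed as deriving from both homologues or from
CNV; surviving heterozygous positions are masked to missing. A strict mode
(`max_het_count=0`) drops any het-containing scaffold, the appropriate
setting for libraries expected to be haploid (e.g. sperm). The two-SNP
filter counts distinct allele combinations at originally adjacent locus
pairs across libraries: a true diploid allows at most two, so pairs with
more mark both loci removed (single pass; pairs that become adjacent after
removal are not re-tested, matching the observation that residual anomalies
are rare and were not further filtered).

The `frag` dialect emitted for the phaser is
`B id s1 a1 s2 a2 ...` — `B` contiguous blocks, each an (1-based allvars
start index, 0/1 allele string) pair; `allvars` is TSV
`index chrom pos ref alt`. The exact dialect consumed by historical phasing
binaries is not standardised, so a reader is provided and round-trips are
byte-identical; fragments with fewer than two called loci after locus
removal are uninformative and omitted.

## Haplotype assembly

Fragments sharing loci form connected components (union–find); each
component yields one block — no attempt is made to bridge components with
population linkage information. Within a component the heuristic solver:

1. scores fragment pairs by (disagreements − agreements) over shared loci
   and greedily moves single fragments between the two sides while the cut
   improves (incremental gain updates);
2. polishes with greedy single-fragment flips that reduce MEC directly;
3. keeps the best of `restarts` (default 20) random initialisations,
   stopping early at MEC 0.

The reported objective is always MEC, computed from the per-locus majority
consensus of the final bipartition (per-locus ties vote 0; the block's sign
is canonicalised so hap0's first phased allele is 0, making results
deterministic given the seed). The exhaustive solver enumerates all
2^(k−1) bipartitions vectorised and is the oracle for components of ≤ 20
fragments; on random ≤12-fragment instances the heuristic matches its
minimum on ≥95% of cases (measured 98% at the default restarts).

## Validation metrics

Consistency is max(#agree, #disagree)/n over shared called loci — computed
in integer arithmetic so it is exactly invariant under complementing either
vector. The majority agreement state defines "in phase" (an exact 50/50 tie
resolves to "agree", an arbitrary documented choice). Minority runs of
length ≥ 2 are switch events; minority runs touching the first or last locus
are also counted as switch events rather than errors, because "out of phase
with neighbours on both sides" cannot apply at a boundary. Switch
consistency = 1 − (isolated interior errors)/n, hence never below raw
consistency. Cross-library aggregation is locus-weighted (pairs sharing more
loci weigh more) and the per-pair table is always available. Feature
containment counts a feature only when a single cover interval contains it
entirely; the missense-pair phasing rate tests every within-gene locus pair
for joint containment in at least one cover.

## Design tools

The haplotype-coverage simulator tiles haplotypes with exponential lengths
(mean 10 kb — the linkage-disequilibrium scale in cattle) end-to-end across
an 86 Mb chromosome (the mean cattle autosome), truncating the final
haplotype at the chromosome end and excluding it from the denominator.
Scaffolds with exponential lengths are placed uniformly (fully
on-chromosome) until their summed length reaches `coverage_depth ×
chrom_length`; a haplotype is captured only when one scaffold contains it
entirely. The primary metric is length-weighted (percentage of chromosome
length in captured haplotypes); the default is 10 replicates with
per-replicate values available for dispersion. The closed form

    ∫ (L/h²) e^(−L/h) · (1 − exp(−c · e^(−L/m))) dL

(h = haplotype mean, m = scaffold mean, c = coverage) agrees with the
simulation within Monte-Carlo noise across the grid and serves as a
cross-check; at low coverage (≤ ~4×) historical published grids sit below
both, which is consistent with unstated placement/truncation details in
those computations — the simulator is validated against the closed form in
that regime rather than against any printed table.

Heterozygote-detection probability is provided under two models —
`fixed_binomial_min1` (1 − 2·(1/2)^depth: both alleles seen among exactly
`depth` fair reads) and `poisson_min_k` (minor allele Poisson(depth/2) seen
≥ k times) — because no single obvious model reproduces commonly quoted
figures (e.g. ~61% at 4×; the two models give 87.5% and 59.4% at k = 2).
Both are exposed; neither is privileged.

The cost model: a library holding per-homologue fraction f covers 2f − f² of
the genome, so n_libraries = ceil(target scaffold coverage / (2f − f²));
total sequence = genome size × read depth over scaffolds × scaffold
coverage; both cost terms are linear in their unit prices (defaults $75 per
library, $6,000 per 100 Gb).

## Problem sizes and numerical choices

The bundled test bench simulates 31 subcell libraries (six cells × six
aliquots, first 31 kept) on a 2 Mb chromosome with 2,000 SNPs — large enough
that every stage is exercised with thousands of pairwise comparisons while
the full suite runs in well under a minute. The design-grid checks use the
full 86 Mb chromosome at 10 replicates for the spot cells and a 20 Mb
chromosome at 4 replicates for the monotonicity scan. Degenerate inputs
(empty gap lists, empty depth tracks, zero-length intervals, zero denominators)
raise `ValueError` or return explicitly flagged undefined reports rather
than NaNs leaking silently.

## Known limitations

* The log-normal amplification skew and the paralog-leakage CNV model are
  pragmatic stand-ins; real MDA bias is locus-dependent and chimeric
  products are not modelled at all.
* Scaffolds joined across homologue boundaries (chimeras) are an inherent
  error mode of gap-threshold joining; they degrade raw block-vs-truth
  consistency while switch consistency stays near 1. Interpreting raw
  consistency of long blocks therefore requires the switch metric alongside.
* The phaser is a heuristic; optimality is only verified against the
  exhaustive oracle at small component sizes.
* SNP calling, duplicate marking and realignment are upstream of this
  package and out of scope; inputs are assumed to be mapped-read intervals
  and pileup counts.
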