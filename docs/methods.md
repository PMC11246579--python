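# Methods

This note documents the models, conventions and numerical choices behind
`capcore`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and naming

BED-style 0-based half-open intervals are used everywhere internally;
1-based coordinates appear only at the VCF boundary. Sub-reference
contigs are named `{chrom}_{start}_{end}` with full-reference 0-based
half-open coordinates, so a contig name alone suffices to lift variants
back (`full_pos = start + sub_pos` for a 1-based `sub_pos`). The parser
rejects contig names not matching this pattern.

## Zone calling

Three parameters, applied in a fixed order:

1. A base is *marked* when its mean depth per sample is **≥**
   `min_mean_cov` (inclusive: the common setting "a minimum average of
   one read per sample" must keep bases averaging exactly 1). The mean
   is taken over **all** samples, including samples with zero coverage
   at the base.
2. Consecutive marked runs merge when the gap between them is
   **strictly smaller** than `min_dist`; a gap equal to `min_dist` does
   not merge. Gap bases absorbed by a merge stay inside the zone, so a
   zone is always one contiguous interval.
3. Merged regions shorter than `min_length` are discarded (length filter
   after merging, and `length ≥ min_length` is kept).

Defaults are 1 read/sample, 100 bp, 100 bp — a parameterization suited
to sparse capture designs on large genomes. User-BED merging unites
overlapping *or touching* intervals: under the half-open convention a
zero-gap boundary is indistinguishable from an overlap at base
resolution.

## Read extraction

Record-level filters (all independently switchable): duplicate flag,
proper-pair flag, primary-only (no secondary/supplementary), and a MAPQ
floor that removes records with quality *strictly below* the threshold
(Q30 keeps MAPQ 30). Duplicate *detection* is out of scope — the flag is
trusted (set by an upstream tool or by the simulator).

Zone assignment uses any-overlap with a largest-overlap tie-break
(leftmost zone on an exact tie); the rule is a package decision, made
explicit so results are reproducible. Pairing is resolved by shared read
id among primary records (secondary/supplementary must be removed first;
more than two records per id is a data error). Classification:

* both mates in the same zone → the pair survives as a pair;
* mates in two different zones → both demoted to single-end;
* one mate in no zone → the in-zone mate becomes single-end, the other
  counts as dropped (the conservative extension of the two-zone rule);
* record in no zone → dropped.

FASTQ output restores sequencing orientation (reverse-strand alignments
are reverse-complemented back, qualities reversed) and keeps R1/R2 files
synchronized.

## Lift-over

`lift_vcf` operates at the text level: CHROM/POS are rewritten, the
`##contig` header lines are replaced by the full-reference chromosomes
(with lengths when known), records are re-sorted by full-reference
coordinates (sorted output is what downstream indexing expects), and
every other byte of every record is copied verbatim. Optional REF
verification against a reference FASTA was considered and dropped: the
offset arithmetic is exact by construction and is covered by exhaustive
round-trip tests.

## Filtering cascade

Step order is fixed 01→04. Thresholds follow a literal reading of the
usual criteria: DP is inclusive (keep DP ≥ 5) while GQ is exclusive
(keep GQ > 15) and QUAL inclusive (keep QUAL ≥ 30); all configurable.
Calls lacking a DP or GQ tag are masked (conservative). Missing-data
filters (per-locus F_missing, per-sample) are disabled by default.

Step 04 evaluates biallelicity on the alleles *observed after masking*,
not on the ALT column; multiallelic sites are dropped, not split. Sites
monomorphic after masking are dropped before the F<sub>IS</sub> test
(F<sub>IS</sub> undefined at He = 0). The minor allele is the
lower-frequency allele among non-missing calls; on an exact 50/50 tie
the ALT allele is treated as minor. When every popgen criterion is
disabled, step 04 is the identity, so a fully disabled cascade passes
input through unchanged.

Note an algebraic consequence: for a biallelic site whose minor allele
appears only in heterozygotes, F<sub>IS</sub> = 1 − 1/(1−p) < 0, so the
minor-homozygote rule is implied by any positive F<sub>IS</sub>
threshold; it acts independently only when the F<sub>IS</sub> filter is
relaxed. Both are kept as separate, switchable rules.

## Statistics

* Per site: `p` = ALT frequency among non-missing diploid calls,
  He = 2p(1−p), Ho = heterozygote fraction, F<sub>IS</sub> = 1 − Ho/He
  clipped to [−1, 1], undefined when He = 0. This is the Nei-style
  per-site estimator; numerical agreement with other estimators (e.g.
  method-of-moments multi-locus ones) is not claimed.
* Selfing equilibrium: F<sub>IS</sub> = (1−t)/(1+t) for outcrossing rate
  t ∈ [0, 1].
* Ts/Tv: transitions are {A↔G, C↔T}; a zero-transversion denominator
  raises a distinct signal rather than returning infinity.
* π: per-site (2n/(2n−1))·2p(1−p), averaged over sites with at least
  `min_per_pop` genotyped individuals in the population (default 10);
  DRI = π_ancestral/π_derived, so stronger diversity loss gives larger
  values.
* F<sub>ST</sub>: the Weir & Cockerham (1984) two-population θ with
  ratio-of-sums aggregation (Σa / Σ(a+b+c)), not a mean of per-site
  ratios; negative estimates are reported as-is. Sites monomorphic
  across both populations carry no information and are skipped; sites
  failing the per-population sample floor are excluded per statistic.
* F<sub>ST</sub> scan: per chromosome, the threshold is the empirical
  0.95 quantile with linear interpolation between order statistics
  (numpy's default, "type 7"), and outliers are zones *strictly* above
  it — which bounds the flagged count by ⌈5%⌉ of the zones. Chromosomes
  with fewer than two defined values are skipped with a warning.

## Synthetic data

The generators define the study conditions for all tests. Alignment
side: 300-bp zones spaced ≥ 250 bp apart (sparse targets on a toy
100 kb × 2 reference), 100-bp reads with a 250-bp insert, a PCR
duplicate probability of 0.8 per fragment (capture of a tiny target in a
huge genome produces mostly duplicates), 10% off-target fragments
resampled until they are zone-free so per-read provenance is exact, and
a handful of properly-paired fragments deliberately bridging two
consecutive zones. Genotype side: ancestral ALT frequencies uniform in
[0.1, 0.5]; population frequencies from the Balding–Nichols beta at a
target F<sub>ST</sub> (a generative model chosen precisely because its
true F<sub>ST</sub> is a parameter); genotypes with inbreeding
coefficient F via probabilities p²+Fpq / 2pq(1−F) / q²+Fpq; DP Poisson
with mean 20 and GQ a noisy increasing function of DP (only its ordering
relative to the thresholds matters). Violation sites for cascade tests
are appended explicitly and recorded in the truth object.

Everything is deterministic given (config, seed). The simulator omits
sequencing errors, indels, multiallelic sites, linked loci and bait
thermodynamics; consequently, passing tests demonstrate correctness of
the *computational stages* (interval logic, pairing logic, coordinate
arithmetic, filter bookkeeping, estimator calibration under the stated
models), not robustness to real-data noise sources the models exclude.

## Problem sizes

Test and validation workloads are sized for quick desk-scale runs:
parameter-recovery suites use 200 individuals × 500 sites for
F<sub>IS</sub> (tolerance ±0.05 around F ∈ {0, 0.5, 0.92}) and
2×50 × 1000 sites for F<sub>ST</sub> (±0.03 around 0.1 and 0.3) — both
tolerances are several standard errors wide at these sizes; the scan
test uses 100 zones × 20 sites with one zone planted at F<sub>ST</sub>
0.6 over a 0.05 background; the zone-calling oracle comparison runs 220
random profiles up to 10 kb.

## Known limitations

* Per-site F<sub>IS</sub> is a ratio estimator and noisy at low minor
  allele frequency; the filters use it site-wise by design, as a
  screening rule rather than an inference.
* The lift-over handles only zone-offset lifting (no chain files, no
  strand flips — zones are always forward-strand slices).
* The CLI's extraction report aggregates over the input SAM as a single
  sample; per-sample splitting is expected upstream (one SAM per
  sample), as is conventional for capture pipelines.
* No imputation, PCA, linkage statistics or haplotype-based scans.
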