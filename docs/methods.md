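# Methods

This note records the models implemented, the defaults and why they were
chosen, what the simulator does and does not emulate, and the numerical
decisions a maintainer would need to reproduce or change behaviour.

## Transposon activity model

A copy is *potentially active* when it is young and close to full length:

- divergence: `perc_div < max_div`, default 5.0 percent, strict inequality
  (a copy at exactly 5.0% is inactive);
- length: `copy length >= min_length_fraction * consensus_length`, default
  0.90, inclusive. Per-family absolute length thresholds can override the
  fraction, reflecting that published full-length definitions differ by
  family.

Simple/low-complexity repeats are excluded from activity calling and from
"transposon" composition. Genome fractions per family/class use the union
of copy intervals so overlapping or nested records count each base once.
The parser converts RepeatMasker's 1-based inclusive coordinates to the
0-based half-open convention used everywhere internally; complement ('C')
rows have their consensus begin/end columns swapped back into begin ≤ end
order.

## Small-RNA processing

Reads of length ≥ 23 nt are treated as piRNA-sized (the 19–22 nt
miRNA/siRNA range is excluded); cluster detection further restricts to
23–33 nt. Collapsing is exact-sequence deduplication with counts. The dust
filter removes reads whose longest mononucleotide run or longest period-2
repeat exceeds 75% of the read; the exact rule of the original
low-complexity duster is not published, so this criterion is a documented,
configurable stand-in.

The toy mapper reports *all* genomic sites where the full-length read
aligns with at most 3 mismatches and contains an exact matched stretch of
at least 15 bases (matching the seed semantics of small-RNA mappers that
require `seedmatch` exact bases); reads with more than 1000 sites are
discarded. It is implemented as exact 15-mer seeding over a sorted k-mer
index plus Hamming verification; a brute-force all-positions scan in the
test suite certifies equivalence. Production data enters through SAM/BAM,
taking n from the NH tag when present.

Multimap weighting: a read with n reported sites contributes count/n at
each site. Weights are split only across *reported* sites, so the total
weighted mass equals the number of mapped reads exactly; this conservation
is asserted to 1e-9 in tests.

Origin classification assigns each alignment by precedence
TE > exon > intron > non-coding (an alignment inside a TE that is itself
intronic counts as TE). The precedence is configurable because public
pipelines rarely state their tie-break; TE-first matches the analytical
focus on transposon-derived piRNAs.

## Ping-pong statistics

For a plus-strand alignment with 5′ end at s and a minus-strand alignment
whose 5′ end is at e−1 (half-open coordinates), the pair distance is
d = (e−1) − s + 1, i.e. the number of overlapping 5′ bases; the ping-pong
signature is a peak at d = 10. Pairs are formed within a chromosome at any
locus among TE-overlapping alignments, weighted by the product of the two
alignment weights (a product is additive over multimapped projections;
taking the minimum would not be), and distances above d_max = 30 are
ignored as uninterpretable overlaps at piRNA length scale. Base
composition at positions 1 and 10 (5′→3′, read orientation) is computed
over all TE-mapped reads, not only paired ones. Groups with pair mass
below 50 are flagged low-confidence rather than dropped.

## Cluster detection

Alignments are length-filtered to 23–33 nt and indexed by their 5′
position. A 5000-bp window slides in steps of window/10 = 500 bp; window
weighted mass is tested against a one-sided Poisson tail under the uniform
genome-wide rate λ = total mass × window / genome length, significant when
p ≤ 0.01. Weighted masses are not integers, so the tail uses
P(X ≥ ⌈mass⌉). Significant windows are merged when overlapping, and each
merged region is then cut back to its outermost 500-bp bin that passes the
same Poisson test at bin scale before the final trim to the outermost
aligned read boundaries. Without that edge refinement a merged region
carries up to window − step of low-density slop at each end (any window
overlapping a dense locus is significant), and a single background read in
the slop would stretch the trimmed cluster by kilobases; the refinement
restores sub-kilobase boundary resolution while using no new model.
Clusters below 10 weighted reads are dropped — a floor against single-read
"clusters" on sparse toy genomes.

Strandedness is uni+ or uni− when the dominant strand holds ≥ 75% of the
cluster's weighted mass, else dual; the threshold follows common practice
for mono-directional cluster calls and is configurable. Ranking sorts by
weighted mass (ties broken by genomic order); N90 is the smallest number
of top clusters whose cumulative fraction reaches 0.9 (a tiny epsilon,
1e-12, guards the ≥ comparison against floating accumulation).

Two cautions. First, the number of called clusters is not mathematically
monotone in the significance threshold on arbitrary input (tightening the
threshold can split a merged run into two); the guaranteed monotone object
is the set of significant windows, which is what the property test checks.
Second, any sufficiently read-dense locus — including an expressed TE
copy — is called; that is intended behaviour for a density-based caller.

## CpG islands

The Gardiner-Garden & Frommer scan slides a 200-bp window at step 1;
windows with GC ≥ 0.5 and observed/expected CpG ≥ 0.6 are merged when
overlapping, each merged region is trimmed to its outermost CpG
dinucleotides and re-tested against every threshold, now including the
significance filter: P = P(X ≥ N_CpG) with X ~ Binomial(L−1, f_C·f_G)
using the region's own base frequencies. This null (independent placement
of C and G at the observed composition) is the simplest one consistent
with applying a P-value cut-off to CpG excess; the upstream tool's exact
null is not published. Regions failing any criterion after trimming are
dropped, so every emitted island verifiably satisfies all four rules. N
positions are excluded from all counts and from the effective length, and
no island may span an N run of ≥ 10. A CpG whose G falls outside a window
is not counted for that window.

Shuffle enrichment places length- and chromosome-preserving random
regions, non-overlapping within each shuffle, annotates them with the same
precedence as real islands (TE > TSS±100 bp > genic > intergenic), and
compares category counts observed-vs-pooled-shuffles with a Pearson
chi-square without continuity correction. Empty categories are dropped
from the table. Calibration on null placements shows type-I error at the
nominal level when category expected counts are not tiny; with very rare
categories the usual chi-square caveats apply.

## Methylome quantification

Windows are consecutive blocks of 50 CpG positions per chromosome
(step = 50 CpGs, i.e. tiled; an overlapping step is configurable since
"running window" tools differ here). A window's level is the pooled-count
mean 100·Σmeth/Σ(meth+unmeth) — not the mean of per-CpG percentages — and
windows with fewer than 10 total observations are dropped. Feature values
are unweighted means over intersecting windows. Metaplots scale each
feature body to 100 bins with 2-kb flanks in 40 fixed-width bins, pool
counts per bin across features, and reverse minus-strand features so bin 0
is always the TSS side; features shorter than the bin count are binned
proportionally (some bins may be empty) and their count is logged.

Conversion: lambda spike-in reads are fully unmethylated, so conversion % =
100·unmeth/(meth+unmeth) on lambda; pUC19 is fully methylated and its
retention (and 100 − retention as overconversion) controls the opposite
failure mode. TSS = first transcribed base (strand-aware); promoters are
the 2 kb upstream. Transposon methylation excludes copies overlapping
exons by ≥ 1 bp. Group comparisons use Welch's unequal-variance t-test
(the safer default when only "unpaired t-test" is specified); two
zero-variance groups with different means are flagged degenerate instead
of returning an infinite statistic. The "highly methylated" cut-off for
genome-vs-CGI fraction comparisons defaults to ≥ 80% and is configurable.

## The simulator

The generator emulates the statistical structure of the study inputs, not
their biology in full:

- **Genome**: i.i.d. background at a target GC (default 0.40), with
  planted features placed non-overlapping by rejection sampling (placement
  failure raises an error naming the feature).
- **Transposons**: each copy is the family consensus, 5′-truncated
  (LINE-style truncation, the dominant mode) and substituted base-by-base
  at the planned divergence rate — substitutions only, no indels, so the
  realized substitution fraction *is* the divergence statistic. The
  emitted percent divergence is rounded to 1 decimal (the annotation
  format's precision) and the truth `active` flag applies the default
  activity rule to those same rounded/realized values, which is what makes
  exact-concordance checks well defined at the 5.0 boundary.
- **Reads**: taken verbatim from the genome (sense or reverse complement),
  so the toy mapper can map them exactly; no sequencing error, adapters,
  or PCR duplicates. Lengths follow a truncated triangular law on
  23–33 nt with mode and median 29. The first base is uridine with
  probability u1_bias = 0.8 (sampling 5′ positions from U-start vs
  non-U-start pools within the locus). For a fraction
  pingpong_fraction = 0.3 of cluster/TE primaries, a partner is emitted on
  the opposite strand with its 5′ end exactly 10 nt inside the primary's
  5′ end; since reads are genomic, the partner's position-10 base is
  automatically the complement of the primary's first base, and partner
  emission is conditioned on the primary's first base so that the fraction
  of partners whose primary starts with U equals a10_bias = 0.9 while the
  overall partner fraction stays at pingpong_fraction.
- **Methylome**: per CpG, depth ~ Poisson(coverage mean, default 10) and
  methylated count ~ Binomial(depth, p), with p chosen by the
  highest-precedence feature covering the CpG: TSS window (default
  ±300 bp, p = 0.60) > active TE (0.96) > TE (0.93) > gene body (0.80) >
  background (0.90). The TSS category sits above the basic TE > gene >
  background precedence because a TSS hypomethylation dip is part of the
  emulated regime (germline genomes of this kind run near 90% CpG
  methylation overall with ~80% gene bodies, a dip toward 60% at the TSS,
  and heavily methylated, young transposons). Zero-depth CpGs are absent
  from the coverage output, as in real coverage files. Spike-ins: 2,000
  lambda CpGs at p = conversion failure (0.005) and 2,000 pUC19 CpGs at
  p = 1.
- **Determinism**: all randomness flows from `numpy.random.default_rng`
  seeded by `[seed, stage]`; identical configs give byte-identical files.

Because reads are error-free and features are placed in otherwise
featureless background, passing tests demonstrate correctness of the
statistics and calling logic — not robustness to sequencing error,
assembly gaps, nested/fragmented repeats, or non-uniform coverage, none of
which the generator produces.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so each
stage still has non-trivial statistics: a 4-Mb genome with 1,000 planted
copies for activity concordance; 100k reads (65% from TE loci) for origin
classification and weight conservation; 100k primaries at ping-pong
fraction 0.3 for the overlap histogram and biases; a 10-Mb genome with 20
planted clusters (5–15 kb, 2,500 reads each, 2,000 background reads) for
cluster recovery; 100 random 2-kb sequences against a brute-force
enumerator for the CGI scan; 20 seeded 80-kb methylomes for window
recovery. Headline numbers from genome-scale studies (hundreds of
thousands of CGIs, thousands of clusters, tens of thousands of active LTR
copies) require the corresponding full genome and sequencing depth and are
out of reach of these fixtures by design; the package reports the same
statistics on whatever input it is given.
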