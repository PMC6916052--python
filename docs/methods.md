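# Methods

## Scope and data model

The package implements a desk-side pipeline for degenerate
endogenous-retrovirus regulatory elements: genome scanning for RcRE-like
sequences, genomic-context annotation, FDR/overlap statistics, unique-read
quantification of repetitive proviral loci, normalization and per-locus
NB testing, and reporter-assay normalization. All coordinates are 0-based
half-open internally; GTF converts at the file boundary (1-based inclusive),
BED and the pysam-backed SAM reader already share the internal convention.
Human-readable location strings are 1-based inclusive with thousands
separators (`chr1:1,410,022-1,410,454`). Chromosomes sort
natural-numerically (`chr2` before `chr10`, numeric before named), which is
what "sort by chromosome number, then start" means for a merged annotation.

Genome builds are user-supplied and the code is build-agnostic; nothing
assumes hg19 vs hg38.

## Element scanning

`global_align` is Needleman–Wunsch via Biopython's `PairwiseAligner` with
BLASTN-like scores (match +2, mismatch −3, gap open −5, extend −2) over an
explicit ACGTN matrix in which N matches nothing, itself included. Percent
identity is identical columns over total alignment columns (the BLAST
convention); gap columns count against identity. For unrelated sequence
pairs co-optimal alignments with different column counts exist, so identity
is only near-symmetric there; in the regime the scanner cares about
(≥ 90% identity) the optimum is effectively unique and identity is symmetric.

`scan_genome` seeds with exact 12-mers of the query (both strands scan the
forward genome, the minus strand using the reverse-complemented query),
clusters seed-implied diagonal starts within 10% of the query length, and
aligns each candidate window semi-globally (query end-to-end, window
overhangs free, implemented as free end-gaps in the target row). Hits below
the identity threshold (default 94.0, exposed as a parameter) or outside
±10% of query length are discarded; overlapping survivors are resolved
greedily by alignment score with ties broken by leftmost coordinate then
plus strand. Reverse-strand hits report the reverse-complemented
(query-oriented) genomic sequence, and each reported hit carries a fresh
global alignment of query vs hit sequence, so reported identity and the
alignment trace are always mutually consistent.

A 12-mer seed requires one exact 12-mer shared between query and copy. For
a 433-nt query at ≥ 94% identity edits are ≥ 16 nt apart on average, so the
probability of losing every seed is negligible; the test suite verifies
this empirically against `oracles.exhaustive_scan`, an independent
edit-distance (edlib) sliding-window aligner run at every genome offset on
both strands. The exhaustive oracle's identity, $(L - d)/L$ with unit-cost
edit distance $d$, agrees with the affine-gap identity to well under half a
point for the substitution-dominated implants used in validation.

The mismatch-track ("highlighter") representation records, per sequence
aligned to a reference, the alignment columns at which they differ together
with the substitution or gap observed — the machine-readable form of a
highlighter plot.

## Annotation

A hit is assigned to a gene when the gene's full transcription span covers
at least 50% of the hit; if several genes qualify the largest overlap wins
and the rest are kept as secondary contexts (this is how a hit inside two
genes on opposite strands is reported). Orientation is sense iff hit strand
equals gene strand. Exonic vs intronic is resolved against the union of the
assigned gene's annotated exons — no transcript-level resolution, since the
biology of interest is "intronic, antisense" placements. LTR-catalog
membership requires ≥ 80% reciprocal overlap, loose enough to match partial
LTRs that still contain the element. Unique-element collapsing groups hits
by exact sequence string; a group's region count is the number of distinct
gene regions among its members, so two identical direct-repeat copies in
one gene region count one region (the solo-LTR direct-repeat pattern).

## Overlap statistics

`bh_adjust` is the Benjamini–Hochberg step-up computed directly (sorted
p·n/rank with a reverse cumulative minimum); the test suite checks it
against statsmodels' implementation. DE gene calls use strict inequality
q < α with α = 0.01 as the conventional threshold. `venn3` computes the
seven exclusive regions by set algebra. The HGNC symbol lists for the
RcRE-containing gene regions and their overlap with the HIV-infection and
Rec-response expression datasets ship as constants for the overlap demo;
identifier harmonization across datasets is the caller's responsibility
(an optional symbol→id mapping helper is provided).

## Unique-mapping quantification

The filter contract is "alignments with a scored secondary hit are
non-unique", detected by presence of a configurable optional tag (`ZS` for
HISAT2, `XS` for bowtie2-style output). Records are removed with category
priority secondary/supplementary > not-proper-pair > multi-hit so the
accounting identity n_input = n_kept + Σ removed holds exactly. Pair
consistency is enforced: a line-wise text filter can orphan the untagged
mate of a tagged read, but fragment-level counting needs both mates, so the
whole fragment is dropped. The test suite and acceptance script compare the
filter against `oracles.literal_sam_filter`, a re-implementation of the
literal `samtools view -f 0x2 | awk '!/ZS:/'` semantics on raw SAM text
plus the same pair rule.

Counting assigns each fragment (the union interval of its two mates) to a
locus it overlaps by ≥ 1 nt. Strandedness follows the dUTP library
convention by default ("reverse": first-in-pair maps antisense to the
transcript); "forward" and "unstranded" are available. Fragments touching
two or more loci are discarded as ambiguous rather than fractionally
assigned — multimapper rescue is out of scope — and every kept fragment
lands in exactly one of assigned/ambiguous/unassigned/wrong-strand, which
the tests assert as a conservation law. Coverage tracks bin the union
intervals at 50 nt (default) and normalize to fragments per kilobase per
million kept fragments, value = overlaps × 10⁹/(bin width × total kept),
written as bedGraph (a text stand-in for bigwig).

## Normalization and the NB Wald test

Size factors are plain median-of-ratios: per-locus geometric-mean reference
over loci with no zero count, per-sample median of count/reference. No
rescaling is applied, so the two-sample 2× fixture yields exactly
[1/√2, √2]. Note the estimator is relative: scaling one of m samples by c
scales factor *ratios* by c while absolute factors absorb a c^(1/m) shift
through the reference; normalized counts are unchanged up to a global depth
constant.

The per-locus test is a deliberately small NB Wald procedure: normalized
group means, log2 fold change with a 0.5 pseudo-count, variance
μ + αμ² propagated by the delta method, two-sided normal reference,
BH adjustment across loci within the contrast. Dispersion α is estimated by
method of moments within each group, averaged, floored at 1e-8. By default
the per-locus estimates are then **pooled** (averaged across loci) before
use: with 2–3 replicates a per-locus moment estimate has so few degrees of
freedom that the Wald statistic is strongly anti-conservative (realized
type-I error ≈ 0.12 at nominal 0.05 in simulation), while the pooled
estimate restores calibration (≈ 0.05). `dispersion="per-locus"` is
available when loci genuinely differ in dispersion and replication is
adequate. This is the same reasoning that leads full-featured DE packages
to share dispersion information across genes; no trend fitting or empirical
Bayes shrinkage is attempted here, and the procedure is validated by null
calibration and parameter recovery, not by numerical identity to any DE
package.

Under the recovery conditions used in validation (n = 3 per group,
reference mean 500, dispersion 0.05) the sampling SD of the log2
fold-change estimator is √(2(α + 1/μ)/n)/ln 2 ≈ 0.27 log2 units. Point
estimates are nearly unbiased (|bias| < 0.05 log2 units for a true
4.2-fold effect), but individual-run estimates scatter accordingly: about
a quarter of runs fall outside ±0.30 log2 units of the truth, a property
of the sampling distribution rather than of the estimator.

Contrasts are always condition vs the empty-vector reference within one
compartment; the compartment report lays total and cytoplasmic fold
changes side by side and flags loci whose cytoplasmic fold change exceeds
the total one (export enrichment). Reporter relative activity is
(p24/SEAP)/(p24_ref/SEAP_ref), making the reference pair exactly 1 and the
statistic invariant to common SEAP rescaling.

## Synthetic data

The generators produce the conditions the pipeline was designed for, not
realistic sequencing data:

* `make_genome` draws i.i.d. bases at a target GC (0.41 default, human-like);
  no repeats other than the ones implanted, no N runs.
* `implant` replaces a genome stretch with a mutated query copy; the edit
  count is ⌈L(1−t/100)⌋ for identity target t, positions drawn without
  replacement, substitutions uniform over the three alternatives, an
  optional fraction of edits realized as 1–2-nt indels. Realized identity
  is computed by `global_align` and stored in the truth record
  (within ±0.5 of target for substitution-only implants; indel interactions
  can widen this slightly).
* `simulate_alignments` emits SAM text of perfect proper pairs (no
  sequencing errors, no quality strings, no duplicates) with classic
  83/163 / 99/147 flag pairs, fragment lengths uniform on 150–200 nt (the
  library size-selection window), and the multi-hit tag on both mates of
  every fragment drawn from a locus's shared segment. Truth is the per-locus
  unique-fragment count.
* `simulate_counts` draws gamma-Poisson counts with mean
  baseline · 2^(LFC·[treated]) · size factor and the given dispersion.
* `simulate_de_table` mixes uniform null p-values with near-zero true
  positives; `make_reporter_table` builds measurements whose SEAP noise
  cancels exactly under normalization.

Everything is a pure function of (spec, seed) with explicit
`numpy.random.default_rng` seeding; no global state. Because the synthetic
data lack alignment error, degraded RNA, PCR duplication and annotation
error, passing tests demonstrate algorithmic correctness under the stated
model, not robustness to real-data pathologies.

## Problem sizes used in validation

Scanner validation uses 10–20 genomes of 50–100 kb with 3–6 implants each
plus 20 implant-free 100-kb genomes for background; filter equivalence uses
≥ 10,000 SAM records; null calibration uses 2,000 locus-replicates; fold
change recovery uses 100 seeds at n = 3; BH agreement uses 1,000 random
vectors. These sizes give sub-minute runtimes per stage while keeping
Monte-Carlo error well below the asserted tolerances.

## Known limitations

* The scanner is for desk-scale genomes (≤ a few Mb); no BLAST-style
  E-values, no translated search, and no performance guarantees on a full
  human genome.
* Identity-over-columns is alignment-dependent for low-identity pairs
  (co-optimal alignments may differ in column count).
* No EM reassignment of multi-mapping fragments; loci sharing sequence are
  quantified only by their unique regions, which *underestimates* total
  locus expression by construction.
* The NB test has no outlier handling, no independent filtering and no LFC
  shrinkage; at one or two replicates per group it degrades to a
  Poisson-like test and should not be trusted.
* BAM input is supported through pysam but SAM text is the tested dialect;
  CRAM and indexed random access are out of scope.
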