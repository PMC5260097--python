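# Methods

## The problem

Expression atlases precompute abundances for annotated gene models, but a
newly assembled transcript (typically a lncRNA) has no entry, and
re-quantifying a whole RNA-seq sample for the sake of one new model is
wasteful: isoform quantification is separable across genomic regions that
share no reads. `locquant` exploits that separability. It quantifies a novel
transcript using only the reads inside its *minimum spanning bundle* (MSB)
and rescales the result so it equals what a whole-transcriptome run would
report.

## Bundles and the MSB

A **bundle** is a maximal continuous genomic region covered by overlapping
fragments and/or annotated gene models, where neighbouring pieces of
coverage separated by **at most 50 bp** are joined into the same bundle
(`gap_threshold`, default 50 bp; a gap of exactly 50 merges, 51 splits; the
gap between `[a,b)` and `[c,d)` with `b <= c` is `c − b`). Bundles on the
same chromosome are therefore pairwise separated by more than the
threshold, so no fragment span can lie in two bundles: each bundle is an
independent unit of quantification. Bundles are built per sample from the
alignment plus the reference annotation and persisted as a small versioned
TSV index together with the sample's global mapped-fragment total. Bundle
construction and MSB inference are strand-agnostic — only genomic
continuity matters.

The **MSB** of a novel transcript starts from the transcript's genomic
span and absorbs every reference bundle it overlaps *or approaches within
the gap threshold*, iterated to a fixed point. We merge within-threshold
neighbours (not only overlapped bundles) so that the MSB always equals the
bundle that a from-scratch rebuild with the novel span added would
produce; that fixed-point identity is property-tested on randomized cases
and is what makes the local result exactly equal to the global one.

## Within-bundle estimation

Fragments overlapping the MSB are fetched (mate pairs collapsed to one
fragment — the F of FPKM; only primary alignments; unstranded). A fragment
is **compatible** with a transcript when every aligned block lies within
the transcript's exon union and every splice gap (N operation) coincides
exactly with a transcript intron. The unsequenced inner gap of a read pair
is not a splice gap and may silently span skipped exons; because the
genome-to-mature projection is monotone, the implied mature fragment
length is then automatically well defined, so no separate inner-distance
check is needed.

Abundances come from the standard isoform-mixture EM. For a compatible
pair the likelihood weight is

    P(f | t) ∝ φ(ℓ_ft; μ, σ) / (L_t − ℓ_ft + 1)

with `ℓ_ft` the fragment's implied length on transcript `t`'s mature
sequence, `φ` the normal density of the fragment-length model, and the
denominator the number of start positions available to a fragment of that
length. Modelling the length term matters: without it, a fragment whose
implied length on a sibling isoform is wildly improbable (because the
sibling retains an exon the source skips) is treated as equally likely,
which systematically misallocates mass between nested isoforms. Unpaired
fragments carry no length information and fall back to `1/effective
length`. Mixture weights start uniform over transcripts with at least one
compatible fragment, so the estimator is fully deterministic and isoforms
with identical compatibility patterns receive equal shares. Iteration
stops when `max |Δθ| < 1e-8` (default) or after 1000 rounds; the
log-likelihood is non-decreasing (asserted in tests), and because the
observed-data log-likelihood is concave in the mixture proportions the EM
fixed point is the global maximum-likelihood solution. Fragments
compatible with no transcript in the bundle still count toward the local
depth but not toward the likelihood.

The **fragment-length model** is estimated inside each bundle from paired
fragments uniquely assignable to one transcript (mean/sd of implied mature
lengths), falling back to a fixed N(200 bp, 50 bp) when fewer than 20 such
fragments exist — local estimation mirrors local quantification, and the
fallback keeps single-end and sparse data working. **Effective length**
uses the mean-length formula `max(1, L − round(μ) + 1)` rather than a full
distribution integral; this only enters the FPKM denominator, not the EM
weights.

## FPKM correction and normalization

Within the MSB, the *relative FPKM* of transcript `t` is

    relative FPKM = expected fragments / (eff_len/1000 × local_total/10⁶)

with the **local** (within-MSB) fragment count as depth. Rescaling

    corrected FPKM = relative FPKM × local_total / global_total

replaces the local depth with the sample's global mapped-fragment total,
yielding exactly the whole-transcriptome value. The totals are fragment
counts by default; a `totals="bases"` switch uses summed aligned-base
totals instead (the two readings differ by the ratio of local to global
mean fragment length; count mode is the FPKM depth denominator and is what
makes the local and global paths agree exactly).

Across samples, corrected FPKMs are made comparable by DESeq-style
median-of-ratios normalization: for each reference transcript nonzero in
every sample, compute its geometric mean across samples; a sample's size
factor is the median of its ratios to those geometric means, rescaled to
unit geometric mean so the factors multiply to 1. Replicates of the same
cell type are averaged arithmetically *after* normalization (averaging
before would defeat the size factors). A single sample gets a factor of
exactly 1.

## Synthetic data

The simulator lays out a single artificial chromosome of multi-exon genes
(defaults: 20 genes, 4–8 exons of 100–400 bp, introns 80–400 bp, 2–4
isoforms per gene sharing the gene's exon skeleton) separated by
intergenic gaps cycling through {10, 30, 60, 120, 200, 1000} bp — values on
both sides of the 50 bp merge threshold, so bundle joining and splitting
are both exercised. Isoform weights are log-normal(0, 1) unless given;
fragment counts are multinomial with probabilities ∝ weight × effective
length; 200,000 paired fragments of length N(200, 50) at read length 75 by
default. Start positions are uniform along the mature sequence (no
positional or GC bias), matching the quantifier's likelihood so parameter
recovery is a clean test; sequence content is placeholder. Records are
sorted in memory and written directly as an indexed BAM so output bytes
are a pure function of the configuration and seed.

What the simulator does **not** emulate: sequencing error and soft
clipping, multi-mapping, positional/GC bias, stranded protocols,
multi-chromosome genomes, annotation errors. Passing tests therefore
demonstrate the locality and estimator algebra, not robustness to real
library artifacts.

## Hold-out benchmarking

Known transcripts are removed from the reference and re-submitted as novel
queries; the whole-transcriptome run is the gold standard and the
simulator's truth table the ground truth. Each query is evaluated against
the reference lacking only that transcript: at annotation scale, removing
a few hundred of ~200k models almost never removes same-locus isoforms, so
per-query leave-one-out is the regime such a protocol actually probes — and
at desk scale it avoids artificially emptying loci of their sibling models.
The benchmark uses 20 genes / ~60 isoforms / 2×10⁵ fragments with 50
held-out queries, sized to run in about two minutes on one CPU.

Observed behaviour at that scale: the local and global corrected FPKMs
agree to ~1e-14 relative (the paths share fragments, transcript sets, and
the estimator — agreement is exact up to float summation order); rank
correlation with truth is ≥0.98; and the median relative error on
transcripts with ≥100 true fragments is ~1.5%. Minor isoforms contributing
~1% of a heavily expressed locus remain hard: their maximum-likelihood
estimates carry sampling dispersion of order 10–25% (bootstrap SD ≈ 50
fragments on a 399-fragment isoform under 40k sibling fragments), which no
estimator sharing the likelihood can reduce.

## Numerical and design notes

- Internal coordinates are 0-based half-open everywhere; GTF converts at
  the I/O boundary.
- EM weight rows are rescaled by their maximum per fragment — posteriors
  and the trajectory are unchanged, the log-likelihood shifts by a
  per-fragment constant, and deep-tail density underflow is avoided; a
  compatible pair is floored at 1e-300 so it is never silently dropped.
- Multi-mapped records: only primary alignments are counted, once.
- The bundle index stores fragment *counts*; `global_base_total` is kept
  alongside for the base-total correction mode.
- There is no unseeded randomness anywhere: simulation takes a mandatory
  seed, and quantification is deterministic by construction, so the full
  pipeline is byte-reproducible under an identical run manifest.
- Known limitations: no CRAM, no stranded modes, no bias correction, no
  uncertainty intervals, no novel-isoform assembly; single-end data works
  but always uses the fallback fragment-length model.
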