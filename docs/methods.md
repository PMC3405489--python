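# Methods

## Scope and data model

`isomirkit` analyses templated miRNA length variants (isomiRs): reads that
map perfectly to a precursor hairpin and differ from the arm reference only
in where their 5′ and 3′ ends fall. Non-templated modifications (tailing,
editing) are out of scope, as are de novo locus discovery and
mismatch-tolerant mapping — loci arrive as annotation (GFF3 + FASTA) and
reads either match the genome exactly over their full length or are
discarded.

Internal coordinates are 0-based half-open everywhere; GFF3 I/O converts
to and from the format's native 1-based inclusive convention at the
boundary. All sequences are normalized to upper-case DNA (U→T) on input,
so RNA- and DNA-alphabet sources mix freely. The central container is an
isomiR × library RPM matrix with rows at (locus, sequence) resolution: a
read that maps inside several precursor intervals is listed once per locus
in per-locus views, but whole-miRNome statistics (correlation, *t*-tests,
clustering) use a de-duplicated sequence view in which it is counted once.
The packaged reference table keys rows by EMBL accession as well; because
accessions in the transcribed table are not all unique per sequence, the
de-duplicated view is keyed by sequence, and accession lookups resolve
only when unambiguous.

## Filtering cascade

Stages run in a fixed order — adapter, length, low-complexity,
contaminants, genome match — with redundant (read) and non-redundant
(distinct sequence) tallies after each. Choices the upstream description
leaves open were fixed as follows:

- **Adapter**: the insert is everything before the leftmost exact
  occurrence of a 3′-adapter *prefix* of at least 6 nt (shorter only when
  the read end truncates it). Reads with no detectable adapter are
  discarded rather than passed through: with fixed-length machine reads
  and inserts capped at 24 nt, a missing adapter implies the insert is
  longer than the retained range.
- **Length**: keep 18–24 nt inclusive.
- **Low complexity**: drop sequences using fewer than 3 distinct
  nucleotides. This removes homopolymers and dinucleotide repeats while
  keeping every sequence in the packaged reference table.
- **Contaminants**: drop reads that are exact substrings of any rRNA/tRNA
  reference on either strand — reads are fragments of full-length
  structural RNAs, so substring containment, not end-to-end identity, is
  the right test.
- **Genome match**: k-mer-seeded exact search (seed 12 nt, verified
  full-length) over both strands; reads containing N are discarded before
  search because a perfect match is undefined for ambiguous bases. A read
  is assigned to every locus whose interval fully contains a same-strand
  hit.

The absolute per-stage tallies of the packaged per-library table are not
reproducible from sequence data (the raw libraries are not shipped), so
the cascade is validated by accounting identities — stage *i* output
equals stage *i*+1 input, tallies never increase — and by exact agreement
with the generator's bookkeeping on simulated libraries.

## IsomiR annotation

A variant is placed by exact string search within the precursor; every
placement is scored by overlap against the mature and star reference
intervals and the best (placement, arm) pair wins, ties resolved toward
the placement nearest its reference start and flagged as ambiguous.
Offsets are reported in precursor 5′→3′ orientation for both arms, which
keeps signs consistent regardless of genomic strand. Placements whose end
offsets exceed 8 nt are declared unaligned: observed variants never
deviate nearly that far, and larger offsets are more plausibly spurious
placements than genuine processing variants.

Dominance is ranked by RPM within each (locus, library); tissue-level
dominance uses the arithmetic mean of the three replicates' RPM, and exact
ties break lexicographically by sequence (deterministic, and flagged). A
locus is *sample-invariant* when its tissue-level dominant read is
identical in every tissue. A per-replicate convention (all replicates of
all tissues agree) is available via `dominance_table(...,
average_replicates=False)`. On the packaged table the replicate-averaged
census finds 23 invariant loci carrying 18 distinct dominant reads; the
per-replicate convention finds 20 loci / 15 reads. The originally
published census reports 16 reads, a value between the two that no
aggregation convention tried (mean, median, majority vote,
raw-count-weighted mean) reproduces from the printed table; the
discrepancy is documented by a deliberately failing acceptance test
rather than papered over.

## Statistics

- **Concordance**: Pearson correlation on untransformed RPM, de-duplicated
  view, exclusions applied before any computation; within-tissue averages
  use each tissue's three replicate pairs, the cross-tissue average pools
  all between-tissue pairs; reported to 2 decimals. The packaged dataset
  excludes one read (HE860285) whose abundance is two orders of magnitude
  above everything else; with it included every pairwise *r* rounds to
  ≥0.99 irrespective of tissue, which is why the exclusion exists.
- **Differential tests**: pooled-variance Student *t* (not Welch),
  two-sided, per isomiR per tissue pair, no multiplicity correction —
  the analysis this mirrors used the plain *p* < 0.05 criterion, and the
  pooled form reproduces its printed significant-comparison count on the
  packaged values. Degenerate inputs are defined: two identical constant
  groups give *p* = 1, different constants give *p* = 0 and are flagged.
- **Clustering**: Canberra distance (0/0 terms contribute 0) with
  complete linkage — the linkage default of the statistical environment
  the original analysis ran in, which names only the metric. Modes:
  all reads (replicate-averaged, duplicates counted once) or
  sample-invariant dominant reads only; a replicate-level variant skips
  averaging. Implementation is `scipy.cluster.hierarchy`; tests check the
  topology against a brute-force enumeration of complete-linkage merges.
- **Arm ratios**: per-replicate ratio of dominant-mature to dominant-star
  RPM; tissue mean is the arithmetic mean of per-replicate ratios
  (replicates with zero star RPM are excluded and flagged); classes are
  high [100, ∞), intermediate [10, 100), low [1, 10), inverted [0, 1).
  Mean-of-ratios (rather than ratio-of-means) reproduces both published
  reference values on the packaged table, and is reported to 1 decimal.

## Synthetic data generator

The generator emulates the reference study design: 5 tissues × 3
replicates, hairpin loci planted in a uniform random genome, 36-nt machine
reads consisting of an 18–24 nt insert followed by the 3′ adapter (so
trimming is always exercised), plus contaminant fragments copied from
synthetic rRNA/tRNA-like references and low-complexity reads at
configurable fractions (defaults 0.15 and 0.01, matching the removal
proportions visible in the packaged per-library tallies).

Each locus is a hairpin `pad(3) + mature + loop(15) + star + pad(3)`; the
star arm satisfies the DCL geometry star[:-2] = revcomp(mature[:-2]),
i.e. the duplex carries 2-nt 3′ overhangs, with the star's own overhang
drawn at random. Cut-site heterogeneity is a product distribution over
(Δ5′, Δ3′) offsets in [−3, 3] (defaults concentrated on 0 with ±1
shoulders, so all variants stay within the 18–24 nt window) and an
arm-bias parameter (default 0.8 mature). These defaults are free
parameters of the generator, not estimates — the emulated study publishes
no variant-frequency model.

Replicate noise: per (locus, library) the total count is gamma-Poisson
(negative binomial; mean = depth × locus share, variance = mean +
dispersion·mean²), split multinomially over variants. With dispersion = 0
counts are deterministic (largest-remainder rounding of expectations), so
equal-depth replicates are bit-identical and their Pearson correlation is
exactly 1 — the anchor of the noise-monotonicity property. One RNG stream
per library, seeded from (seed, tissue index, replicate), keeps libraries
reproducible and order-independent. Precursors and contaminant references
are redrawn until free of the 6-nt adapter seed, so no simulated insert
can trigger a spurious adapter trim; this is what makes the generator's
truth accounting exactly equal to the cascade's tallies.

What the simulation does *not* model: sequencing errors and quality
variation, non-templated additions, unmappable degradation products, and
realistic locus abundance spectra. Passing round-trip tests therefore
demonstrates correctness of the bookkeeping, normalization, annotation
and statistics on ideal templated data — not robustness to base-calling
noise or modification artifacts.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use scaled-down problem
sizes chosen as the smallest that keep the statistical checks
well-powered: genomes of 25–90 kb with 4–15 loci, library depths of
5,000–20,000 reads, 20 seeds per property, ≥2,000 tests for type-I-error
calibration. Expected RPM values are depth-invariant (probability × locus
share × 10⁶), so depth only affects sampling noise. RPM recovery is
judged per isomiR at 3 standard errors of the 20-seed mean; variants of
one locus share its replicate-noise draw, so deviations cluster by locus
and the acceptance script also reports the mean absolute relative RPM
error (typically 4–12%) alongside the within-3-SE fraction.

Fixture-based results are deterministic; every output file carries a
provenance header (version, seed, configuration hash, output path
excluded from the hash) and rounding conventions are frozen (correlations
2 dp, ratios 1 dp, *p*-values unrounded).

## Known limitations

- Exact-match mapping makes the pipeline blind to SNP-bearing or edited
  reads; on real data a fraction of genuine miRNA reads is lost at the
  genome-match stage.
- The low-complexity and adapter rules are reconstructions of behaviour
  the upstream toolchain does not specify; absolute cascade tallies on
  real libraries will differ.
- Accession-keyed lookups into the packaged table fail deliberately for
  the handful of accessions the transcription left ambiguous; use
  sequences there.
- The dominance-invariance census is sensitive to the replicate
  aggregation convention (see above); comparisons across studies should
  state the convention explicitly.
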