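# Methods

This note documents the models, conventions and numerical choices behind
`texapt`, and what the synthetic-data tests do and do not establish.

## Coordinates and interval semantics

All genomic coordinates are 0-based half-open (BED). Intervals sharing only
a boundary never overlap; every set operation requires ≥ 1 bp of overlap
unless a larger `min_overlap` is requested. Strand matching, where applied,
requires identical strand symbols (BEDTools `-s` semantics); exon-aware
("split") overlap evaluates probes against exon blocks only. RepeatMasker
consensus coordinates (`repStart`/`repEnd`) remain 1-based inclusive as in
the source table, and the TE reader requires `rep_start ≤ rep_end` on the
consensus regardless of genomic strand, pushing minus-strand `repLeft`
ambiguity into a validated input contract. Rows violating the consensus
invariants are rejected with a logged count rather than aborting a run.

Set operations are vectorised per chromosome in numpy rather than delegated
to an external interval library: the rotation null re-evaluates
peak-vs-subfamily overlap thousands of times, and keeping one overlap
definition in-package guarantees the half-open/strand conventions above are
the only ones in play. The test suite checks every operation against naive
all-pairs oracles, at up to 10³ × 10³ intervals.

## Rotation-permutation enrichment

The null hypothesis is that peak positions are unrelated to TE positions
while preserving everything else: peak count, peak lengths, per-chromosome
peak density, and the TE annotation itself. Rotation is per chromosome with
independent integer offsets drawn uniformly on [0, chrom length); peaks
wrapping past the end are split into two fragments that share the original
peak's identity, so both peak count (pre-split) and peak mass are conserved.
Per-chromosome rotation (rather than rotating one concatenated genome) was
chosen because it preserves per-chromosome densities and avoids an
arbitrary concatenation order; the expectation under either scheme agrees
on single-chromosome genomes, where the implementation is validated against
exact enumeration of every offset.

The binomial test is one-sided (upper tail), matching the directional
question of *enrichment*; `p0 = expected_mean / n_peaks` is floored at
`1/(n_perm × n_peaks)` when the permutations produced zero expected overlap,
avoiding p = 0 artifacts of a finite null sample. The Bonferroni divisor is
the full subfamily universe present in the TE table, not just subfamilies
with observed overlap. The enrichment ratio is reported as `inf` when the
expectation is zero but overlap was observed. Counting is per distinct
peak: a peak overlapping two copies of one subfamily counts once for it,
while a peak overlapping copies of two subfamilies counts once for each.

## Metaprofiles

Windows are anchored on the element midpoint — the only reading consistent
with a fixed 10 kb window over variable-length elements — and are not
flipped for minus-strand copies (plain genomic orientation, as in a
straightforward coverage workflow); `aggregate_profile` callers can flip
anchors beforehand if strand-oriented profiles are wanted. A tag increments
every bin it overlaps by ≥ 1 bp, so one tag can contribute to two bins.
The aggregation order is fixed: replicate mean per bin per anchor → minus
the pooled control mean per bin per anchor → mean over anchors; bins clipped
at chromosome ends are missing (NaN), excluded from the anchor mean, and
reported with a per-bin effective n. Controls are pooled rather than paired
with replicates.

Smoothing is Nadaraya–Watson with the Epanechnikov kernel
K(u) = 0.75(1 − u²) on bin-centre distances; the bandwidth default of
150 bp (three bins) is a reporting parameter, not a modelling claim, and
results should always state it. Constant curves are invariant under the
smoother, which the tests assert.

## Promoter discovery

The funnel order is fixed: (1) CAGE clusters within `window` bp (default
300) of ≥ 1 peak, pooled over TFs but with TF provenance recorded, strand
blind; (2) survivors overlapping ≥ 1 TE copy, strand blind; (3) survivors
overlapping the promoter of an annotated transcript, strand matched. The
promoter is the 2 kb region *centred* on the transcript 5′ end (TSS ±
1000 bp); "around the 5′ ends" is ambiguous between centred and
upstream-anchored, so the alternative is exposed as
`promoter_mode="upstream"`. Stage 3 uses ≥ 1 bp overlap (plain intersect
semantics) rather than full containment of the cluster in the promoter;
with 20–60 bp clusters against 2 kb promoters the distinction is a boundary
sliver, and overlap matches the behaviour of the standard tool chain this
procedure mirrors. One candidate row is emitted per (cluster, transcript,
TE, TF) combination; gene-level summaries deduplicate. Probe annotation is
hierarchical and exclusive: a probe takes all matches from the highest tier
that hits and none from lower tiers, and probes matching nothing are
dropped and counted.

## Subfamily-normalized levels and the three tests

"The same region in all copies of the subfamily" is defined by consensus
coordinates: the candidate's TFBS footprint is projected onto the consensus
through the affine floor map `c(g) = rep_start + ((g − start)·C)//G` (with
the orientation mirrored for minus-strand copies, whose leftmost genomic
base corresponds to `rep_end`), then lifted into each copy covering ≥ 1 bp
of the footprint by exact integer-preimage arithmetic. The lift never
exceeds the host copy and is idempotent; tests verify it base-by-base
against an independent per-base liftover, including minus-strand and
length-scaled copies. The normalized level is the distinct-tag count in the
candidate footprint over the count in the subfamily-wide footprint, which
cancels library size.

Hypomethylation is tested with a one-sample lower-tail t on paired
tumour−normal differences (df = n − 1); zero-variance differences are a
degenerate-input error, not p = 1. The DNase comparison is a two-sample
proportion test on (candidate count, subfamily count) per cell line as a
2 × 2 table with Yates continuity correction (toggleable); the one-tailed
p-value is half the χ² upper tail when the observed direction matches the
alternative, else one minus that half, and exactly 0.5 at the null centre.
Luciferase analysis: per-well firefly:Renilla ratio → triplicate mean per
construct → divided by the positive-control mean within each experiment →
scaled by the mean wild-type activity across experiments → lower-tail
pooled-variance two-sample t (df = n₁ + n₂ − 2) for deletion effects, with
0.05/0.01/0.001 star annotations.

## The synthetic-data generator

Defaults define the study conditions: 4 chromosomes × 2 Mb, a catalogue of
30 named subfamilies spanning SINE/LINE/LTR/DNA classes (≈ 4,900 copies,
≈ 21% of the genome), 2,000 peaks of 150–250 bp per TF, Poisson tag tracks
at 0.02 tags/bp with a 5× rate within ± 500 bp of bound copies, 60 genes in
tiers (0.8/0.1/0.1), 20 planted promoter positives plus 4 × 50 single-
violation decoys, 6 methylation pairs at δ = −0.2 and sd = 0.15, DNase
sensitivities 0.04 vs 0.02 over 5,000-count denominators, and a 0.15×
TE-deletion luciferase effect. These sizes give stable permutation
estimates and minutes-scale runs; consensus lengths are scaled down from
genome-scale values in proportion to the synthetic genome. All randomness
flows from one `SeedSequence` per stage, and identical configurations
produce byte-identical file trees.

Deliberate idealisations, and hence limits on what passing tests show about
real data: TE copies are non-overlapping (no nested or interrupted
elements, although the readers accept them); copies are ungapped, so
genomic length equals consensus span; tags are fixed-length Poisson events
with no fragment-length or mappability structure; random CAGE clusters are
suppressed when they would fall inside a TE, and promoter constructs live
in reserved chromosome-end zones that random peaks avoid, so that the
planted positives/decoys are provably the only objects satisfying (or
singly violating) the discovery predicates. Consequently the
precision-recall-equals-one result certifies the geometry of the funnel,
not robustness to ambiguous real-world annotation. Methylation levels are
ratios clipped to (0.001, 0.999); the clipping touches < 1% of draws but
makes the paired-test null p-values very slightly non-uniform, visible
occasionally to a KS test at 2,000 simulations.

## Calibration checks and problem sizes

The acceptance suite runs: type-I behaviour of the enrichment scan on an
unplanted genome (2,000 peaks, 30 subfamilies, 1,000 rotations; the
fraction of subfamilies with p < α must not exceed α + 3√(α/30)); planted
recovery at folds 5 and 4 with ratio > 1 and Bonferroni significance;
Monte-Carlo-vs-exact rotation expectation on a 10 kb single-chromosome toy
(2,000 rotations against all 10,000 offsets, within three standard errors);
promoter precision/recall 1.0 at 20 positives vs 200 decoys; metaprofile
centre-bin recovery of the planted 5× fold within 20% over ≥ 200 anchors
(measured as the bound/unbound smoothed centre ratio on raw RPKM curves,
since after control subtraction the unbound curve is ≈ 0 and a ratio is
undefined); and paired-test calibration at 2,000 simulations (KS uniformity
under δ = 0; power at δ = −0.2, sd = 0.15, n = 6 within three simulation
standard errors of the noncentral-t value, plus a 0.01 allowance for level
clipping).

## Known limitations

Read alignment, multi-mapper resolution, peak calling, coverage
pre-normalization and probe alignment are upstream of this package; inputs
arrive as intervals in one assembly. BAM/CRAM and FASTA are out of scope
(tag tracks are BED intervals with a library-size total; a mapping-quality
filter uses the BED score column). GC- or mappability-matched nulls are not
provided; the rotation null controls only for positional structure along
each chromosome.
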