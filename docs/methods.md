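# Methods

## Coverage representation

Each gene is represented by its full-locus, base-resolution pileup: an
integer matrix of read depth at every genomic position of the locus (exons
*and* introns) for every sample. Introns are kept because real pileups of
expressed genes show exon-concentrated structure against near-empty intron
background, and that contrast is part of the shape being scored; an
`exons_only` projection is available for libraries where intronic signal is
uninformative. Extraction from BAM/SAM counts aligned bases of retained
reads: spliced segments (CIGAR `N`) and deletions contribute nothing to the
skipped reference positions, counting is strand-agnostic (the intended
inputs are unstranded libraries), secondary and supplementary alignments
are skipped by default (`count_mode="primary_only"`), duplicates are kept
(`keep_duplicates=True`), and the MAPQ floor defaults to 0. All of these
are flags, not assumptions baked into the arithmetic. Internally all
coordinates are 0-based half-open; GTF is converted from 1-based inclusive
at the boundary, BED12 is native.

## Level of Shape Similarity

The score for gene g, sample s is the cosine between the sample's
log-adjusted coverage vector and a cohort consensus profile.

**Log adjustment.** `x = log10(d + k)` with `k = 1` (unitless pseudo-count).
k = 1 makes zero depth map to exactly 0, keeps vectors non-negative (so the
cosine lies in [0, 1]), and compresses the dynamic range so that shape, not
amplitude, dominates the angle. k is exposed because other pseudo-counts
are defensible; the interpretation of "k-adjusted" as the offset inside the
log is a design choice of this package.

**Expressed-sample floor.** A sample "shows expression" if it has any read
in the analysis domain — the simplest testable definition. If fewer than
`min_expressed_frac = 0.05` (5%) of samples show expression, no consensus is
estimated and every sample scores 0. This floor prevents a handful of
noise-dominated pileups from defining a "consensus" that would then
certify each other as *on*. The boundary is inclusive (exactly 5%
qualifies).

**Consensus estimation.** The consensus starts as the plain mean of the
expressed samples' log-adjusted vectors. Each round, every expressed
sample is scored against the current consensus, the lowest
`floor(trim_quantile * n_expressed)` samples are set aside
(`trim_quantile = 0.05`), and the mean is re-estimated over the remainder —
always trimming from the full expressed set, so a sample excluded in one
round can re-enter later. Iteration stops when the L2 change of the
consensus drops below `tol = 1e-6` or after `max_iter = 20` rounds; with
identical columns it converges in one round. The trimming robustifies the
consensus against outlier shapes (degraded or aberrant samples) without
requiring any distributional model. Ties at the trim boundary are broken
by sample-id lexicographic order so results are bit-reproducible.

**Degenerate inputs.** A gene with zero reads in every sample scores
exactly 0 everywhere (shape undefined); a zero-depth sample scores 0
through the zero-norm convention of the cosine (0 rather than NaN). Final
values are clipped to [0, 1] to absorb floating-point overshoot of order
1e-16.

## On/off calls and offonome sets

A sample is *on* iff LSS > `lss_threshold = 0.6`, strictly: the threshold
sits in the density gap of bimodal LSS distributions (sex-specific genes),
so the boundary assignment is essentially arbitrary; strict-greater is
adopted and documented, making 0.6 itself *off*. The threshold is fixed,
not per-gene adaptive, by design: the method's value is a single
interpretable cut near the detection limit.

The offonome is the set of genes off in at least `min_off_frac = 0.20` of
samples, boundary inclusive, with off fractions computed over the samples
retained by the degradation filter (pipeline order: extract → degrade
filter → LSS → on/off → offonome → cluster). Off fractions are reported
for every gene so membership decisions are auditable.

`count_filter` reproduces the edgeR-default `filterByExpr` semantics (CPM
cutoff `min_count / median(lib.size) * 1e6`, required in at least the
adjusted minimum group size `large_n + (n - large_n) * min_prop` samples,
plus a total-count floor of `min_total_count`) so that overlap between the
offonome and conventionally filtered gene sets can be quantified on any
data. It is a comparison utility, not a recommended filter; a test
cross-checks it against edgeR itself.

## Degradation filter

Degraded RNA loses coverage toward the 5′ end. The per-(sample, gene)
decay rate here is the sign-flipped OLS slope of `log10(depth + 1)` against
normalized 5′→3′ exonic position in [0, 1] (genomic order reversed for
minus-strand genes): flat coverage scores 0, 3′-biased coverage scores
positive, units are log10-depth per transcript length. A value is reported
only when at least 50 exonic positions have nonzero depth — slopes on
near-empty vectors are noise. This statistic is a transparent surrogate
with the ordering semantics the filter needs (higher = more degraded); it
lives behind a single function so an alternative decay formula can be
swapped in without touching the filter.

The filter itself: (1) pool all finite decay rates of the cohort; (2) cut
at the value ranked `ceil(top_frac * n)` (1-based) of the descending sort,
`top_frac = 0.05`, i.e. the pooled 95th percentile; (3) exclude samples in
which strictly more than `max_degraded_gene_frac = 0.10` of scored genes
exceed the cut. A sample with no scored genes is retained with fraction 0
and a warning. The threshold is an order statistic, hence invariant to
permutation and monotone in `top_frac`.

## Clustering and evaluation

Ward's minimum-variance linkage on Euclidean distances (the metric Ward
requires), via scipy, over either axis of either the LSS matrix or the 0/1
state matrix — binarized input is the default for offonome clustering, the
continuous matrix is supported because both views are legitimate. The
merge tree is cut into k groups by removing the k−1 highest merges; k is
user-chosen (dendrogram inspection), never automatic. Cluster ids are
assigned in dendrogram leaf order for determinism. The classification
rate assigns each cluster its majority true label and reports the
percentage of samples explained, both raw and rounded to the nearest
integer percent; majority ties resolve to the alphabetically first label
and are flagged. The linkage implementation is validated against an
exhaustive merge-criterion search on instances of up to 8 points.

## Synthetic cohorts

The simulator generates what the score assumes about real data, with
ground truth:

- **Gene structure**: exon/intron layouts sampled from ranges (default 5
  exons of 100–300 bp, introns 100–500 bp), laid head-to-tail on one
  contig.
- **Shared shape**: per-gene positive template = smooth log-Gaussian
  positional modulation (SD `template_roughness = 0.5`, smoothing scale 50
  bp, roughly a read footprint) × per-exon lognormal levels, normalized to
  exonic mean 1; introns carry `intron_leak = 0.01` of the exonic level.
- **On samples**: per-base depth ~ negative binomial with mean
  `depth_mean × library scale × template` (`depth_mean = 50`,
  dispersion 0.3 so var = m + 0.3 m²; lognormal library scales, σ = 0.3).
- **Off samples**: Poisson(`background_reads = 3`) whole reads of
  `read_length = 50` placed uniformly over the locus — blocky, inconsistent
  pileups, deliberately *not* i.i.d. per-base noise.
- **Degradation**: a fraction `degraded_sample_frac = 0.1` of samples has
  its templates attenuated by `exp(−δ · position)` with
  `decay_strength δ = 4` (≈ e⁻⁴ ≈ 2% of 3′ coverage remaining at the 5′
  end, a severe but realistic degradation profile) before sampling. The
  documented detection floor is δ\* = 2: cohorts simulated at or above it
  are flagged with sensitivity and specificity ≥ 0.9 at default filter
  parameters.
- `on_prob = 0.7` per gene-sample gives cohorts where typical genes carry
  a ~30% off fraction — squarely in offonome territory with both classes
  well represented.

All randomness flows from one seed via `numpy.random.SeedSequence`
spawning (stream 0: structure; stream 1: states, degradation, library
scales; streams 2+i: per-gene depths), so cohorts are bit-reproducible and
every artifact records its parameters. `export_sam` decomposes each depth
vector into maximal coverage runs, chunks them to the read length, and
writes per-sample SAM files whose re-extracted pileup equals the stored
matrix exactly — giving the extraction path an end-to-end oracle.

What the simulator does **not** emulate: fragment-level effects (GC and
positional priming bias, duplicates), per-base autocorrelation beyond the
smooth template, splice-isoform mixtures, and partial degradation confined
to a gene subset. Passing recovery tests therefore demonstrates that the
pipeline identifies the *modeled* contrast (shared structured shape vs
sparse incoherent background, global 3′ bias) at realistic depths; they do
not certify performance under biases the generator omits.

## Problem sizes and tolerances in the test suite

Simulation-recovery tests use cohorts of 30–45 genes × 40–60 samples
(≥ 2,000 gene-sample pairs for accuracy estimates, 200 samples for the
bimodality check), sizes at which the Monte-Carlo noise of the assessed
rates is well below the asserted margins. Oracle-equivalence tests assert
1e-12 agreement (identical arithmetic up to summation order), analytic
identities 1e-12, and the consensus-trimming fixture 1e-9. Set-arithmetic
worked examples are exact integer checks.

## Known limitations

- The decay statistic is a surrogate chosen for its ordering semantics;
  it is not claimed to reproduce any particular published exclusion list.
- A fixed LSS threshold is a compromise: the optimal cut drifts with
  expression level, and very short genes give noisy cosines (fewer
  positions, heavier tails).
- Cohort LSS is O(genes × positions × samples) in memory per gene; very
  long loci with thousands of samples should use the `exons_only` domain
  or chunked extraction.
- The edgeR-comparison filter implements the default (single-group or
  explicit `group`) code path only, not design-matrix hat-value logic.
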