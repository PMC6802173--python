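# Methods

## Scope and assumptions

seregnet operates strictly downstream of alignment and peak calling: its
inputs are signal-scored peak intervals (BED/narrowPeak), refFlat gene
models, expression tables, and optionally single-position read placements.
All coordinates are 0-based half-open. Chromosome names are matched by
exact string equality; a validation helper warns when two inputs share no
chromosome names (the usual `chr1` vs `1` mismatch) rather than silently
producing empty intersections.

Peaks are treated as points for all occupancy logic: the *center* is the
geometric midpoint `floor((start + end) / 2)`, and narrowPeak summit
columns are ignored. Point semantics remove peak-length dependence from
feature assignment and overlap windows. Gene-level operations collapse
transcripts to one model per symbol — the widest span, ties broken by
transcript name — since isoform resolution is outside the method.

## Super-enhancer calling

1. **TSS exclusion (±2.5 kb default).** A peak is removed only when its
   interval is *fully contained* in `[tss − z, tss + z)`; partial overlaps
   survive. Exclusion runs before stitching, so promoter-proximal signal
   never seeds a stitched region.
2. **Stitching (12.5 kb default).** Single-linkage merging on the gap
   between interval ends: peaks whose gap is ≤ the stitch distance join one
   region, and merging is transitive. A sorted sweep with a running
   maximum end implements the closure exactly; the test suite checks it
   against an O(n²) union-find oracle. Region signal is the **sum of
   constituent peak scores** (per-bp coverage is not available at this
   stage of the data).
3. **Elbow cutoff.** Regions are sorted by ascending total signal; with
   rank mapped to x ∈ [0, 1] and min–max-scaled signal to y ∈ [0, 1], the
   cutoff index is `argmax(x − y)` — for a convex ascending curve this is
   the point where the tangent slope reaches 1. Super-enhancers are the
   regions with signal **strictly above** the cutoff signal, so boundary
   ties stay typical. Fewer than 3 regions or a zero signal range raise
   explicit errors instead of returning a degenerate partition.

**Known limitation — discreteness of the elbow.** On small region sets the
discrete argmax is sensitive to the upper order-statistic gaps of the
typical-enhancer signal distribution. With exponential typical signals the
largest typical-to-typical gap is on the order of the signal mean
(memorylessness), while one rank step on the scaled diagonal is
`(max − min)/(n − 1)`; when the two are comparable the cutoff can land one
or two ranks below the strongest typical region and promote it into the SE
set. Recall of true SE clusters is unaffected (they sit far above any
cutoff placement); only exact set equality degrades. At the default
synthetic conditions (210 regions) roughly half of seeds yield one or two
such extra calls; with thousands of regions, as in genome-wide data, the
diagonal step shrinks and the effect vanishes. We keep the plain argmax
rule because it is the standard formalization of the slope-1 tangent
criterion and any smoothing would trade transparency for stability.

## Feature annotation

Precedence is promoter > upstream > intron > exon > intergenic, evaluated
for the peak center against every gene; the highest-precedence feature
across genes wins, with ties broken by TSS proximity then symbol. Promoter
is |center − TSS| ≤ 2 kb on either side; upstream is 2–20 kb 5′ of the TSS
on the gene's strand; intron/exon require the center inside the gene body.
Regions 3′ of a gene are intergenic — the hierarchy has no downstream
category. Note the stated order ranks intron above exon; the package
follows it as given.

Two related but distinct gene-assignment rules coexist deliberately:
enhancer *counting* uses 20 kb upstream + gene body (no downstream
window), while network *target assignment* uses the gene body ± 20 kb on
both sides with a nearest-gene fallback (distance to TSS first, then to
the gene-body boundary, then lexicographic symbol — a documented total
order so results are deterministic).

## Co-occupancy and correlations

Centers of peaks from different factors within a **strict** 500-bp window
(distance < 500) overlap; chained overlaps merge into one union site via
single linkage (a sorted sweep over centers). A union site's interval
spans its members; its anchor is the lower median of member centers. The
occupancy matrix is binary — a factor either contributed a peak to the
site or not — and every row has at least one 1 by construction.

Pearson correlations are computed between binary factor columns over the
global union-site universe by default; a `pairwise` mode rebuilds a
two-factor universe per pair for users who prefer the per-pair
construction. A factor bound at every site (or none) has zero column
variance; its correlations are reported as missing, never coerced to 0,
and such factors are excluded from the average-linkage (1 − r) clustering
that supplies the display order.

## Network and circuitry

Edges are TF → gene with the supporting peak ids as evidence; "binding
near a gene implies regulatory control" is the (deliberately simple) edge
semantics, with no activation/repression sign. Factors are linked to their
own genes through an explicit factor→gene map rather than name equality,
so `cFos` vs `Fos` naming mismatches cannot silently hide autoregulation.
Circuitry is enumerated on the TF-restricted subgraph: autoregulators are
self-edges; feedback pairs are unordered mutual edges; feed-forward loops
are ordered triples (A, B, C) of distinct TFs with A→B, B→C, A→C — the
standard FFL convention, so a complete triad contains 6. Peaks on
chromosomes without any gene are skipped with a logged warning.

## Expression analyses

All ratios add a pseudocount (default 1.0) before division; expression is
assumed non-negative and TPM-like, with no internal normalization.

- **Moving average:** genes ranked descending by log2 pseudocounted mean
  ratio (ties by symbol for determinism), window (default 100 genes) slid
  with step 1 over the enhancer counts in that order.
- **Time-course classes:** profiles divided by their per-gene mean (rows
  average exactly to 1); clustering operates on log2 of the
  pseudocounted relative profile. Hierarchical average linkage is cut
  into four classes, labeled by archetype: the minimum-variance centroid
  is the flat class, the rest matched one-to-one to
  biphasic/decreasing/increasing templates by maximal correlation
  (Hungarian assignment). The default distance is **Euclidean** on the
  log2 relative profiles: a flat-class gene's profile is noise around
  zero, so flat genes form a tight cluster at the origin under Euclidean
  distance, whereas their pairwise Pearson correlations are undefined in
  the noise-free limit and essentially random under noise, scattering the
  flat class across the dendrogram. Correlation distance remains
  available (`timecourse_metric: correlation`) for structured-profile
  data. All-identical profiles raise an error naming the genes.
- **Cross-dataset screen:** per dataset, genes ranked by log2
  pseudocounted case/control mean ratio; the top and bottom
  `floor(0.10 × n)` genes are extreme. A gene qualifies when it is an
  ortholog of an SE-associated gene and extreme in ≥ 3 datasets;
  direction is the majority of its extreme hits (up/down/mixed). The
  comparison is a mean ratio, not a test statistic — the screen is a
  rank-intersection filter, not a differential-expression test.

## Signal profiling

Reads enter as single representative positions. Offsets in [−3000, +3000)
around each center are binned at 100 bp (half-open bins; +3000 itself is
excluded); bin counts are summed over centers, divided by total reads in
millions, and averaged over centers. Everything is reads-per-million, so
duplicating the library is an exact no-op — a property the tests check
bit-for-bit. Profiles are not strand-flipped (peaks are unstranded).

## Synthetic data: what it does and does not emulate

The generators are pure functions of (parameters, seed) and return the
planted truth alongside the data.

- **Landscape:** exponential peak signals produce the convex "hockey
  stick" rank curve that makes an elbow meaningful; typical peaks are
  isolated (pairwise gaps > stitch distance) and clusters sit > stitch
  distance from other peaks and clear of TSS exclusion zones, so each
  planted cluster stitches into exactly one region whose extent is
  recorded as truth. Defaults: 200 typical peaks (mean 5), 10 clusters of
  8 peaks (mean 50) within 10-kb spans, 200 genes on two 20-Mb
  chromosomes.
- **TF peak sets:** factors bind shared anchor sites independently with a
  per-factor rate (scalar or sequence), jittered ±100 bp, plus private
  sites per factor. Independent binding plus private sites yields
  positive correlations between high-rate factors and negative
  correlations against low-rate factors over the union universe; it does
  not emulate cooperative binding or motif content.
- **Time-course:** four fixed log2-scale template shapes (cosine
  biphasic, linear down, linear up, flat) scaled by a lognormal per-gene
  baseline with multiplicative lognormal noise (default σ = 0.1).
- **Case/control:** per-gene log2 baselines N(6, 2), per-sample noise
  N(0, 0.2), 5 + 5 samples, planted genes shifted ±2 in case means.

None of the generators mimic real chromosome sizes, mappability, GC
structure, replicate variability, or batch effects; passing recovery
tests demonstrates the correctness of the algorithms under the stated
statistical model, not performance on real sequencing data.

## Problem sizes and determinism

The package's own validation (test suite and `scripts/acceptance.py`)
runs at the generator default sizes above — 100 seeds for landscape
recovery and oracle-equivalence checks, 20 seeds for time-course
recovery, 10 for the dysregulation screen — chosen so the whole
validation completes in seconds while keeping Monte-Carlo standard errors
small. Every stochastic component takes an explicit seed; the demo
pipeline is byte-deterministic given its seed, and the run manifest
records SHA-256 digests of all inputs and outputs.
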