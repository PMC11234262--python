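# Methods

This note documents the models and procedures implemented in `regulome`,
the conventions and defaults chosen where the problem left them open, and
what the synthetic-data tests do and do not demonstrate about real data.

## Coordinates and formats

All intervals are 0-based half-open internally (the narrowPeak/BED native
convention); GTF/GFF3 input (1-based inclusive) is converted on read. The
TSS of a gene is its biological 5′ end: `start` for '+' genes and `end − 1`
for '−' genes. Annotations carry a single TSS per gene; multi-isoform TSS
handling is unresolved and out of scope — callers who care should collapse
isoforms to a representative model upstream. Gene bodies are never used:
the target-assignment window is TSS-anchored only.

## Consensus binding sites

Peaks from *D* datasets are extended symmetrically by `flank` bp (default
150, clamped at the chromosome origin). Two peaks qualify as mutual
evidence iff they come from different, non-excluded datasets and each
extended interval is covered by the overlap to at least
`min_reciprocal_frac` (default 0.75). A **site** is a connected component
of the qualifying graph spanning at least `min_support` (default 2)
distinct datasets, reported on the union span of members' *original*
coordinates: the flank is a jitter-tolerance device, not a claim about
site boundaries.

Conventions worth stating because they are genuinely ambiguous:

- The qualifying threshold is `≥` rather than strictly `>` (matching how
  the standard interval tools implement "75% reciprocal overlap"); a
  `strict` flag flips this.
- Excluding a dataset pair removes *edges*, not peaks. Two excluded
  datasets bridged by a third still merge into one site, and both count
  toward the distinct-support minimum.
- Output order is (chrom, start, end), with deterministic site ids, so
  reruns are byte-identical.

The production implementation is a per-chromosome sweep with union-find
(near-linear in sorted peaks); an independent O(n²) all-pairs +
breadth-first-components oracle lives in the test suite and the two are
compared exactly on hundreds of randomized instances.

## Target and non-target genes

Each site is anchored at its midpoint, `floor((start+end)/2)`. For a gene
with TSS *t*, the signed distance is `anchor − t` on '+' genes and
`t − anchor` on '−' genes (positive = downstream). The gene is assigned
iff the distance lies in the closed window `[−upstream, +downstream]`
(default 4 kb both sides); bracketed window notation is read as inclusive
on both boundaries. A site may hit several genes and vice versa.

**Targets** = bound genes ∩ (union of per-factor upregulated gene lists).
What "consistently upregulated" means is delegated to the upstream
overexpression study that produced those lists; this package only
intersects. **Non-targets** are defined more stringently than
"not a target": no peak from *any single dataset* (midpoint test, same
window) and membership in no upregulated list. This makes the control set
conservative — genes with even one-dataset binding evidence are excluded
from it.

## Expressed-gene flags

Thresholds are stated per unit in log form (log10 TPM > 0.75,
log10 TP10k > 0.1, normalized counts > 5) but applied in linear space with
a strict inequality, which is mathematically identical and needs no
pseudocount for zeros: a value exactly at the cutoff is *not* expressed.
Replicates are averaged (arithmetic mean, linear scale) before
thresholding. The TPM cutoff of 10^0.75 was chosen in the source analyses
from density plots of the log-expression distribution; this package treats
all thresholds as configuration and implements no automatic cutoff
detection.

## Trajectory enrichment

Per cell, the expressed fraction of a gene set is
`100 · (#set genes flagged) / (#set genes present in the matrix)`.
Curves are means of this per-cell fraction in half-open pseudotime bins
`[k·w, (k+1)·w)` (default w = 0.1), left-anchored at 0 and labelled by
midpoint; bins with fewer than 2 cells are dropped. A loess smooth
(statsmodels lowess, span 0.75, locally linear) is available for
presentation only; nothing quantitative depends on it.

The early/late contrast takes the *k* = 10 earliest (or latest) cells by
pseudotime — ties at the cutoff broken by lexicographic cell id, making
the selection input-order invariant — and compares the per-cell target
fractions against the per-cell non-target fractions of the *same* cells
with a one-tailed Welch *t*-test (alternative: targets higher):

t = (x̄_T − x̄_N) / √(s²_T/k + s²_N/k), df by Welch–Satterthwaite,
p = upper tail of Student's t.

Pairing the two sets on the same cells is the only reading under which the
test's n equals the number of extreme cells. The fold enrichment is the
ratio of the two group mean percentages (not a pooled-cell fraction ratio,
for consistency with the test structure). Before any of this, genes not
expressed in at least `min_cell_frac` (default 10%) of the early *or* late
reference cells — pseudotime ≤ 1 and ≥ 86 on the protophloem-style axis,
or groups {T0,T1} / {T8,T9} on group-annotated data — can be removed; both
rules are configurable, and the filter is skipped when no rule applies.

## Core regulome

The core is the intersection of the target set with each tissue's
expressed-gene set; it is monotone non-increasing in the number of tissues.
Per evaluation dataset, enrichment is
`log2(% core expressed / % complement expressed)`, with both percentages
computed over genes actually measured in that dataset so assay coverage
does not deflate them. The complement defaults to the non-target set from
the target-definition stage (keeping panels comparable), configurable to
"all measured genes outside the core". A complement with zero expressed
genes yields NaN with a warning, never a silent infinity.

## Segregation

Observed affected counts are tested against an expected fraction (default
0.25, a fully recessive two-locus lethal in a selfed heterozygote) with
the exact two-sided binomial test in the minimum-likelihood summation
convention (`scipy.stats.binomtest`); the test suite re-derives it by
exhaustive summation over all n+1 outcomes. Reported class frequencies use
half-up integer rounding (20/29 → 69%).

## Synthetic-data generators

The generators plant known truth and emit exactly the flat formats the
readers accept; all are byte-deterministic under their seed.

- `gen_genome`: fixed-length genes, random strand, TSS spacing ≥
  `min_spacing` enforced by construction.
- `gen_peak_sets`: shared sites copied into each dataset with independent
  Normal(0, `jitter_sd`) start jitter; decoy peaks placed at least
  `2·(peak_len + 2·flank)` from everything so they can never qualify.
  With zero jitter, consensus recovery is exact by construction and tested
  as such.
- `gen_expression_trajectory`: cell pseudotimes uniform on [0, t_max]
  (default a normalized [0, 1] axis); per gene-cell Bernoulli expression
  with probability interpolated linearly from an early value (default 0.40
  for targets, 0.20 for background) to a shared late baseline (0.10) —
  the simplest monotone emulation of the observed decaying curves. TPM
  values are emitted threshold-consistently (expressed → uniform above the
  cutoff, silent → uniform below), so flagging inverts the planted draws
  exactly and threshold logic is decoupled from distributional realism.
- `gen_multi_tissue_expression`: core genes expressed per tissue with
  probability `p_core` (default 0.75), others `p_other` (0.35).
- `gen_segregation`: a single binomial draw.

What passing these tests shows: the interval algebra, graph semantics, set
algebra, binning and test statistics are correct, calibrated (the Welch
test's null rejection rate is verified by simulation) and recover planted
parameters within sampling error. What they do not show: robustness to
real scRNA-seq count noise (no negative-binomial dispersion, no dropout
structure), to pseudotime estimation error, to peak-caller artifacts, or
to annotation incompleteness — real inputs arrive after all of those.

## Problem sizes and numerical choices

Default desk-scale test sizes — ≤ 50 peaks over 3–5 datasets for oracle
comparisons, 100–120 cells with 300 target / 3000 background genes for
trajectory plants, 2400 genes with a 400-gene core for multi-tissue plants,
10,000 simulations for test calibration — were chosen so the whole suite
settles in seconds while keeping binomial standard errors small relative
to the planted effects. Planted-recovery assertions use 3-SE bands for
single comparisons and Bonferroni-adjusted simultaneous bands when a test
sweeps all pseudotime bins at once. Percentages are kept on the 0–100
scale everywhere; degenerate inputs (empty sets, empty groups, zero
variance, zero-expressed complements) raise informative errors rather than
produce NaN silently, except where a NaN sentinel is the documented
behaviour.

## Known limitations

- Consensus sites are merged components; alternative readings (peak pairs,
  summit-clustered sites) would count differently on deeply overlapping
  inputs.
- Target assignment uses one midpoint distance per site–gene pair; a site
  half-overlapping a window edge contributes all or nothing.
- Whether a bound-gene count "per site" or "per peak" is wanted depends on
  the question; this package counts distinct genes over merged sites.
- The pipeline consumes called peaks and precomputed pseudotime; peak
  calling and trajectory inference are deliberately out of scope.
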