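# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic-data generators do and do not emulate, and the
numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and interval semantics

All genomic coordinates are 0-based half-open (`[start, end)`), the native
BED convention; the GTF reader converts its 1-based inclusive coordinates
at the parsing boundary. Two intervals overlap when their intersection is
at least `min_overlap_bp` bases (default 1), so half-open adjacency never
counts. A single convention internally eliminates off-by-one ambiguity;
the overlap threshold is a parameter because "bound by" / "marked by" has
no universal definition across ChIP analyses. Strand influences only TSS
derivation (`tss = start` for `+`/unstranded records, `end − 1` for `−`),
never overlap arithmetic.

## Signal tracks

A `SignalTrack` stores one non-negative value per fixed-width bin
(default 50 bp, configurable — typical for ChIP-seq coverage tracks;
`ceil(length / bin_width)` bins per chromosome, last bin possibly short).
bedGraph records are binned as coverage-weighted means with uncovered
bases counting as zero, which makes per-base quantification exact: a
region total is the sum over covered bases of the bin value, and region
mean = total / region length, so totals are additive over partitions.

Smoothing is a centered moving average over an odd number of bins
(default 5, matching the practice of averaging five consecutive bins to
stabilize low signal-to-background factors). At chromosome edges the
window truncates to the bins that actually exist rather than reflecting —
reflect-padding would fabricate support where none exists; truncation
keeps every output bin an average of observed data only.

## Specificity index, pSI and TSI

Expression is collapsed to per-tissue means first. For tissue *t* and each
other tissue *u*, genes are ranked by descending ratio
`(mean_t + pc) / (mean_u + pc)` with average ranks on ties; SI(g, t) is the
mean rank over the T−1 comparisons (lower = more specific). The
pseudocount (default 1, in expression units such as TPM) keeps ratios
defined at zero expression and damps rank instability among barely
expressed genes; ratio ranks are otherwise scale-free.

pSI(g, t) is a permutation p-value: sample→tissue labels are shuffled, SI
is recomputed, and null SI values are pooled per tissue **across genes**;
pSI = (1 + #{null ≤ SI}) / (1 + N_null), the add-one correction keeping
pSI in (0, 1]. When the number of distinct label permutations is at most
`n_perm` the null is enumerated exhaustively (then seed-independent);
otherwise `n_perm` (default 1000) random shuffles are drawn from the
explicit seed. Pooling across genes assumes genes are exchangeable under
the null; it buys p-value resolution N_genes-fold beyond the permutation
count.

TSI aggregates a gene's pSI row. The defining formula is
`TSI = −log10(max pSI)`; `tsi()` implements it verbatim (and is then
monotone non-increasing in every entry). For screening, the max is taken
over the tissues in which the gene is *called specific*
(`max_psi` cutoff; genes with no entry at or below the cutoff get max pSI
= 1, i.e. TSI = 0), mirroring the convention of specificity-index software
in which non-candidate entries are undefined. The pipeline default cutoff
is 0.01 rather than the more common 0.05, for a structural reason: a gene
truly specific in tissue *t* has a hard floor on its SI in every other
tissue — the comparison against *t* ranks it at the bottom, so
SI ≥ ((T−2)·1 + G)/(T−1) (≈ 56 for 500 genes, 10 tissues) — and the pooled
null places a few percent of its mass below that floor. A 0.05 cutoff can
therefore admit a spurious second-tissue entry into the row max and wipe
out the gene's TSI, whereas 0.01 sits below that null mass and makes the
contamination impossible at these problem shapes.

Permutation p-values are quantized to multiples of 1/(1 + N_null), so
genes whose SI undercuts the entire finite pool collapse onto the same
TSI. `specificity_ranking` therefore orders genes by TSI and breaks ties
by the gene's best (smallest) SI — the statistic the p-value summarizes —
then by gene id, making rankings deterministic and faithful to the
underlying evidence.

### The two-axis screen

Cohort variance is the sample variance (ddof = 1) of log₂(x + 1) across
tumor samples; the log stabilizes the heavy right tail of expression so
that variance reflects bimodality rather than scale. `screen()` selects
genes with TSI ≥ tsi_min and variance ≥ var_min (defaults: the 90th
percentile of each axis, always overridable), returning the full two-axis
table for plotting. Percentile thresholds are descriptive, not
inferential: by construction ~10% of genes pass each axis, and since the
two axes are computed on independent datasets a few null genes pass both
jointly by chance (~n_genes/100 in expectation). Exact recovery of a
planted candidate set should therefore be assessed with thresholds at the
planted margins or via the ranking, not via percentile defaults; the test
suite checks both behaviours explicitly.

## Super-enhancer calling

Peaks whose inter-peak gap (`next.start − prev.end`) is at most the stitch
distance merge transitively per chromosome; the default 12,500 bp is the
long-standing convention for enhancer stitching, and a gap of exactly the
distance still merges. Optional TSS exclusion (off by default, window
±2,500 bp) removes peaks lying fully inside promoter windows before
stitching.

Region signal is `max(0, total_factor − total_input)` (background
subtraction floored at zero so region signal stays a non-negative
quantity). Regions are sorted ascending by signal with ties broken by
genomic order — documented so runs are bit-reproducible — and rank 1 is
the highest signal. On the min–max-scaled curve (rank index and signal
each mapped to [0, 1]) the cutoff is the first index, scanning from the
left, whose forward difference quotient exceeds 1; the unscaled signal at
that index is the cutoff and regions **strictly above** it are
super-enhancers. A flat curve, or one that never out-climbs the diagonal,
yields zero SEs. Because the geometry runs on the scaled curve, the SE set
is invariant under positive affine rescaling of the signal.

SE sets are compared by ≥ 1 bp overlap: pairwise fractions (fraction of
A's SEs touching any SE of B), the fraction of A overlapping the union of
the other sets, and Venn-style counts over connected components of the
pooled regions.

## Loop filtering and enhancer–gene association

A loop is retained iff both anchors overlap at least one H3K27ac interval
(≥ 1 bp); an optional `max_score` keeps loops at or below a significance
score (scoreless loops pass — the caller upstream is trusted). The filter
preserves order and is idempotent. Association tests, for each loop, both
orientations of (enhancer on one anchor, TSS ± window on the other;
window default ±2.5 kb, a conventional promoter-proximal span). One
association is emitted per (enhancer, gene, loop) triple; hits confined to
a single anchor are not associations; a loop connecting two
enhancer+promoter anchors may associate in both directions, flagged in the
evidence string. There is deliberately no nearest-gene fallback: the point
of loop-based assignment is that contact evidence, not proximity, names
the target.

## Synthetic data

The generators produce the statistical *structure* the pipeline is built
for, at desk scale, with every planted object recorded in a JSON manifest
and byte-identical regeneration under a fixed (seed, parameters) pair.

**Tissue expression** (default 500 genes × 10 tissues × 10 samples):
log-normal baseline abundance (median 50, σ = 1 in natural log), planted
genes multiplied by `fold` (default 8) in one random tissue, multiplicative
log-normal noise of σ = 0.5 per measurement (~53% CV between samples of a
tissue, a realistic between-individual spread for bulk expression). Ten
samples per tissue emulates a modest multi-tissue atlas; specificity
detection operates on tissue means, whose noise shrinks as 1/√n.

**Tumor cohort** (default 500 genes × 30 samples): planted bimodal genes
are high (× 8) in exactly `round(fraction_on × n_samples)` samples
(default 30%) and baseline elsewhere — the "subset-expressed" pattern of
an oncogene aberrantly activated in a fraction of tumors.

**Regulatory genome** (default 3 chromosomes × 5 Mb, 50 bp bins): isolated
1 kb enhancer peaks and gene promoter peaks, plus dense clusters of 5
peaks spaced 2 kb apart (span 13 kb, stitchable into one region). Sites
are rejection-sampled with ≥ 15 kb separation — beyond the stitch distance,
so no cross-site stitching can occur — with a deterministic retry cap.
Per factor, each H3K27ac site draws a target signal total
(base × U(0.5, 1.5)); clusters occupied by the factor are boosted by
`signal_gap_fold` (default 20), which produces the hockey-stick ranked
curve with a clean background band. The first factor occupies every
cluster; later factors occupy a `shared_fraction` subset (default 0.7),
giving designed SE-overlap fractions. A flat low input track stands in for
control coverage.

**Loops**: true loops run from the first peak of a distinct cluster to a
distinct gene's promoter peak; decoys connect regions ≥ 12.5 kb away from
any H3K27ac peak, so the activity filter removes exactly the decoys.

What the generators do **not** emulate: read-level noise and mappability
artifacts, copy-number variation, overlapping/nested regulatory domains,
distance-dependent contact frequency, correlated expression programs, or
batch structure. Passing the planted-recovery tests therefore demonstrates
correctness of the algorithms under their stated assumptions, not
performance on real libraries.

## Problem sizes in tests and the acceptance script

The recovery studies run 100 seeded screens at 500 genes × 10 tissues with
a 200-permutation null (the library default is 1000; 200 is the test-scale
choice and leaves the pooled null with 10⁵ values per tissue), and the
acceptance script reports the same quantities over 50 seeds derived from
its `--seed`. The synthetic genome defaults (100 sites over 15 Mb) let the
full pipeline run in seconds.

## Known limitations

* The pooled permutation null assumes gene exchangeability; strongly
  structured real expression (co-regulated modules, shared batch effects)
  violates it and would miscalibrate pSI.
* The SE cutoff uses the first-left-crossing of slope 1; curves with
  heavy-tailed background can cross early, and the caller intentionally
  does not smooth the curve first.
* `se_overlap` counts any ≥ 1 bp contact as shared; fraction-of-length
  reciprocal-overlap criteria are not implemented.
* Chromatin-state segmentations are consumed as given (disjointness across
  labels is enforced); training such models is out of scope, as are read
  alignment, peak calling and loop calling.
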