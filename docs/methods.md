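# Methods

This note records the models, conventions and numerical choices behind
smcpipe, and what the synthetic data can and cannot show about real
experiments.

## Coordinates and formats

All coordinates are 0-based, half-open (BED convention), including the TSS
column of the gene table; distances between intervals are edge-to-edge
gaps, matching the stitching semantics. I/O covers BED3/BED6, bedGraph
(fixed bins emitted per-bin), and TSV gene/count tables; malformed lines
fail with their line number, and strict mode validates coordinates against
chromosome sizes (which also catches 1-based exports whose end exceeds the
chromosome).

## Coverage and signal

Reads are extended to `extend_len` (default 200 bp, a common ChIP-seq
fragment size) in their strand direction, midpoint-symmetric when
unstranded, and binned at `bin_size` (default 50 bp; 25 bp is appropriate
for display exports). A bin counts every extended read overlapping it, so
bin sums exceed the read count; RPM scaling always uses the mapped-read
total, not the bin sum. Region signal is computed pro-rata over partial
bins, which removes bin-phase sensitivity: a region's total RPM equals the
integral of the per-base step function implied by the bins. Density is
total RPM divided by region length (reads per million per base pair).

## Occupied-region calling

The caller is deliberately simple: per bin, treatment count *k* is tested
against Poisson(λ) with λ = control count × (treatment depth / control
depth), floored at the control's genome-average bin rate so that sparse
control bins cannot manufacture significance. Bins with upper-tail
p < 10⁻⁵ are merged within 200 bp and regions under 100 bp are dropped. A
treatment identical to its control yields no calls, and the called base
count is monotone non-increasing in the cutoff. This is a pragmatic
stand-in for a full peak caller; it is exposed with all parameters
because the downstream region definitions only need reproducible,
control-disciplined calls on data whose enrichment is planted and strong.

## Region classes and gene association

Enhancers are the bases jointly occupied by OCT4, SOX2 and NANOG (set
intersection of the three region sets); promoters jointly by TBP and
POL II; heterochromatin is the merged union of H3K9me3 and H4K20me3.
Condensin II/cohesin co-occupied genes require at least one CAPH2 and one
SMC1 region within ±2,500 bp of the TSS (TSS-centric because promoter
occupancy is the organizing observation; the window is configurable).
Enhancer→gene assignment uses the nearest TSS within 50 kb, distance 0 when
the TSS falls inside the region, ties to the lexicographically smaller
gene id. Genes targeted by any super-enhancer classify as SE-associated even
if a typical enhancer is also nearby.

## Metagenes

Each region's body is rescaled to a fixed number of equal fractions
(default 60) so that ~700 bp typical enhancers and multi-kb super-enhancer
domains share one axis; flanks use fixed bins of the track's bin size
(1 kb flanks for enhancer/promoter panels, 3 kb for super-enhancer
panels). The profile is the unweighted mean across regions (each region
counts once regardless of width; a width-weighted variant is a flag).
Regions whose flanks cross a chromosome edge are dropped and counted in a
log message. The profile is linear in tracks at equal depth and invariant
to region order; both properties are tested.

## Super-enhancer identification

Constituents within 12,500 bp stitch into one domain (the distance is the
conventional stitching span for this analysis and is configurable; an
off-by-default flag removes TSS-proximal constituents first). Each domain
is scored by control-subtracted total RPM of the coactivator track;
negative scores are kept in records but floored at 0 for ranking, and ties
order by genomic position for determinism. On the ascending ranked curve
with both axes scaled to [0, 1], the cutoff is the point where a line of
slope 1 is tangent to the curve — computed discretely as the index
minimizing y − x, ties resolved to the topmost index. Geometrically this
is the point past which the curve rises faster than the diagonal; it
matches an exhaustive tangent search on piecewise-linear curves and is
invariant to adding a constant to all signals. An all-equal curve yields
no super-enhancers. Whether the original analysis used this tangent
criterion or a fixed threshold is not documented in the text available to
us; the tangent method is the standard choice for ranked-signal curves and
is the package default.

Fold differences follow two conventions: at *enhancers*, mean total RPM
over super-enhancer spans divided by the mean over typical spans (width
differences contribute); at *constituents*, mean density over
super-enhancer constituents divided by mean density over typical
constituents (a pure per-bp comparison).

## Rank normalization

To compare a factor's occupancy across conditions, each track's nonzero
bins are replaced by the value at the same fractional rank in a reference
distribution; ties share the mean of their rank range; zero bins stay
zero. By default the reference averages the two samples' empirical
quantile functions (quantile normalization to the pair average, the
standard choice — two identical tracks pass through unchanged, and the two
outputs share one value multiset). An explicit `reference` array may be
supplied instead; each output then depends on its track only through bin
ranks, making the normalization strictly invariant under any monotone
transform of that track's counts — the property to use when one fixed
scale must serve several comparisons. With the averaged reference that
invariance holds for the rank structure but not the values (the transform
moves the reference); this trade-off is inherent to any symmetric scheme
whose reference is built from the inputs. Idempotence is exact for
tie-free tracks with equal nonzero support and drifts at the ~1% level
otherwise (interpolation between unequal supports). The display floor
(0.2 by convention) is applied only at bedGraph export; analysis values
are never floored.

## Expression statistics

Counts are normalized to counts per million; fold changes are
log₂((mean kd CPM + c)/(mean control CPM + c)) with pseudocount c = 1 CPM
(configurable), and the two condensin II shRNAs are averaged at the level
stage before the ratio when pooled. CPM is a compositional scale: when
most genes go down, per-gene fold changes shift toward zero relative to
the simulated absolute effects; the class *difference* is unaffected,
which is what the comparison tests. Class comparisons use Welch's
unequal-variance t test (two-tailed for class contrasts, one-tailed where
a direction is pre-specified; pooled-variance available by flag) — the
robust default when only "t test" is conventional. Box statistics report
median, quartiles, whiskers at most 1.5×IQR beyond the quartiles clipped
to the data, and outliers beyond the fence. Spearman correlation uses
mean ranks on ties and is reported as undefined (NaN) for constant input.
No multiple-testing correction is applied: each comparison is reported
singly. qPCR relative quantities use the standard 2^−ΔΔCt arithmetic.

## Synthetic data

The generator is the package's study-condition definition, not a tuning
surface. The demo genome is 20 Mb over two chromosomes, divided into 50 kb
slots after carving heterochromatin domains (8 × 50 kb) off the
chromosome ends. A slot holds one enhancer entity and one gene: the gene's
TSS at +10 kb (promoter = TSS ± 1 kb, gene body from TSS + 1 kb so classes
never overlap), the enhancer entity at +25 kb — a super-enhancer cluster
(4 × 700 bp constituents, 2 kb apart, spanning ≈ 8.8 kb) or a single
700 bp typical constituent. The geometry guarantees that constituents of
one cluster are within stitching range, distinct entities are far beyond
it, and each enhancer's nearest TSS is its own slot's gene, so planted
gene classes match nearest-TSS assignment exactly. Defaults: 20 clusters,
300 typical constituents, 60 unassociated filler genes.

ChIP-seq reads are emitted as already-aligned 36 bp intervals: the genome
is segmented by element class, each segment weighted by background rate ×
class fold, the total is Poisson around the requested depth,
per-segment counts are multinomial and positions uniform. Enrichment
magnitudes are not published for these factors, so defaults are chosen
once at field-realistic levels and surfaced in `default_factor_profiles`:
Mediator (MED1) fold 20 at super-enhancer constituents vs 8 at typical
(density ratio 2.5), NIPBL/SMC1/CAPH2 12 vs 5 with promoter fold 6,
OCT4/SOX2/NANOG 16 vs 8, TBP/POL II 10 at promoters (POL II 4 over gene
bodies), H3K9me3/H4K20me3 10 in heterochromatin and 0 at regulatory
elements, and a flat whole-cell-extract control.

RNA-seq counts are negative binomial (dispersion 0.05) around
lognormal baseline means (~500 counts). Each gene draws a true condensin II
log₂ effect from its class distribution (means −1.0 for SE-associated,
−0.3 for TE-associated, 0 otherwise; sd 0.5); its cohesin effect is that
value × 1.3 plus N(0, 0.3) noise, because the two depletions hit the same
genes with the cohesin effect somewhat larger. Both CAPH2 hairpins share
each gene's true effect. Three replicates per condition.

What the simulation does *not* model: sequence content and mappability,
PCR duplicates, fragment-size variation, diploidy, enhancer–promoter
overlap, signal between cluster constituents (gaps sit at background, so
per-bp density across a whole super-enhancer span is not elevated the way
real domains often are), and transcription-coupled confounders. Passing
tests therefore demonstrate that the estimators recover what was planted
under clean Poisson/NB noise — not that they are robust to real-data
artifacts.

## Problem sizes and determinism

Tests and the acceptance script run the demo genome at 10⁶ reads per
factor, recovery checks over 20 simulation seeds, and 200 replicates for
null-uniformity checks — sizes at which every planted quantity is
measurable with comfortable margins on a single CPU in minutes. All
randomness flows from one master seed through per-stage SHA-256-derived
substreams (stable, independent, below 2³¹), so identical configuration
and seed reproduce byte-identical fixtures, summaries and manifests.

## Known limitations

The Poisson bin test is not a replacement for a production peak caller on
real data; the co-occupancy gene rule is TSS-window-based by design
choice; the tangent cutoff, while standard, is one of several published
conventions for separating the ranked-signal elbow; and CPM normalization
inherits its compositional bias (a DESeq-style size-factor scheme would be
the natural extension for real count data).
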