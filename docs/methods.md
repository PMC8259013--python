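# Methods

## The measurement model

An m6A epitranscriptomic array splits each RNA sample by antibody capture
into a methylated (IP, Cy5) and an unmethylated (supernatant, Cy3)
fraction, both spiked with an exogenous control mixture, labeled, and
hybridized in two channels. For a transcript with linear abundance *A* and
methylated fraction *m*, the two channels ideally measure *A·m* and
*A·(1−m)* up to an array/channel scaling. Because the spike-ins experience
the same scaling, the mean log2 spike-in intensity of each array/channel
identifies it, and subtracting it (then adding back the grand mean F̄ so
values stay on an intensity-like scale) aligns all arrays. % modification
is then `100·IP/(IP+SUP)` and expression the channel sum.

Two consequences of recentring by the grand mean are worth stating.
First, % modification is exactly invariant under rescaling of any single
sample's raw intensities — it is a within-sample ratio. Second, expression
is invariant only up to one multiplicative constant shared by every sample
and transcript (rescaling one sample shifts F̄ itself); fold changes and
all downstream calls are unaffected, and the tests assert exactly this
form of equivariance.

## Synthetic data: what it emulates and what it does not

The generator emulates a rat mRNA + lncRNA array design at reduced scale:
2200 mRNA and 800 lncRNA probes by default (~the 2.6:1 ratio of the
emulated 38k-probe design, sized so that a 20-simulation recovery study
runs in seconds), 20 spike-ins, 3 phenotype groups × 3 replicates.
Choices, with units and defaults:

- **Baseline abundance**: log2 ~ Normal(10, 2) — a typical span of
  microarray signal above background.
- **Baseline methylation fraction**: Beta(2, 2) on (0,1) — bounded,
  symmetric, mildly concentrated at intermediate fractions.
- **Planted effects**: logit shifts of the methylation fraction and log2
  shifts of abundance, magnitude 2 by default (~7.4-fold odds change /
  4-fold expression), on ~5% of transcripts per kind, split between the
  two stimulated groups with alternating signs; a small block carries both
  kinds so all four joint quadrants are populated. Effects are applied on
  the logit scale so fractions stay in (0,1). The baseline fraction of a
  methylation-effect transcript is drawn from the band where the planted
  change is expressible on the percent scale (gains start in [0.15, 0.50],
  losses in [0.50, 0.85], truncated Beta): planting a gain on an
  already-saturated transcript would be biologically vacuous and, because
  the percent scale is bounded, could never reach the 1.5-fold calling
  threshold.
- **Array effects**: per sample × channel log2 offsets ~ Normal(0, 0.5),
  shared by all probes of that array/channel *including spike-ins* — this
  sharing is precisely what makes spike-in normalization identifiable.
- **Measurement noise**: independent multiplicative log-normal noise per
  probe × sample × channel, sd 0.1 on the log2 scale — a typical residual
  technical variance after normalization. Noise must be per-channel:
  noise shared by both channels of a sample would cancel in IP/(IP+SUP),
  making % modification replicate-identical and the t-test degenerate;
  with per-channel noise the null P values are uniform to good
  approximation (the null type-I fraction at α=0.05 sits in [0.03, 0.07]).
- **Spike-ins**: fixed known abundances, log2 evenly spaced in [6, 14],
  with the same array effect and noise as real probes.
- **Gene sets**: 30 pathways of 25 symbols; 3 are planted with 80% of
  members drawn from expression-upshifted genes of the second group, so
  over-representation is guaranteed by construction.
- **qPCR**: Ct = c0 − log2(amount) + Normal(0, sd_ct); sd_ct 0.2 cycles,
  input fraction 0.1, reference gene constant across groups. With noise
  off, 2^−ΔΔCt and percent-input recover the designed values exactly.

All randomness derives from one seed via named SeedSequence children per
stage, so partial runs and full runs agree file-for-file.

What the generator does **not** emulate: image-level artifacts, dye bias,
probe cross-hybridization, probe-level replication (one probe per
transcript), correlated biological variability between transcripts, or
heavy-tailed outliers. Passing tests therefore demonstrate correctness of
the arithmetic and calibration of the statistics under a clean error
model, not robustness to every pathology of real arrays.

## Statistical choices

- **Pooled t, not Welch**: the classical two-sample Student's *t* with
  pooled variance and df = n₁+n₂−2, matching the convention of array
  studies at n=3 per group. Zero pooled variance is resolved as p=1 for
  equal means, smallest positive float (flagged) otherwise.
- **Calls on linear scales**: methylation tests run on linear %
  modification and expression tests on linear abundance; a config switch
  (`log2_expression`) enables log2-scale expression testing, default off.
- **No multiplicity correction in calls**: calls filter on raw P < 0.05
  with FC ≥ 1.5 or ≤ 0.7 (boundaries inclusive, alpha strict); a
  Benjamini–Hochberg column is emitted for information only.
- **Fisher's exact, two-sided**: minimum-likelihood summation implemented
  with exact integer hypergeometric weights (ties decided by exact integer
  comparison, no floating-point guard needed), divided once at the end.
  Depletion counts as two-sided significance; a query disjoint from a
  large set can legitimately be significant.
- **Enrichment universe**: defaults to array mRNA symbols that appear in
  ≥ 1 gene set — the most defensible array-aware background; "all array
  genes" and "all GMT genes" are config alternatives.
- **Clustering**: Euclidean distance, average linkage (scipy); leaf order
  and merge heights are serialized so downstream rendering is
  deterministic given the input ordering.
- **qPCR statistics on ΔCt**: SEM and t-tests are computed on ΔCt values
  (closest to normal); folds are reported as transformed means.

## Genomic conventions

Coordinates are 0-based half-open (BED). The gap between [a,b) and [c,d)
with c ≥ b is c−b; touching or overlapping intervals have gap 0; cis links
use gap ≤ 300,000 inclusive (a gene whose start is exactly 300,001 bp past
an lncRNA end is excluded). Context classification is total and
single-valued with precedence exon-overlap > intron-overlap > natural
antisense > intronic antisense > bidirectional > intergenic;
"bidirectional" requires no gene overlap and a divergent opposite-strand
TSS within 1 kb (configurable), with the TSS at the left edge on + and the
right edge on −. "Within gene body" means containment in the gene
interval. "Negatively correlated" across comparisons is operationalized as
the fully opposite quadrant (both the methylation and the expression
direction flip), with the denominator being transcripts quadrant-assigned
in both comparisons; both the numerator and denominator are reported.

## Numerical and degenerate-input handling

Intensities are floored at 1.0 at load time so log2 is defined (background
handling is otherwise out of scope); floored counts are logged. A
reference-group mean of zero in a fold change is floored at 1e−6 with a
warning. % modification of a 0/0 entry is defined as 0 and logged.
Percentages in reports use one-decimal round-half-up (Decimal, not banker's
rounding); a zero denominator flags the percentage undefined rather than
erroring. Single-row/column matrices yield single-leaf cluster trees.

## Problem sizes

Defaults are sized for quick, well-powered simulation studies: 3000
transcripts × 9 samples per simulated array; 20 seeds for the recovery
study (~3900 planted-effect calls); the Fisher oracle sweep covers every
2×2 table with N ≤ 60 (~635k tables); t-test calibration uses 10 × 2000
null transcripts; qPCR recovery 200 Monte-Carlo designs. These are the
package's chosen operating points for its own validation and run in
seconds on one core.

## Known limitations

- One probe per transcript; no aggregation rule for multi-probe designs.
- No IP-efficiency calibration from the m6A spike-in mixture: the spike-in
  registry is used for array/channel scaling only.
- No background subtraction, within-array loess or quantile normalization.
- The expression profile's definition on such arrays is ambiguous (Cy3
  alone vs total); both modes are provided (`total` is the default) and
  recorded in output metadata rather than guessing intent.
- Gene-level joins are by transcript id; symbol-level rollup uses "any
  transcript" semantics and is a reporting option, not the default.
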