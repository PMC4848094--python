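# Methods

This note documents the models and procedures riboten implements, the
parameter choices that matter, and what the synthetic-data validation
does and does not establish.

## Positional footprint counting

Alignments live in transcript coordinates (0-based, half-open); genomic
mapping and splice handling happen upstream and are out of scope. A
gene's counting window is

```
[ orf_start − start_off + 3·excl_codons ,  orf_end − stop_off )
```

with defaults `start_off = 12`, `stop_off = 18`, `excl_codons = 30`,
clipped to the transcript. The 12/18-nt offsets reflect where ~28-nt
footprint 5'/3' ends fall relative to start and stop codons; the 30-codon
exclusion removes the 5'-proximal region whose coverage is distorted by
initiation-associated variability. A read is counted iff it is uniquely
mapping **and wholly contained** in the window. Two conventions here are
choices rather than forced facts, and both are explicit knobs:

* the 30-codon exclusion is applied to the read **5' end** (by shifting
  the window's 5' boundary), not to an inferred P-site — P-site offset
  calibration is out of scope;
* "mapping within the boundaries" is read as whole-read containment, not
  5'-end containment.

Every rejected read is tallied by reason (`non_unique`,
`outside_window`, `uncountable_gene`, `unknown_gene`), so counted +
discarded always equals the stream length. Genes whose window is empty
(ORFs ≤ 30 codons + offsets) are flagged uncountable.

Gene-level expression measurements use only genes with ≥ 128 reads
pooled across the libraries entering the analysis (inclusive threshold).

## Normalization and TE

Size factors are median-of-ratios: with m libraries,
`s_j = median_g k_gj / (Π_j' k_gj')^(1/m)` over genes nonzero in every
library, the median taken in linear ratio space. Factors are defined up
to a common scale; what is invariant is the factor *ratio* between
libraries, and all TE quantities depend only on those ratios. Size
factors are computed separately for FP and total-RNA libraries by
default because the two assays have different count compositions
(switchable to joint). A `MedianOfRatiosNormalizer` class exposes the
same computation through a fit/transform interface.

TE per replicate is normalized FP over normalized total; the condition
TE averages replicates **geometrically** by default, since dTE is
analyzed in log space (arithmetic averaging is available). Genes with
zero normalized total in any replicate have undefined TE and are dropped
with a tally — never imputed. `dte_log2 = log2(TE_mut/TE_wt)` and
`dte_percent = 100·(2^dte_log2 − 1)` are stored together so each
analysis can use its natural scale.

Two analysis modes: the main TE table uses the 128-read filter and no
pseudocount; transcriptome-wide gene-set analyses use no read filter but
apply the pseudocount rule — for each gene detected (> 1 read) in some
but not all libraries, one read is added in **every** library (all-zero
genes are excluded). Adding to all libraries rather than only the zero
ones keeps the adjustment symmetric across libraries; this is the
documented resolution of an ambiguity in the rule's usual statement.

## Length dependence

The binned profile sorts genes by ORF length ascending (ties broken by
gene id for determinism), cuts consecutive bins of 100 genes (final
partial bin retained, so no gene is lost), and reports per-bin mean and
sample s.d. of percent dTE. Correlations against gene attributes are
Spearman by default (tie-corrected, pairwise deletion of missing
values). The partial correlation of y and x given a control is computed
by OLS-residualizing both on the control (with intercept) and
rank-correlating the residual vectors; with a constant control this
reduces exactly to the ordinary Spearman correlation. Regressions on
length use log10 length because ORF lengths span orders of magnitude;
rank correlations are transform-invariant so the choice only affects
regression-based steps. "Decreased" genes are selected by
`z = (dte_log2 − mean)/sd ≤ −1`.

## Gene-set rank tests and length correction

A set is compared to the remaining universe genes (or to an explicit
background set) by the Mann–Whitney U test, one-sided in a direction the
caller must declare — decreased TE is `alternative="less"`. The opposite
side's p is always reported alongside. P-values are exact when
`n_in·n_out ≤ 10,000` and the data are tie-free, otherwise a normal
approximation with tie and continuity correction; the two agree to
< 0.01 in the overlap regime. Fully tied data yield p = 0.5 (no shift
information). Raw one-sided p-values are reported without
multiple-testing adjustment by default (Benjamini–Hochberg available as
an opt-in column).

The length correction fits OLS of dte_log2 on log10 ORF length over the
**whole universe**, then re-runs the rank test on the residuals.
Residuals smaller than 1e-10 of the response scale are snapped to zero
so that a perfectly length-explained signal produces genuinely tied
residuals. The correction assumes the length relationship is linear on
the chosen scale and, like any residual analysis, demonstrates
association only — it cannot assign causality between length and
set-membership effects.

Per-set percent summaries (n, median length, median/mean percent dTE)
cover sets with > 20 in-universe members, ordered by median ORF length.

## Polysome trace quantification

Input is a sampled A254 curve over gradient position. The procedure:

1. **Smooth** with a moving average; the default window is
   `max(5, n/50)` samples — scaled to the trace so that detector noise
   is suppressed comparably at any sampling rate. Edge samples use a
   truncated-window mean so endpoints are not overweighted.
2. **Boundaries**: peaks with topographic prominence ≥ 5% of the dynamic
   range are located on the smoothed curve; the lowest sample between
   each consecutive pair of retained peaks becomes a boundary minimum
   (so minima separating only sub-prominence bumps are dropped, merging
   segments). Endpoints are always boundaries; an endpoint also acts as
   a peak when the curve falls away from it (a V-shaped trace yields its
   vertex). Boundaries closer than 2% of the trace length merge, keeping
   the lower. The 5%-of-range prominence default is set so that noise at
   up to ~2% of the maximum peak height (whose smoothed excursions reach
   several percent of the range) cannot seed spurious peaks.
3. **Baseline**: the chord through the lowest boundary minimum in each
   half of the trace (halves split at the midpoint position; an empty
   half falls back to its endpoint with a warning). Anchor values are
   read from a 5×-smoothed curve so that "lowest of several noisy
   minima" selection does not bias the baseline downward.
4. **Integration**: per inter-boundary segment, the trapezoidal integral
   of the smoothed curve minus baseline, clipped below at zero.
   Integrating the smoothed curve keeps rectified noise in near-baseline
   stretches from accumulating as area; boxcar smoothing conserves the
   integral of real peaks. Segments below 1% of the largest segment's
   area are discarded as noise.
5. **Labels and ratios**: the first three retained peaks in gradient
   order are 40S, 60S, 80S; later peaks are polysome_2, polysome_3, ….
   `60S/40S = area(60S)/area(40S)`;
   `P/M = Σ area(polysome_k) / area(80S)`. The P/M denominator being the
   80S monosome peak, and positional-order labeling, are standard
   conventions adopted here; with fewer than three peaks only the
   computable ratios are emitted. Ratios are invariant to uniform
   rescaling of absorbance or position.

On simulated five-Gaussian profiles the recovered ratios are exact
noiseless and stay within 5% of planted truth for white noise up to 2%
of the maximum peak height (the validated operating range); halfmer
shoulders and fraction-collector alignment are out of scope.

## Synthetic data generator

The generator emulates the study design — two conditions, two biological
replicates, matched FP and total-RNA libraries — with these defaults,
chosen once as realistic for a yeast-like transcriptome:

| parameter | default | rationale |
|---|---|---|
| n_genes | 4,000 | order of the filtered yeast transcriptome |
| ORF length | log-normal, median 1200 nt, ln-σ 0.65 | yeast-like length spread; rounded to codons, floored at 150 nt so the 30-codon exclusion never empties a window |
| UTRs | log-normal, medians 60/120 nt, ln-σ 0.5 | short yeast UTRs; the UTR scatter makes transcript length = ORF length + noise, which the partial-correlation analysis needs |
| abundance | log-normal, ln-σ 1.0, length-independent | wide dynamic range; a length–abundance coupling knob exists |
| WT TE vs length | −0.6 log2 per decade, scatter 0.5 log2 | short ORFs best-translated in WT |
| dTE vs length | +0.55 log2 per decade, scatter 0.55 log2 | gives a planted Spearman(dTE, log10 L) ≈ 0.27 — the observed magnitude for this class of mutant — while keeping the signal variance large enough that counting noise attenuates the recovered rank correlation by ≲ 0.02 |
| NB dispersion | 0.01 | typical biological-replicate overdispersion for RNA-seq counts |
| depth | 5×10⁶ per library | realistic lane fraction for yeast |
| read length | 28 nt | footprint size-selection target |

Expected counts factorize as depth × relative abundance × (TE for FP
libraries only), so the FP/total ratio in expectation equals the planted
TE up to a per-library scale. Counts are negative-binomial
(variance μ + α μ²; Poisson at α = 0). Gene groups are defined by
length-quantile predicates or explicit id lists, optionally subsampled,
each with an extra log2 dTE shift — so both "short-gene set with a
purely length-mediated effect" and "set with an excess shift beyond
length" scenarios are constructible. A set drawn from the shortest 5% of
ORFs inherits a ≈ −20% median TE change from the length trend alone,
matching the magnitude reported for ribosomal-protein gene sets.

Read-level simulation places each counted read uniformly over the legal
window positions and adds decoys (multi-mappers, or unique reads
violating containment) that counting must reject, giving an exact
round-trip identity at any contamination fraction. Traces are sums of
Gaussians over a linear baseline with white noise; analytic areas are
retained as ground truth.

Everything derives deterministically from one seed, with independent
child streams per stage.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: no nucleotide sequences (so no
mapping ambiguity structure, biased decoys, or motif effects), no codon-
level ribosome dynamics or 5'-ramp coverage shape, no UTR isoforms or
splicing, no library-preparation biases (ligation, PCR, rRNA carryover),
no correlated gene-gene structure beyond the planted length trend and
groups, and white rather than drift-like trace noise. Results on real
libraries depend on upstream mapping quality, which is out of scope.

## Numerical and design choices

* Median-of-ratios medians are taken in linear ratio space (arithmetic
  interpolation of middle elements at even counts), matching the
  standard implementation exactly.
* Geometric replicate averaging; undefined TE drops genes with a tally.
* Bin sorting ties break by gene id; binned profiles are therefore
  invariant to input order.
* The dTE–length regression in the correction uses log10 length
  (switchable to raw nt); whether to log-transform is genuinely open,
  and the log scale is preferred because lengths span orders of
  magnitude.
* MWU exactness cutoff at n_in·n_out = 10,000; all-tied data → p = 0.5.
* Trace knob defaults (adaptive smoothing window, 5%-of-range
  prominence, 2%-of-length merge separation, 1%-of-max-area noise
  floor) are set for robustness across the validated noise range; all
  four are caller-overridable.
* Pipeline stages communicate only through documented TSV/CSV formats;
  the run manifest records per-output SHA-256 checksums, and identical
  config + seed reproduces identical checksums.

## Problem sizes used in validation

Simulation-based checks run at 4,000 genes and 5M reads per library
(two replicates), the generator's default study conditions; the
counting-oracle check uses 200 genes with ~10,000 reads plus 50%
decoys; Mann–Whitney calibration uses 1,000 random 30-gene sets over a
2,000-gene null universe; traces use 2,000-sample grids. The committed
end-to-end regression fixture is smaller (250 genes, 20,000 reads per
library) so the full pipeline, including read-level simulation and
recounting of all eight libraries, stays fast.

## Known limitations

* The positional conventions (5'-end exclusion, whole-read containment)
  are documented choices among defensible alternatives; results on real
  data can shift slightly under the other conventions.
* The length correction is linear on one chosen scale; genuinely
  nonlinear length dependence leaves structure in the residuals.
* Rank-correlation estimates attenuate under counting noise; at shallow
  depth or high dispersion the recovered Spearman underestimates the
  planted value.
* Trace quantification assumes a single well-formed profile per file
  with peaks in canonical order; it does not detect halfmers or recover
  overlapping peaks by deconvolution — overlap is split at the saddle.
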