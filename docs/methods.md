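# Methods

This note documents the models implemented in `isoretain`, the choices
made where the underlying assay protocols leave the analysis open, and
what the synthetic benchmarks do and do not establish.

## Coordinates and counting rules

Internal coordinates are 0-based half-open; the SAF interchange format is
1-based inclusive and converted only at the I/O boundary, matching the
convention of the standard feature-counting tools the format serves.  A
read is assigned to a feature if any of its aligned blocks overlaps the
feature by ≥ 1 bp, and intron and CDS counters are independent: the two
quantifications correspond to separate counting runs, and a read
straddling an exon–intron boundary is genuinely informative about both
features.  A spliced read whose gap covers an intron never counts toward
that intron (its blocks do not overlap it).  Junction-end counting admits
only single-block (contiguous) reads — the structural counterpart of a
no-mismatch alignment over the boundary, given that inputs are intervals
rather than sequences — and requires the read to cover at least one base
on each side of the boundary coordinate: a read merely touching the
boundary carries no information about whether the junction is intact.
Multi-mapping is not modelled; every read record counts once.

## Retention estimators

The density estimator is r = (I/L_I)/(C/L_C); the CDS length is exonic
(span minus contained introns).  Genes with several CDS introns pool
counts and lengths into one joint record; each 5′UTR intron is scored on
its own.  Genes whose CDS has zero reads are flagged and excluded from
ranking rather than imputed — there is no defensible imputation for a
gene with no expression evidence.  The junction estimator averages the
two boundary counts, divides by the read length, and normalizes by the
same CDS density.

Fold changes use a pseudocount, fold = (r_t + ε)/(r_c + ε), with
ε defaulting to 10⁻³ of the median nonzero rate across the paired
records; this keeps zero-rate controls from producing undefined folds
while leaving well-measured ratios essentially untouched.  Note the
corollary exploited in the validation design: at shallow coverage a
zero-count control intron gives a fold of order r_t/ε, so fold-based
rankings demand enough control coverage that true-zero observations are
rare (the enrichment study uses ~400 reads per kilobase per gene).
A gene with several records enters the ranking with its maximum fold
change, ties breaking lexicographically for determinism.  Set enrichment
is a fixed-cutoff hypergeometric tail P[X ≥ k] on the top n of the
ranking (n defaults to a tenth of the universe), Benjamini–Hochberg
corrected across the sets tested.  Threshold-free enrichment statistics
(e.g. the minimum hypergeometric over all cutoffs) are deliberately out
of scope.

### Read-length edge bias, and the recovery benchmark geometry

Under the ≥ 1 bp overlap rule, a feature of length L accumulates reads
from L + ℓ − 1 start positions (ℓ = read length).  The density estimator
therefore carries a multiplicative factor

  (L_I + ℓ − 1)/L_I · L_C/(L_C + ℓ − 1),

≈ +8% for a 400 bp intron against a 1.4 kb CDS at ℓ = 50.  This is a
structural property of the estimator, not of the implementation; it
cancels exactly in control-normalized fold changes, which is what the
ranking consumes.  The estimator-recovery benchmark is designed so that
raw-rate recovery is meaningful: calibration genes carry one 5′UTR intron
whose length equals the CDS length (1500 bp each), making the edge
factors identical and their ratio 1.  The read simulator also extends
transcripts by stylized 100 bp UTR exons beyond the annotated feature
hull, since a UTR intron is always flanked by UTR exon and transcripts
run past the stop codon; without the flanks, features abutting the
transcript ends would lose their start-position allowance on one side.

The recovery study sweeps ρ ∈ {0, 0.1, …, 1} with 20 replicate seeds and
3 genes per replicate at ~200 expected intron reads for ρ = 0.1
(1.3 reads per start position per kb); measured |bias| stays below 0.01,
per-ρ RMSE below 0.02, and the estimated-vs-true regression slope within
0.01 of unity.

## Read simulation

Each gene's introns are retained independently with their latent
fractions ρ, giving up to 2^k isoforms per gene with product weights.
Read starts form a Poisson process along each isoform with rate
depth·abundance/1000 per start position, i.e. `depth` is reads per
kilobase at unit abundance.  Reads are single-end, strand-ignored, 50 bp
by default (the primary library layout being modelled); there is no
base-level sequence, no sequencing-error model and no FASTQ/BAM output —
interval records suffice for every estimator.  Reads crossing a splice
junction become multi-block records with blocks on the flanking exons;
reads within retained introns stay single-block because retention makes
the region genomically contiguous with its neighbours.

## Flow-cytometry simulation and the bimodality score

Cells draw log₁₀ expression from a two-component normal mixture with
fixed component means (defaults 1.0 and 3.0 log₁₀ units, σ = 0.25);
stress dose moves only the mixture weight.  The high-mode fraction of a
well is p = logistic((log₁₀ m − log₁₀ m*)/s), where m is the
dose-response target median, m* = 100 the level of maximal bimodality
(the putative unstable fixed point, placed at the mixture's symmetric
midpoint) and s = 0.25 the logistic steepness — the simplest monotone map
reproducing bimodality that peaks at an intermediate median.  Forward
scatter is an independent log-normal; FITC is expression × FSC, so the
cell-wise FITC/FSC normalization in the analysis recovers expression
exactly.  Independence of size and expression is the minimal assumption —
no size–expression coupling is being modelled — and means the benchmark
exercises the normalization arithmetic, not its biological efficacy.

Histograms use 100 log-spaced bins over 10⁻³–10⁵ relative to the
in-range cell count; out-of-range values are counted separately, never
clipped into edge bins where they would fabricate tail peaks.  The trough
depth d inverts the (optionally smoothed) histogram, takes interior local
maxima of the inverted series as candidate troughs, and scores each as
min(highest peak left, highest peak right) − trough on the original
scale, keeping the maximum.  Smoothing (default 5 bins) suppresses
single-bin noise troughs; the definitional path with `smooth_window=1`
is what the exhaustive triple-scan oracle checks, and histograms with
fewer than three nonzero bins score 0 by convention.  With several
troughs the deepest wins — the score assumes two dominant subpopulations
and generalizes gracefully.  No mixture model is fitted: the score is
deliberately non-parametric.

The grid study pools all wells, sorts by median (ties by well id for
determinism), smooths d with a centred 30-point running average (window
split (w−1)//2 left, w//2 right; clipped at the edges; a window larger
than the series returns its global mean), and reports the median at the
smoothed maximum.  The peak-recovery benchmark (24 × 24 wells, 2000
cells per well, 20 seeds) asks that this peak fall within one inter-well
spacing of the analytic p = 0.5 median.  One caveat documented rather
than hidden: with well-separated modes the mixture median is steep in p
around 0.5, so adjacent dose steps there are far apart on the median
scale and "one inter-well spacing" is a wide tolerance in m even though
it is a single grid step in dose.

## Growth rates and gradient design

Background defaults to the minimum of a curve's first three OD readings
when not supplied.  This overestimates the true offset by about the
inoculum OD, so fits are trustworthy when the fitting window sits well
above the initial OD — the standard windows (0.01–1 and 0.02–0.2 after
correction) do this for typical inocula.  The fit is an OLS slope of
ln(OD − background) against time over in-window points; fewer than two
such points is an error naming the well, not a silent NaN.  The
contamination filter discards rates strictly above 0.85 h⁻¹.  Dose–
response curves pass through decreasing isotonic regression
(pool-adjacent-violators) before interpolation, since measurement noise
can break the monotonicity interpolation requires.  The antiparallel
gradient mixes iso-effective doses linearly: point i of n is
(IC_A·(1−t), IC_B·t) with t = i/(n−1) — the simplest design holding
nominal inhibition constant, exact on a Loewe-additive surface (the
benchmark checks all designed points stay within 5% of the target level
on an equal-exponent Hill surface).

## Resampling statistics

The survival statistic is Δ = Σ low − Σ high over all timepoints and
replicates.  The surrogate null pools both populations' replicates per
timepoint into λ_t — the maximum-likelihood rate under the hypothesis
that the populations do not differ — and redraws every cell from
Poisson(λ_t).  P values use the add-one guard (r+1)/(n+1), so a reported
p can never be zero; comparisons use ≥ so that ties count against
rejection.  Both one-sided (Δ* ≥ Δ_obs) and two-sided (|Δ*| ≥ |Δ_obs|)
versions are exposed, two-sided being the default reported.  Calibration
under the bootstrap's own null (500 datasets, 2000 surrogates each,
exponential-decay truth with equal rates) keeps the α = 0.05 rejection
rate within [0.03, 0.07]; the strong-effect scenario (death rates 0.05
vs 0.5 h⁻¹, 200 CFU at t = 0, four timepoints × two replicates) is
detected at p < 0.01 in ≥ 95% of runs.

The permutation test on outcome fractions permutes pooled labels
explicitly and is one-sided in the stated direction.  The Mann–Whitney
implementation assigns half credit to ties; for n·m ≤ 400 without ties
it uses the exact null distribution (Gaussian-binomial counting
recursion), for small tied samples full enumeration of group
assignments, otherwise a tie-corrected normal approximation with
continuity correction; identical samples return p = 1.  The t test is
the classical pooled-variance two-sample procedure; zero pooled variance
is handled explicitly (p = 1 for equal means, a flagged p → 0 limit
otherwise) rather than propagating NaNs.

## What the synthetic benchmarks do not show

The generators are deliberately minimal: uniform read starts (no
coverage bias, no mismatches or multi-mappers), log-normal expression
with a dose-controlled mixture weight only (no growth-rate or
cell-cycle structure, no measurement compensation effects), Poisson
plating noise (no plating efficiency drift).  Passing the recovery and
calibration studies demonstrates that the estimators and tests are
implemented correctly and are well-behaved under their own model
assumptions; it does not validate those assumptions against real
sequencing or cytometry data, and the latent retention fractions in the
scenarios are stand-ins, not calibrated to any particular stressor.

## Problem sizes and determinism

Every generator and resampling routine is a pure function of
(parameters, seed); reruns are bit-identical.  The validation studies
use: 3 × 11 × 20 simulations at ~10⁴ reads each (estimator recovery),
100 random instances up to 10⁴ reads × 10² features (counting oracle),
500 random + 1000 unimodal histograms (trough oracle), 20 grids of 576
wells × 2000 cells (peak recovery), 500 + 100 bootstrap datasets
(calibration/power), and 100 end-to-end runs of 100 genes at ~10³ reads
per gene and condition (enrichment).  The full suite and the
reproduction script each complete in a few minutes on one CPU.
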