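# isoretain

Stress can change not just *how much* a cell expresses a gene, but *how* a
population distributes expression across cells.  In budding yeast, osmotic
stress inhibits the splicing of ribosomal-protein (RP) transcripts; the
resulting intron retention can feed a post-transcriptional switch that
splits an isogenic population into stable high- and low-expression
subpopulations with different survival prospects under starvation — a
bet-hedging strategy.  Quantifying this chain of effects takes four
distinct pieces of analysis, each of which `isoretain` implements as a
tested, reusable library with matching synthetic-data generators so every
estimator can be validated against known ground truth:

1. **Intron-retention estimation** from block-structured aligned reads.
   For intron read count *I* over length *L_I* and CDS count *C* over
   length *L_C*, the retention rate is the density ratio

   *r* = (*I*/*L_I*) / (*C*/*L_C*),

   with CDS introns of a gene pooled jointly and each 5′UTR intron scored
   separately.  A junction variant replaces the intron body with contiguous
   reads spanning the two exon–intron boundaries:
   *r* = ((*n₅*+*n₃*)/2 / ℓ) / (*C*/*L_C*) for read length ℓ.
   Treated rates are normalized to a no-stress control as pseudocounted
   fold changes, genes are ranked, and label sets (e.g. "RP") are tested
   with a hypergeometric tail probability, Benjamini–Hochberg corrected.

2. **Bimodality scoring** of single-cell fluorescence.  FITC-H is
   normalized cell-wise to FSC-H, binned into 100 log-spaced bins over
   10⁻³–10⁵, and scored by the trough depth *d*: the vertical distance
   between the trough separating two histogram peaks and the lower peak
   (the prominence of the inverted histogram's peak; *d* = 0 when
   unimodal).  Across a two-drug gradient, the running average (window 30)
   of *d* against the median expression *m* locates the expression level
   of maximal bimodality — the signature of an unstable fixed point
   between two stable expression states.

3. **Growth and gradient design.**  Exponential rates are ordinary
   least-squares slopes of ln(OD − background) in a fixed OD window
   (0.01–1 or 0.02–0.2); rates above 0.85 h⁻¹ are flagged as bacterial
   contamination.  Single-drug dose–response curves are isotonically
   cleaned and interpolated to iso-effective doses, from which an
   antiparallel two-drug gradient holds total inhibition constant.

4. **Resampling statistics** for fitness comparisons, centred on a
   Poisson-surrogate bootstrap for colony-forming-unit survival assays:
   the statistic Δ is the difference between total low- and
   high-expression colony counts over all timepoints; 10⁴ surrogates
   redraw each (population, timepoint, replicate) count from
   Poisson(λ_t) with λ_t the pooled per-timepoint mean.  Companion tests:
   one-sided permutation test on outcome fractions, exact/approximate
   Mann–Whitney U, and a pooled-variance two-sample t test.

## Worked example

Run all three end-to-end scenarios from one config (seed 1):

```python
from isoretain import AnalysisConfig, run_scenario
summary = run_scenario(AnalysisConfig(seed=1), "all", "out/demo")
```

which prints (via `summary.json`):

```json
{
  "bimodality": {"m_peak": 82.96563680005993, "max_depth": 0.071, "n_wells": 64},
  "retention": {"best_p_adj": 0.0007811271525452956, "best_set": "RP",
                "n_genes": 120, "n_ranked": 88, "n_undefined": 0,
                "top_gene": "g0093"},
  "survival": {"delta_obs": 772.0, "n_surrogates": 10000,
               "p_one_sided": 9.999000099990002e-05,
               "p_two_sided": 9.999000099990002e-05}
}
```

Reading these numbers: in the retention scenario, 120 synthetic genes were
sequenced in a stress-like condition where only the RP-labelled genes have
elevated retention; after counting, rate estimation, fold-normalization
and ranking, the RP set beats five size-matched decoy sets with adjusted
p ≈ 8 × 10⁻⁴.  In the bimodality scenario an 8 × 8 dose grid of simulated
cells yields a pooled depth-vs-median curve peaking at *m* ≈ 83, close to
the generating mixture's p = 0.5 median of 100.  In the survival scenario
the low-expression population out-survives the high-expression one
(Δ = 772 colonies) and the bootstrap p attains its add-one lower bound
1/(10⁴+1).

The same stages are scriptable from the shell:

```sh
isoretain simulate reads --n-genes 20 --seed 3 --out-dir sim
isoretain retention --saf sim/annotation.saf --reads sim/reads.bed --out-dir ret
isoretain run --scenario all --seed 1 --out-dir out/demo
```

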