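# Methods

## Scope and data model

`abarray` analyses single-channel autoantibody protein microarrays of the
KREX/Immunome type: each antigen is printed in quadruplicate, every sample is
one array, and the scanner software exports per-spot foreground and
background median intensities (RFU) in a GenePix-results (GPR) dialect.  The
package consumes those exports — it does not touch images — together with a
GAL-style layout (which features are analytes, buffer-only negative
controls, Cy3-BSA scaling controls or biotinylated-IgG positive controls)
and a clinical manifest (group ∈ {control, MCI, dementia}, age, sex,
diabetes, run-year batch, MoCA score, low-education flag).

The central container is the `AntigenMatrix`: antigens × samples log2 net
intensities with a per-cell validity mask and a `stage` tag that can only
move forward through

```
net → consensus → scaled → ncf → loess → batch_corrected
```

so a stage can assert what has already happened to its input.

## Stage order

1. **Net intensity.** `net = max(fg − bg, 1)` RFU.  The 1-RFU floor keeps
   the log2 transform defined when background exceeds foreground and marks
   such cells as at-background; the alternative (masking them) discards
   exactly the antigens a negative-control filter needs to see.
2. **Replicate CV gate.** Per (antigen, sample) cell, the coefficient of
   variation of the replicate net intensities is computed on the raw scale
   with the n−1 standard deviation (the array-industry convention).  If
   CV > 20% the spot farthest from the cell median is removed and the CV
   recomputed, iterating while more than two spots remain.  Cells still
   above threshold at two spots, or with fewer than two valid spots, are
   masked.  The consensus is the mean of the surviving raw net intensities,
   carried as log2.  The farthest-from-median rule is the simplest
   deterministic outlier policy consistent with "remove outlier spots while
   at least two valid values remain"; it is confined to one function and
   pluggable.
3. **Cy3-BSA control scaling.** Each array receives the additive log2 shift
   that brings its median Cy3-BSA control value to the cohort grand median
   of those medians.  This removes per-array scanner gain.  Arrays with no
   valid Cy3-BSA cell cannot be scaled and are failed outright.
4. **PSA detection and sample exclusion.** A sample's polyspecific
   (PSA) score is the fraction of analytes on which it strictly exceeds the
   antigen's 95th-percentile reference value; samples above 25% breadth are
   flagged.  Two deliberate design points:
   * Detection runs **before** between-array normalization.  A PSA sample's
     broad shift is mathematically the per-sample trend that cyclic loess
     removes, so detecting afterwards is blind; it also distorts the NCF
     correlations and the loess reference if left in.  Excluded samples
     (PSA + control failures) therefore leave the matrix here, and
     everything downstream sees only retained samples.
   * Quantile references are computed **within run-year batch**: detection
     precedes batch correction, and a batch location shift would otherwise
     push clean high-titer samples of the shifted batch over the breadth
     threshold.
   Both constants (quantile 0.95, breadth 0.25) are configuration-exposed;
   they are a quantitative stand-in for what is usually a visual heatmap
   call.
5. **Negative-control filtration (NCF).** The reference profile is the
   per-sample mean of the negative-control features.  Analytes whose Pearson
   correlation with that profile exceeds r = 0.7 are removed as nonspecific.
   The 0.7 default mirrors the convention used for the cross-reactivity
   screen; at cohort sizes of ~100 samples the null distribution of r is so
   tight (sd ≈ n^(−1/2)) that the choice is not delicate.  All
   control-class features leave the analysis matrix here — they are
   reference material, not analytes.
6. **Cyclic loess.** The `fast` variant: per iteration, each sample is
   regressed (M = sample − row-mean on A = (sample + row-mean)/2, tricube
   degree-1 lowess, span 0.7) and the fitted trend subtracted; three
   iterations.  A `pairs` variant (every sample pair, half the trend to
   each) is available for small cohorts.  Span/iterations follow the
   standard implementation's defaults.  Two numerical notes: with a constant
   abscissa the fit degenerates to the M mean; and under heavy per-cell
   noise the M-on-A fit contains a genuine regression-to-the-mean
   component, so loess shifts each antigen's mean identically across
   samples — harmless for contrasts, but the reason the mean-preservation
   property is only asserted at low cell noise.
7. **Batch correction.** Parametric empirical-Bayes location/scale
   adjustment of the run-year batches (the ComBat model): standardize per
   antigen under a design that *protects* the biological covariates (group,
   age, sex, diabetes) so group signal is not absorbed; estimate per-batch
   per-antigen location (γ) and scale (δ²) on the standardized residuals;
   shrink toward moment-matched normal / inverse-gamma priors by the
   standard iterative update (convergence 1e−4); remove and restore.  A
   single batch is a no-op; a batch confounded 1:1 with group raises an
   error naming the confounding; constant covariates (e.g. a single-sex
   cohort) are dropped rather than treated as confounding.  Masked cells
   are mean-imputed for estimation only and re-masked afterwards.
8. **Differential reactivity.** Pairwise contrasts (dementia vs control,
   dementia vs MCI, MCI vs control), each an OLS fit per antigen on
   intercept + case indicator + centered age + sex + diabetes.  Residual
   variances are moderated across antigens: prior df d0 and prior variance
   s0² come from moment-matching the log-variance distribution
   (digamma/trigamma inversion, with a Newton trigamma-inverse), and

   s̃²_g = (d0·s0² + df_g·s²_g)/(d0 + df_g),  t̃_g on df_g + d0 df.

   If the log-variance excess is non-positive, d0 = ∞ and every antigen
   gets the common moment-matched variance (which differs from the raw s²
   by the small bias factor exp(log(df/2) − ψ(df/2))).  Significance
   defaults to unadjusted p < 0.05 — the study convention — with BH FDR
   always reported alongside and a logged warning about multiplicity.
9. **MoCA correlation.** Spearman rho (mid-ranks) of each antigen against
   education-adjusted MoCA (raw +1 if ≤ 6th-grade education, capped at 30;
   impairment ≤ 26) across MCI + dementia samples only.  p-values by the
   t-approximation, exact permutation for n ≤ 9.  The screen filter is
   |rho| ≥ 0.27 and p < 0.05.  Clinical reports sometimes label these
   coefficients "r²" while carrying signs; here they are plainly signed
   Spearman rho.
10. **Cross-reactivity.** Pearson correlation matrix of the significant
    antigens per contrast; every pair with r > 0.7 is globally aligned
    (Needleman–Wunsch, BLOSUM62, gap open 10 / extend 0.5) and percent
    identity computed over the full alignment length including gap columns
    (the stricter denominator; a shorter-sequence denominator is a flag).
    Pairs at ≥ 28% identity are verdicted `possible_crossreactivity`; the
    28% default is an observed ceiling in the motivating data rather than a
    principled constant, and is configuration-exposed.
11. **Enrichment.** One-sided hypergeometric (Fisher exact upper tail) of
    the significant-antigen protein set against user-supplied GMT sets, BH
    across sets.  The universe defaults to the post-NCF array panel, not
    the proteome — array composition is the correct background for what
    could have been called.

## Synthetic cohort generator

`simulate.generate_cohort` renders, from a single mandatory seed, GPR files
plus layout/manifest/truth tables with the structure above.  Each component
(layout, manifest, baselines, group effects, batch, nonspecific, PSA, MoCA,
noise, spots, gain/bias, twin pairs) draws from its own deterministically
derived substream, so e.g. changing the PSA sample count does not move the
planted differential antigens.

Defaults are the study-scale conditions: 600 analytes + 20 negative
controls + 8 Cy3-BSA + 2 IgG features, quadruplicate spots; 98 clean
samples (38 control / 42 MCI / 18 dementia) plus 4 PSA samples and 1
control-failure sample; two run-year batches with a +0.4 log2 location
offset; 30 dementia-contrast and 20 MCI-contrast differential antigens at
|Δ| = 0.75 log2 (1.5× the antigen-level noise SD, random sign); 15
nonspecific antigens built on the negative-control background profile with
noise sized for r ≈ 0.9; 3 MoCA-coupled antigens (ranks −0.5, −0.5, +0.4);
PSA samples shifted +1.5 log2 on 60% of analytes.  The signal model per
analyte cell is

baseline_g ~ N(8, 1.5²) + sample effect N(0, 0.2²) + cell noise N(0, 0.5²)
(+ planted effects + batch γ), then per-array gain N(0, 0.25²) and a smooth
quadratic intensity-dependent bias with amplitude U(−0.3, 0.3), then spot
replicates at N(0, 0.08²) with 1% outlier spots (×5 raw) and 0.2% scanner
flags, an additive background ~N(100, 10²) RFU, and 16-bit saturation at
65,535.  MoCA, age, and sex are drawn per group at the cohort's published
scale (MoCA 28.9±1.4 / 22.9±6.6 / 11.6±6.6; ages 66±7 / 70±8 / 75±5; sex
ratios per group).  Diabetes prevalence (0.30) and low-education fraction
(0.20) are not published for the cohort and are set once at realistic
regional values.

What the generator does **not** emulate: spatial print-tip/block artifacts,
isotype structure, epitope spreading, non-Gaussian heavy-tailed titers,
missing-at-random manifest fields, and any real protein identity
(synthetic FASTA sequences are random amino-acid strings; synthetic GMT
sets are random panel subsets plus one set seeded with planted antigens).
Passing recovery tests therefore demonstrates internal statistical
correctness of each stage under the assumed noise model, not performance on
real plasma arrays.

## Problem sizes used by tests and the acceptance script

Type-I calibration pools 20 null cohorts of 600 antigens at n = 38 vs 18
(12,000 tests); power/effect recovery uses 5 cohorts with 30 planted
antigens at Δ = 1.5σ; batch correction uses 10 two-batch cohorts (30/30)
with γ = 0.8 and checks the signed post-correction batch difference,
the γ estimate, and 95%-CI coverage of planted group effects; the loess
check uses amplitude 0.4 bias at low cell noise (0.1) with gain off, since
the M-vs-A trend metric would otherwise measure its own lowess noise floor
and the gain belongs to the scaling stage; NCF and PSA run on the full
spot-level GPR path of a default cohort.  These sizes make the whole suite
run in seconds while keeping every Monte-Carlo band comfortably away from
its threshold.

## Known limitations

* The PSA breadth detector assumes a broadly *positive* shift; a
  polyspecific sample that saturates only mid-affinity antigens could
  evade the 95th-percentile breadth score.
* ComBat is the parametric variant only; nonparametric priors and
  reference-batch mode are out of scope.
* The cross-reactivity verdict is sequence-identity-based; structural or
  epitope-level similarity is not modelled.
* Contrasts are pairwise two-group models, not a joint three-level model;
  this mirrors the study convention but forfeits some power.
* The analysis pipeline is exposed as library functions plus thin numbered
  driver scripts rather than a console command: the expected user is a
  scientist driving it from Python or the provided drivers, not a shell
  tool chain.
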