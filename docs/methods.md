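# Methods

This note documents the statistical models implemented in `methaccord`, the
calibration of the synthetic data generator, the numerical choices, and the
limitations of what the synthetic reproduction can show.

## The measurement model

Both assays report a percentage of methylated cytosines, but at different
genomic targets: LINE-1 pyrosequencing averages four CpG sites of a
retrotransposon promoter (A+T-rich compartment), LUMA digests CCGG sites
genome-wide (enriched in C+G-rich, promoter-proximal regions).  The package
treats each assay readout as an affinely calibrated quantity: the raw value
is a deterministic function of pyrogram peak heights, and a two-point
control calibration maps the 0 %/100 % control readings onto 0 and 100.
Calibrated values falling outside [0, 100] are flagged, never clipped, so
agreement statistics see the raw linear transform.

Quantification conventions:

* The enzyme ratio of one digestion reaction is `peak2 / mean(peak1, peak3)`
  — the first dGTP+dCTP fill-in over the mean of the dATP and dTTP
  reference peaks.  The second dGTP+dCTP dispensation (step 4) is recorded
  but not used in the ratio; step 6 relative to step 1 serves the
  carry-over QC rule only.
* QC thresholds are strict inequalities: informative peak heights (steps
  1–3) below 2 (blood) or 1 (cell specimens) exclude; an MspI/MfeI ratio
  above 4.2 excludes; a step-6/step-1 fraction above 25 % excludes, exactly
  25 % is retained.  All rules are evaluated so the recorded reason lists
  every fired rule, and the retained set does not depend on rule order.
* LINE-1 aggregation is mean over four CpG sites → mean over within-run
  duplicates → mean over two runs; run means are calibrated with their own
  run's controls before averaging.  Reads failing the bisulfite-conversion
  flag are dropped (the sequence-level conversion check itself is accepted
  as an upstream boolean).
* Interassay CVs of duplicate pairs are aggregated as the arithmetic mean
  of per-pair CVs (SD/mean, n−1 denominator).  A root-mean-square
  aggregation would weight discordant pairs more heavily; the arithmetic
  mean is used because the per-pair CV is already a relative quantity.

## Agreement statistics

Differences are always d = LINE-1 − LUMA.  The Bland–Altman block reports
the fixed bias mean(d) with a t-distribution CI, the 95 % limits of
agreement mean(d) ± 1.96·SD(d) (the conventional constant, not a t
quantile), and the proportional bias as the OLS slope of d on the pairwise
average (mean of the two methods), with t-based CI and two-sided p.

Normality of d is assessed by a Kolmogorov–Smirnov test.  Because the
normal parameters are estimated from the same data, the naive KS p-value is
conservative; the Lilliefors-corrected test (statsmodels) is therefore the
default and the naive variant is available via `lilliefors=False`.  The
Wilcoxon signed-rank test uses the exact null distribution up to n = 25
non-zero differences and the normal approximation with continuity
correction above; the reported V is the sum of positive-difference ranks.
The assay × subset analysis is a mixed two-way repeated-measures ANOVA
(pingouin), with post-hoc Wilcoxon p-values Bonferroni-multiplied by the
number of subsets and capped at 1.

## Pattern analysis of the differences

**PDE.**  The empirical density is a uniform-ball kernel estimate with the
Pareto radius — the 18th percentile of pairwise absolute differences
(computed on a seeded 1000-point subsample above that size) — evaluated on
a 512-point grid spanning the data range ± 3 radii and renormalized to unit
trapezoid integral.

**Mixture fit.**  For each candidate component count M, EM (scikit-learn,
k-means initialization, 3 starts, 200 iterations, tolerance 1e-8, SD floor
1e-3 of the data SD) provides the start, and Nelder–Mead then minimizes the
RMSE between the mixture curve and the PDE curve (softmax weights, raw
means, log SDs).  Two numerical choices matter here:

* *The RMSE objective convolves the candidate mixture with the PDE's own
  kernel* (closed form via normal CDFs).  The PDE is the true density
  smeared by the kernel; comparing a raw Gaussian mixture to it penalizes
  sharp components for the kernel's bias and rewards splitting them.
  Convolving makes the criterion measure distributional mismatch only.
* *k-means initialization rather than quantile placement.*  With a dominant
  cluster (55 % of the default differences sit in the narrow blood mode),
  quantile starts seed two components inside that cluster and EM settles in
  a degenerate optimum that splits it; k-means follows the cluster
  structure.

**Component-count selection.**  The RMSE to a kernel density keeps falling
as components are added, because extra Gaussians track sampling wiggles of
the estimate; a fixed relative-improvement cutoff therefore runs away to
the top of the scan range.  The scan instead stops at the smallest M whose
RMSE is at or below the PDE's own sampling-noise floor, the RMS over the
grid of the pointwise kernel-estimator SD sqrt(p̂(x)/(2 r n)); if no
candidate reaches the floor the best RMSE wins.  This rule recovers M = 1
on a single-Gaussian sample and M = 2 on a well-separated pair.  On the
default calibrated study it selects M = 2: under the per-subset summary
statistics the MCF7 and SHSY5Y difference distributions overlap so strongly
that their blend is unimodal, and no label-blind criterion (this rule, BIC,
AIC, or cross-validated likelihood) can justify a third component.  The
three-component analysis of the original design — three tissues — remains
available by fixing `M_range=[3]`, which is how the tissue-tree stage is
exercised; its fitted boundaries then fall near −3 and +12 % methylation,
tissue-aligned.

**Boundaries and assignment.**  Bayes boundaries are the roots of
wᵢN(x|μᵢ,σᵢ) = wⱼN(x|μⱼ,σⱼ) between adjacent means (Brent's method); under
extreme weight imbalance the root can lie outside the mean interval, and
the boundary is then taken at the posterior-argmax changeover on a fine
grid.  Posteriors are computed in log space and normalized per point.

**Tissue tree.**  The only predictor is the categorical tissue label.
Splits are dichotomic subsets of the labels chosen to maximize the decrease
of the information index Σ −p ln p; leaves predict their majority
component.  Cross-validation holds out ⌈n/10⌉ samples drawn without
replacement, rebuilds the tree, and averages held-out accuracy over 100
repetitions.  On a single categorical predictor this tree is equivalent to
a per-tissue majority map once fully grown (a scikit-learn entropy tree on
one-hot labels reproduces its predictions; that equivalence is a test, not
the implementation).

## Subset-specific regression

The model `LINE1 = (θ₁ + θ_Int,s) + (θ₂·θ_Slope,s)·LUMA + ε` with a common
Gaussian residual has no random effects, so maximum likelihood is exactly
constrained least squares and −2LL = n·ln(2π·σ̂²) + n with σ̂² = RSS/n.
Internally a model structure is a partition of subsets into intercept
groups (optionally pinned at 0) and slope groups — always identifiable.
The θ product parametrization of the full model is redundant (only
θ₂·θ_Slope,s is identified when every subset carries a free factor); the θ
reporting view then sets θ₂ to the shared cell-line slope or 1, and the
`from_free_mask` constructor refuses over-parameterized masks outright.

Model building starts from the single shared line and proceeds in a fixed,
logged order: subset intercepts (subset order), subset slopes, slope
equality ties, and finally intercept-to-zero tests.  Each decision is a
likelihood-ratio test at α = 0.05: the richer model is kept only if
Δ(−2LL) < −3.84 strictly (χ² quantile at the appropriate df otherwise).
Intercept merges between subsets are not tested — the equality hypotheses
of the design concern the slope factors.  Note the ceiling this α implies:
when the generating structure itself contains exact null decisions (a zero
intercept, an exact slope tie), perfect structure recovery cannot exceed
(1−α) per such decision (≈ 0.90 for two), whatever the sample size.

Bootstrap CIs are percentile intervals over 1000 refits on resamples drawn
with replacement, stratified by subset to preserve the design's group sizes
(unstratified available); failed refits are redrawn and counted.

## Effect sizes

Cohen's d with the pooled (n−1-weighted) SD; the Hedges small-sample
correction is available but off by default since the plain statistic is the
study's convention.  DMSO solvent controls are pooled with the untreated
condition.  All unordered condition pairs within each cell line are
compared under both assays; pairs involving a condition with fewer than two
replicates are skipped, because no pooled SD exists.  Under the default
design this yields 66 MCF7 pairs and 6 SHSY5Y pairs (the two
single-replicate SHSY5Y conditions remove 9 of the 15 nominal pairs) — 72
comparisons, whose two d-profiles are compared by Spearman correlation.

## The synthetic generator

Each subset is a bivariate Gaussian over (LINE-1 %, LUMA %) matching the
published per-subset means and SDs.  The correlation parameter is stored as
a Spearman ρ and converted by the exact bivariate-normal relation
r = 2·sin(πρ/6).  The default ρ values (0.8436 MCF7, 0.9360 SHSY5Y, 0.3087
blood) are calibrated so that the implied SD of the interassay differences
reproduces the published 95 % limits of agreement; a Gaussian with the
published marginal SDs cannot match the published rank correlations and
the published limits of agreement simultaneously (the rank statistics come
from visibly non-Gaussian real data), and the covariance is what drives
every downstream statistic — difference SDs, mixture components, regression
slopes.  The blood default is practically the published rank value.

Treatment conditions follow the published exposure plan (replicate counts
per condition).  Per-condition shifts are free parameters chosen so
demethylating agents lower and methyl donors raise methylation
(5-Aza-CdR −12, SAM +6, RG108 −8 % methylation, etc., equal on both assays
by default); they are centred to zero weighted mean per subset and the
within-condition variance is shrunk so the subset-level marginals and
covariance stay exactly calibrated.  Draws are clamped to [0, 100] with a
logged count.  Pyrogram-level tables are generated by inverting the
quantification formulas (including the control calibration, with the
methylated LINE-1 control reading 75.08 and the LUMA lambda control 95.7),
so the full quantification round-trips to floating-point accuracy; a
configurable fraction of records violates each QC rule to exercise the
filters, and optional Gaussian peak jitter breaks the exactness on demand.

What the generator does **not** emulate: non-Gaussian marginals (skewness,
outliers) of the real data; any dependence of the interassay difference on
treatment condition; pyrosequencing chemistry noise beyond optional peak
jitter; bisulfite-conversion errors.  Consequences worth knowing before
reading test results as statements about real data:

* The mixture scan on generated data honestly selects two components — the
  generated MCF7/SHSY5Y difference blend is unimodal by construction.  A
  third, tissue-aligned component is recoverable only when M is fixed to
  the number of tissues, as the original three-tissue design does.
* With M fixed at 3 the tissue tree cross-validates around 0.89–0.95
  accuracy, somewhat above the published 83.6 %: the published fit's left
  boundary bisects the MCF7 differences, while a fit to Gaussian synthetic
  data places the boundary at the purest separation point.
* The blood regression parameters carry large sampling noise at n = 131
  (narrow LUMA range), so single-draw estimates of the blood slope scatter
  with SE ≈ 0.07; replicated runs are used where a stable estimate is
  needed.

## Problem sizes and determinism

Default analysis settings are the study's: 1000 bootstrap resamples, 100
tree cross-validation repetitions with k = ⌈n/10⌉, mixture scan M = 1..5.
Simulation-based checks in the test suite use 200–1000 repetitions at small
per-repetition sizes, chosen to estimate rejection rates and coverages to
about one percentage point.  Every stochastic routine takes an explicit
seed; the pipeline derives independent per-stage seeds from one master seed
so that disabling a stage never shifts another stage's random stream, and
repeated runs are byte-identical.
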