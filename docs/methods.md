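# Methods

## The model

`pgstransmit` fits a two-group (MZ / DZ twin families) structural model of
how polygenic scores (PGS) relate to a child phenotype across generations.
One family contributes a six-variate observed vector

    (PGS_m, PGS_f, PGS_tw1, PGS_tw2, Y_tw1, Y_tw2)

— mother's, father's and both twins' PGS plus the two twins' phenotype
scores — any subset of which may be missing. The generative assumptions
are:

* parental PGS are bivariate Gaussian with common variance `V_PGS` and
  correlation `r_a`. `r_a` absorbs both assortative mating and residual
  population stratification; it is what lets parent–child PGS
  correlations exceed the Mendelian 0.5.
* each child's PGS is the mid-parent average plus a Mendelian
  segregation deviation. The regression of a child PGS on each parental
  PGS is fixed at 0.5 (transmission of half the autosomal genome). The
  child PGS variance is constrained to the same `V_PGS`, which forces
  the segregation variance to `V_PGS (1 − r_a)/2` (derived, not free).
  MZ co-twins share one segregation deviation — their implied PGS
  correlation is exactly 1 — while DZ co-twins draw independent
  deviations, giving an implied twin-PGS correlation of `(1 + r_a)/2`.
* the phenotype of twin *i* is linear in the family's PGS:

      Y_i = mu_Y + g_tw PGS_i + g_m PGS_m + g_f PGS_f + e_i

  with residuals of variance `V_ADHD` correlated `r_MZ` (`r_DZ`) within
  MZ (DZ) pairs. `g_tw` is *direct genetic transmission*: the effect of
  the alleles the child actually carries. `g_m`, `g_f` are *genetic
  nurture*: parental genotype acting on the child through the rearing
  environment.

Ten parameters are free: `V_PGS, r_a, V_ADHD, r_MZ, r_DZ, g_tw, g_m, g_f`
and the two means; all but `r_MZ`/`r_DZ` are constrained equal across
zygosity groups. The "no-nurture" submodel fixes `g_m = g_f = 0`
(eight free parameters), giving a 2-df likelihood-ratio test of
genetic nurture.

## Implied moments: two constructions

`build_implied_moments` uses general path-model (RAM) algebra,
`cov = (I − A)^{-1} S (I − A)^{-T}`, with the fixed 0.5 transmission
entries and the free `g` paths in `A` and the exogenous (co)variances in
`S`. `closed_form_moments` evaluates hand-derived scalar formulas for
every entry with no matrix inversion. The two are developed
independently and their agreement (to 1e-10 over wide random parameter
draws) is a standing test; the likelihood evaluates the scalar
construction because it is cheaper in the optimizer's inner loop.

## Estimation

Fitting is full-information maximum likelihood (FIML): each family
contributes the Gaussian log-density of its observed sub-vector under
the corresponding sub-moments for its zygosity group. No imputation is
performed anywhere. Families are grouped by (zygosity, missingness
pattern) and the likelihood is evaluated from per-pattern sufficient
statistics (count, mean, scatter), which is algebraically identical to
the per-family sum but makes the cost independent of sample size. An
analytic gradient (chain rule through the implied moments) is verified
against finite differences in the tests.

Optimization runs on an unconstrained scale — log variances, atanh
correlations — with L-BFGS-B (`ftol` 1e-13, `gtol` 1e-6, analytic
gradient), started from method-of-moments values computed on
pairwise-complete data, with up to five jittered deterministic restarts
on non-convergence. Solutions with |correlation| > 0.99 or variance
below 1e-8 are flagged as boundary solutions. The ML (divisor *n*)
covariance convention is used throughout, matching the likelihood.

**The MZ degeneracy.** Because the model implies an MZ twin-PGS
correlation of exactly 1, an MZ family with both twin PGS observed (and
equal, as the shared-genotype assumption requires) has a singular
implied sub-covariance. The package drops the redundant second
coordinate row by row — exact FIML on the degenerate support, up to a
parameter-free constant — and applies the same reduction to the
saturated and baseline reference models so all model comparisons use
the same effective data. MZ rows with *unequal* observed twin PGS
contradict the model and contribute −inf with a diagnostic.

**Reference models.** The saturated model (unstructured per-group mean
and covariance) is fitted by EM for the multivariate-normal MLE under
missingness, which maximizes the same FIML objective; variables never
observed within a group are excluded from that group's
parameterization, with the free-parameter count reduced accordingly.
The baseline (independence) model has a closed-form per-variable
solution. CFI, TLI and RMSEA follow their standard chi-square
definitions with the number of *families* — the independent sampling
units — as the RMSEA n. With sparse missingness patterns (a handful of
observations informing some saturated covariance cells) the saturated
model overfits in finite samples, and the LRT against it is
anti-conservative at a few hundred families; the nested full vs.
no-nurture test does not suffer from this and is the calibrated test of
genetic nurture.

## Standardization and variance decomposition

Standardized effects are `g' = g sqrt(V_PGS / V_phen)` with `V_phen`
the model-implied phenotype variance. The explained-variance shares
are

* `R2_total = (V_phen − V_ADHD) / V_phen` — all PGS jointly;
* `R2_gt = g_tw^2 V_PGS / V_phen` — direct transmission: the parental
  paths are zeroed while the full covariance structure is retained;
* `R2_gn = R2_total − R2_gt` — genetic nurture, exact by construction.

Because the child's PGS is correlated with the parents' (passive
gene–environment correlation), opposite-signed `g_tw` and `g_m`/`g_f`
make the cross terms negative: `R2_gn` can be negative and `R2_gt` can
exceed `R2_total`. Both behaviours are asserted in tests.

## Inference

The bootstrap resamples *families* with replacement, stratified by
zygosity so the MZ/DZ design counts are preserved (the stratification is
this package's choice; free resampling would be defensible too).
Replicates are refitted starting from the base-fit estimates with one
jittered fallback; non-converged replicates are dropped and counted,
and a result with more than 20% failures is flagged unreliable.
Intervals are equal-tailed percentile intervals (linear interpolation
between order statistics), the minimal reading of a bootstrap CI; the
convention is isolated in `percentile_interval` for easy swapping.
Default levels are 0.95 and the Bonferroni-adjusted
`1 − 0.05/6 = 0.992` for three PGS effects tested with two PGS.
Resample indices are pre-drawn from one seed, so results are
bit-reproducible and independent of the worker count. The default
replicate count is 10,000.

## Preprocessing

For raw symptom data the pipeline is: average the item ratings (0/1/2
scale; five hyperactivity or three inattention items) within each
measurement occasion, average the occasion means within a developmental
period, square-root transform, and take OLS residuals on an intercept
plus sex (per period by default; twins treated as independent rows,
since only point residuals are needed). PGS are residualized on an
intercept plus ancestry covariates (ten genetic principal components
expected) and re-standardized to mean 0, SD 1 over all genotyped
persons pooled across family roles — one scale for everyone, consistent
with the single `V_PGS`. For MZ families with exactly one genotyped
twin the observed PGS is copied to the co-twin. Preprocessing never
imputes anything else; missingness is left to FIML.

## The simulator and its defaults

`simulate_families` draws from the generative model exactly as stated
above, with three independent RNG streams (PGS structure, phenotype
noise, missingness) so toggling missingness never changes the
underlying complete data. Missingness is MCAR, either cell-wise at a
global rate or by assigning families to genotype-availability patterns
with fixed counts.

The default study preset is 169 MZ + 246 DZ families (415 total) with
159/67/189 families having both/one/no parental genotypes, 378/37
having both/one twin genotypes, and a 17% cell-wise phenotype blanking
rate — which brings the overall missing fraction to roughly a quarter
of all data points. The default generating parameters are `V_PGS = 1`
(standardized scores), `r_a = 0.075` (spouse PGS correlations near
0.07–0.08), `g_tw = 0.157, g_m = −0.089, g_f = −0.015` (a child effect
of realistic size with small, negative parental paths), `V_ADHD = 0.95`
(implied phenotype variance near 1), and residual twin correlations
`r_MZ = 0.70, r_DZ = 0.35`, typical for rater-assessed childhood
symptom scores.

What the simulator does *not* emulate: non-Gaussian PGS or phenotypes,
informative (MAR/MNAR) missingness, rater effects, sibling interaction,
multigenerational dynastic structure, or measurement error in the PGS.
Passing calibration tests therefore demonstrates correctness of the
estimator under the model's own assumptions, not robustness to their
violation in real cohort data.

## Problem sizes used in the checks

The test suite calibrates the method at the following scales, chosen so
the Monte-Carlo error is small relative to the tolerances: moment
matching on 1e5 simulated DZ families; parameter recovery over 200
replicates at 2,000 families (with 200 replicates each at 1,000 and
4,000 families for the 1/sqrt(n) efficiency check); type-I error of the
nurture LRT over 500 null simulations at 2,000 families; bootstrap
coverage over 200 simulated datasets of 1,000 families with 500
replicates each; and 1e6 draws for the Monte-Carlo check of the
variance decomposition.

## Known limitations

* The saturated-model LRT and the derived CFI/TLI/RMSEA are
  anti-conservative when many saturated parameters are informed by few
  observations (sparse missingness patterns at a few hundred families).
* Residual phenotype variances are constrained equal across zygosity
  groups (only the residual correlations differ); sex-limitation,
  multivariate and longitudinal extensions are out of scope.
* `r_a` conflates assortative mating with residual stratification by
  design; the model cannot separate them.
* Percentile intervals are first-order accurate only; BCa or
  profile-likelihood intervals are not implemented.
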