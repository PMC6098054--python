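# Methods

## Model

The core model is the multivariate Cholesky twin decomposition. For
phenotypes `y_1 … y_p` measured on both members of same-sex twin pairs, each
phenotype loads on its own latent additive-genetic (A), shared-environment
(C) and non-shared-environment (E) factor and on the factors of all
preceding phenotypes, giving lower-triangular path matrices `L_A`, `L_C`,
`L_E`. Component covariance matrices are `A = L_A L_Aᵀ` etc., the
within-twin covariance is `V = A + C + E`, and the cross-twin covariance is
`A + C` for MZ pairs and `0.5·A + C` for DZ pairs (latent A factors
correlate 1 across MZ co-twins and 0.5 across DZ co-twins; C factors
correlate 1 in both groups; E factors are uncorrelated across twins). The
Cholesky parameterization guarantees positive semi-definite components; the
sign indeterminacy of each factor is resolved by constraining diagonals
non-negative.

Assumptions are the classical ones: additivity of genetic effects (no
dominance component is modelled — it would only be indicated when MZ
correlations exceed twice the DZ correlations, which the anchored truths do
not produce), no gene–environment correlation or interaction, equal
environments across zygosity, and multivariate-normal phenotypes.

### Likelihood

Fitting is full-information maximum likelihood: each pair contributes
`−2 log N(y_obs; μ_obs, Σ_obs)` evaluated on its *observed* subvector, so
single responders contribute the p-dimensional marginal of the responding
twin rather than being discarded. Pairs are grouped by zygosity × sex and by
missingness pattern; each pattern's covariance submatrix is Cholesky-factored
once per likelihood evaluation and all residual vectors are solved in one
triangular solve, which keeps a five-variate fit on ~760 pairs around a
second.

Degrees of freedom follow the observed-data-points convention:
`df = (number of non-missing phenotype entries) − (free parameters)`, and
`AIC = −2LL − 2·df`. This convention reproduces the AIC arithmetic of the
classical twin-modelling fit tables exactly.

### Sex limitation

Three regimes, in decreasing order of freedom:

- **common**: all path matrices free per sex (means are always free per sex
  and variable);
- **scalar**: one shared set of paths plus a free positive scale factor per
  variable for females (males fixed at 1), applied to all components alike —
  unstandardized covariances may differ between sexes while standardized
  parameters (heritabilities, component correlations) are identical by
  construction;
- **equal**: a single parameter set.

With scale factors fixed at one the scalar likelihood is exactly the equal
likelihood, and with identical per-sex paths the common likelihood is
exactly the equal likelihood; both identities are enforced by test.

### Optimization

The −2LL is minimized with L-BFGS-B under bounds (component diagonals ≥ 0;
the `L_E` diagonal bounded at 1e-6, which keeps every implied pair
covariance positive definite; scale factors ≥ 1e-3). Starting values are
moment-based: double-entered within-twin and cross-twin covariances give
Falconer-style estimates `Â = 2(Ĉ_MZ − Ĉ_DZ)`, `Ĉ = 2Ĉ_DZ − Ĉ_MZ`,
`Ê = V̂ − Â − Ĉ`, eigenvalue-floored to positive definiteness before
Cholesky factoring. `fit(n_restarts=...)` adds jittered restarts (default
5) and returns the best; since the moment starts land close to the optimum,
the recovery studies and most tests use 1–2 restarts, which in practice
reach the same optimum. Boundary solutions (a diagonal path at zero, e.g.
c ≈ 0 when fitting ACE to AE data) are flagged on the results object, not
treated as errors. Phenotypes are z-scored over all twins before fitting by
default; standardized quantities are always recomputed from implied
variances, so this only conditions the optimization.

### Profile confidence intervals

Intervals for scalar functions of the parameters (`h2:<var>`,
`rg:<v1>,<v2>`, …) are likelihood-based: the bound is where the profile
−2LL (minimized under an equality constraint on the quantity, via SLSQP
warm-started from the previous profile solution) rises by the χ²(1)
quantile (3.84 at 95%). The outward search expands in steps of 4% of the
quantity's natural range and brackets the crossing with Brent's method
(absolute tolerance 2e-3). A bound reaching the natural range edge (0/1 for
variance shares, ±1 for correlations) is returned one-sided and flagged.
Coverage is verified by simulation (200 small univariate cohorts) at
nominal 95% within binomial tolerance.

## Regression stage

The facet regression mirrors a GEE analysis of clustered twin data with an
independence working correlation: point estimates are OLS on z-scored
outcome and predictors (hence standardized betas), and standard errors are
CR1 cluster-robust sandwich estimates over twin pairs (statsmodels'
cluster covariance, which the tests check against a from-scratch
score-outer-product oracle; with singleton clusters it degenerates to HC1).
Multiple-testing control offers Bonferroni and Benjamini–Hochberg FDR; the
facet-selection rule retains facets with |β| above a threshold (default
0.10) and adjusted p below a threshold (default 0.01, applied to the FDR
column by default, with all three columns reported). Phenotypic
correlations are Pearson over all responding individuals with
pair-clustered p-values; twin–co-twin correlations are double-entered
(every complete pair contributes both orderings), making them invariant to
twin labelling, with the number of pairs as effective n for inference.

## Synthetic cohorts

The generator emulates the structure of a middle-aged same-sex twin cohort:
four zygosity-by-sex groups with default sizes 145 / 124 / 228 / 262 pairs
(MZ-m, DZ-m, MZ-f, DZ-f), ages uniform on 50–65 (SD ≈ 4.3, close to the
cohort's reported 4.5), a single-responder rate of 0.161 (one twin's
phenotypes blanked, the twin chosen at random so individual-level marginals
are unchanged), and optional measurement-error injection that adds
independent noise of variance `σ²_true·(1−α)/α` so the observed score's
reliability equals a target Cronbach's α. Phenotypes are simulated at
scale-score level — downstream analyses use scale scores only — and the
three generation stages (structure, missingness, noise) consume independent
child streams of the design seed, so toggling one stage does not perturb
the others. Age slopes are supported but default to zero (the biometric
models are fitted without age adjustment by default).

What the generator does *not* emulate: item-level responses and floor/
ceiling effects of Likert scales (phenotypes are exactly multivariate
normal), opposite-sex pairs, non-additive genetic architecture, and any
gene–environment interplay. Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness to their violation in real questionnaire data.

### Anchored generating truths

Three ready-made truths drive the demonstrations and recovery studies. All
are AE architectures (the anchored solutions contain no C), built as
`A = D_a R_g D_a`, `E = D_e R_e D_e` from standardized summaries and then
Cholesky-factored with the target variable last.

- **Trivariate** (neuroticism, extraversion, life satisfaction):
  heritabilities 0.53 / 0.49 / 0.32; genetic correlations with LS −0.70 (N)
  and 0.53 (E); environmental correlations −0.32 and 0.15. The N–E
  component correlations are not available as published values; −0.35
  (genetic) and −0.15 (environmental) were chosen once, and imply
  phenotypic correlations r(N,LS) = −0.47 and r(E,LS) = 0.30 — matching the
  published descriptive table to two decimals, which corroborates the
  construction.
- **Five-facet** (anxiety, depression, activity, positive emotions, LS):
  heritabilities 0.47 / 0.46 / 0.42 / 0.40 / 0.31, and the LS variance
  decomposition pinned *exactly* to 20% personality-genetic, 11%
  unique-genetic, 11% personality-environmental, 58% unique-environmental.
  Genetic correlations of LS with the neuroticism facets are held at the
  published −0.74 / −0.71; the two extraversion-facet cross-loadings are
  then solved (a scalar quadratic) so the personality-genetic share is
  exactly 0.20. Facet–facet component correlations use high within-domain
  (r_g 0.80 / 0.75, r_e 0.45 / 0.40) and moderate negative cross-domain
  values (−0.40 genetic, −0.15 environmental), plausible for neuroticism
  versus extraversion facets.
- **Study truth** (30 NEO facets + LS): within-domain r_g 0.70 and r_e
  0.30, small cross-domain values, facet heritability 0.45; LS is the
  standardized four-facet equation (−0.15 anxiety, −0.35 depression, +0.12
  activity, +0.16 positive emotions) explaining R² = 0.33 of its variance
  plus an independent AE residual contributing 11% unique-genetic variance.
  This truth drives the facet-selection demonstrations: at study-like n the
  selection rule recovers exactly the four generating facets in ≥ 90% of
  seeds.

In the anchored truths the reliability is left at 1: the published E
component already contains random measurement error (the 9% implied by
α = 0.91 for the target scale), so it is folded into `L_E` rather than
added on top; `inject_measurement_error` exists as a separate stage for
explicit reliability studies.

## Recovery studies and problem sizes

The recovery studies (`twinsat.recovery`, also run by
`scripts/acceptance.py`) simulate 20 replicate cohorts of 759 pairs with
single-responder rate 0.161, fit the equal-across-sex AE model (the
anchored solutions have standardized parameters equal across sex, so this
is the efficient parameterization of the same standardized solution), and
average the standardized quantities. At this design the Monte-Carlo
standard error of a mean heritability is about 0.01, comfortably inside the
±0.05 recovery tolerance. The profile-CI coverage study uses 200 univariate
AE cohorts of 4 × 75 complete pairs, generating h² = 0.5; the test-suite
null-selection study uses 120 null cohorts of 150 pairs with 30 predictors.
These sizes were chosen to keep the full test suite in the minutes range
while leaving Monte-Carlo error well below every asserted tolerance.

## Numerical choices and degenerate inputs

- Non-positive-definite implied covariances during optimization return a
  large penalty (1e12) rather than raising; bounds make this rare.
- Groups with fewer than three complete pairs yield missing twin-correlation
  entries, not exceptions; zero-variance variables are rejected at model
  construction and flagged in correlation tables.
- A rank-deficient regression design raises an error naming the collinear
  columns (identified via the QR diagonal).
- Model comparison flags negative Δ−2LL beyond 1e-6 and non-nested
  requests (more free parameters than the base) with warnings and NaN
  p-values; Δdf = 0 against itself gives p = 1.
- Percent outputs are carried at full precision and rounded only in
  reporting.
- When a C component is present, the target-variance partition folds its
  cross and unique contributions into the environmental shares.

## Known limitations

- The scalar-sex-limitation scale factors multiply all components alike;
  per-component scalar limitation is not implemented.
- Dominance (D) components, ordinal-threshold likelihoods, GxE moderation
  and definition variables are out of scope.
- The saturated-model −2LL is closed-form and therefore available for
  complete-response cohorts only.
- Profile CIs assume the χ²(1) calibration; near parameter-space boundaries
  they are returned one-sided and flagged rather than corrected.
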