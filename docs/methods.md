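# Methods

`collidermr` implements the individual-level ("one-sample") Mendelian
randomisation toolkit needed to ask whether an exposure causally affects an
outcome when exposure, genotypes and outcome are measured in the same
cohort: two-stage least squares (TSLS) univariable and multivariable MR, a
pleiotropy-robust multivariable collider-correction estimator, difference-
method mediation with bootstrap uncertainty, instrument quality control,
and moderation analyses.  Everything is exercised on a synthetic cohort
generator, because the cohort data such analyses are usually run on
(biobank-scale individual-level genotypes and phenotypes) is access-
controlled and cannot ship with a package.

## Models and estimators

### TSLS MR

With allele dosages `G` (n x m), exposures `X` (n x K), covariates `C` and
outcome `Y`, stage 1 regresses each exposure on all instruments and
covariates; stage 2 regresses `Y` on the predicted exposures and
covariates.  For continuous outcomes the package reports proper IV
standard errors (residual variance taken against the observed, not
predicted, exposures).  For binary outcomes stage 2 is a logistic
regression on the predicted exposures (two-stage predictor substitution)
and effects are on the log-odds scale; the reported standard errors are
the logistic fit's, without first-stage propagation — the standard
practice for this design — and a bootstrap SE mode exists where the extra
variability matters.  Exposures are inverse-normal transformed (Blom
offsets 3/8, 1/4) before analysis so effects read "per 1 SD of exposure".

Instrument strength: per-instrument first-stage F (averaged; the "mean F")
and the joint F for univariable models; the Sanderson–Windmeijer
conditional F for multivariable models.  The conditional F for exposure k
is computed by TSLS-partialling the other exposures out of X_k (fitting
X_k on the other exposures with their genetically predicted values as
regressors, residualising against the observed values) and taking the
instruments' F on the remainder with numerator degrees of freedom
m − (K − 1).  The TSLS partialling matters: projecting on the *predicted*
exposures directly leaves first-stage estimation noise in the fitted
coefficient and inflates the statistic in exactly the collinear regimes it
is meant to flag.  Over-identification is assessed with the Sargan n·R²
statistic on χ² with m − K degrees of freedom.

### Multivariable collider correction

Naive TSLS MVMR is biased when instruments are weak or pleiotropic
(variants with direct outcome paths).  The collider-correction device
splits estimation into:

1. an observational fit `Y ~ X1..XK + C` giving the confounded
   coefficients `beta_obs`, plus per-SNP summary associations: the
   conditional SNP–outcome association `alpha*_j` (coefficient of SNP j in
   `Y ~ G_j + X + C`, one SNP at a time) and SNP–exposure associations
   `gamma_kj` from `X_k ~ G_j + C`;
2. a summary-data regression of `alpha*` on `gamma` giving a correction
   `Delta`, with causal effects `beta = beta_obs + Delta` (an identity by
   construction).

Because stage 2 consumes only summary associations, any robust summary
estimator can stand in it.  The one implemented minimises
`sum_j rho(t_j)` with standardised residuals
`t_j = (alpha*_j − gamma_j·Delta) / s_j(Delta)`,
`s_j² = se_alpha_j² + sum_k Delta_k² se_gamma_kj²` (an overlap-correlation
cross term is available and defaults to 0 for the one-sample conditional
associations).  The Delta-dependent scale makes this an adjusted-profile-
score objective: its score contains an errors-in-variables term that
removes weak-instrument dilution.  Losses: squared (reduces exactly to
multi-exposure IVW when the gamma uncertainty is negligible), Huber
(k = 1.345) and Tukey biweight (c = 4.685, ≈95% Gaussian efficiency, the
default), the robust pair down-weighting outlying — pleiotropic — SNPs
with per-SNP weights ψ(t)/t in [0, 1] reported for audit.

Numerics.  The profile objective flattens as |Delta| grows (the scale
saturates every residual), so generic descent can escape to a spurious
basin; and the errors-in-variables score term is destabilised by gross
outliers under the non-robust losses.  The solver therefore proceeds in
two phases: (A) a damped reweighted-IVW fixed point *without* the
errors-in-variables term, chained squared → Huber → Tukey, which is stable
under contamination and settles the outlier weights at the price of some
dilution; (B) one corrected fixed-point solve for the target loss from
that point (`Delta = (A − D)⁻¹ b`, D the errors-in-variables diagonal),
with a step cap and a locality guard — if the corrected score still leaves
the warm start's neighbourhood the diluted phase-A solution is kept and
flagged.  Standard errors: a sandwich formula with the scale fixed at the
solution; combined with the observational stage's variance assuming stage
independence, or by a full bootstrap over individuals (the reference
method; agreement is checked in the tests).

The exact construction of this multivariable extension (the stage-1
regressions and the choice of summary estimator) is a reconstruction from
the univariable collider-correction idea; the SNP-at-a-time choice for
`alpha*` was made because it scales in m and matches the univariable
precedent.  Each stage is exposed separately so alternatives can be
swapped in.

### Univariable robust summary MR (RAPS-style)

For weak-instrument univariable summary problems (e.g. reverse-direction
analyses), `mr_raps_uv` maximises the same profile objective in one
dimension with an additive overdispersion variance τ² ≥ 0 for systematic
balanced pleiotropy.  τ² is updated by moment-matching the robustly
weighted standardised residuals (E[ψ(t)t] under N(0,1) as the consistency
target, m − 1 as the effective count), truncated at zero — a simplification
of the full joint adjusted-profile-score maximisation that keeps the
estimator inside the same fixed-point machinery.

### Mediation

The difference method: total effect of X on Y from univariable MR, direct
effect from multivariable MR that also genetically proxies the mediator,
indirect = total − direct (exact), mediated proportion
π_m = indirect / total, interpretable as a proportion only when indirect
and total share a sign (a flag records this; π_m is reported untruncated
either way, so values outside [0, 1] remain visible).  Uncertainty comes
from re-running every regression stage under bootstrap weights:

* non-parametric bootstrap — multinomial resampling expressed as counts/n;
* Bayesian bootstrap — flat Dirichlet(1,…,1) weights (normalised unit
  exponentials), every observation kept with strictly positive weight.

π_m is computed per draw; the point estimate is the median of the draws
and the CI the 2.5th/97.5th percentiles.  Weighted refits that fail (e.g.
separation in a sparse weighted logistic fit) are dropped and counted; if
more than 5% of draws fail the result is refused rather than silently
summarised.  The Bayesian variant is the one to prefer for sparse binary
outcomes: resampling can drop most of the few cases from a draw, whereas
Dirichlet weighting never does.

For speed the bootstrap loop runs on sufficient statistics: covariates,
instruments, exposures and outcome are stacked once, each weighted refit
reduces to one weighted cross-product matrix plus small solves, and the
weighted logistic stage uses an internal IRLS routine whose score
equations match statsmodels GLM with variance weights (checked in tests).

### Instrument QC

Greedy clumping (ascending p, window 50 kb, r² > 0.001 removed; ties
broken on (chrom, pos, id) for determinism); iterative pairwise LD pruning
on sample dosage correlations at r² > 0.05 keeping the smaller discovery p
(a `literal` flag reproduces the keep-largest-p reading of the source
protocol's text, which contradicts its own clumping rule and is treated as
an erratum); weighted genetic risk scores after allele harmonisation (sign
flips for swapped alleles, strand resolution through complements,
ambiguous palindromic variants with EAF in (0.42, 0.58) dropped); Steiger
directionality filtering retaining a SNP only if it explains more variance
in the target trait than in every competitor (point r² comparison;
individual-level r² as squared covariate-adjusted correlation, summary
r² = 2f(1−f)β², both invariant to common rescaling).

### cis-PC MR

For a dense region of correlated variants, the weighted LD matrix
ψ_ij = bx_i bx_j R_ij / (sy_i sy_j) is eigen-decomposed; SNP-exposure and
SNP-outcome vectors are projected onto the top k components and combined
by IVW with the correlation-adjusted covariance.  k defaults to the
components explaining ≥99% of variance (a fixed k, e.g. 10, is available);
the LD matrix gets a 1e-6 ridge.  With identity LD and full rank this
reduces exactly to standard IVW, and duplicated variants do not change the
estimate.

### Moderation

Stratified estimation runs any estimator per stratum (moderator excluded
from its own strata's covariates; a failing stratum is recorded, not
fatal).  Two-stratum heterogeneity uses Fisher's
z = (b1 − b2)/√(se1² + se2²).  Trends across ordered strata use
fixed-effect (inverse-variance) weighted least squares of stratum effects
on the centred moderator, optionally plus the centred square (centring
decorrelates the terms).  Q statistics are weighted residual sums of
squares; Q_diff = Q(intercept-only) − Q(model) is χ² with one df per added
term, and the additivity Q_reduced = Q_full + Q_diff is exact.  Fixed
rather than random effects was the design choice; Q is always reported so
over-dispersion is visible, and age-bin moderator values are bin
midpoints.

## The synthetic cohort generator

`simulate_two_exposure_cohort` draws independent Hardy–Weinberg dosages
(two Bernoulli(maf) alleles; maf uniform in a configurable range,
default 0.1–0.5), builds two exposures from partially overlapping SNP sets
plus a shared standard-normal confounder and noise, z-standardises them,
and forms the outcome `Y = b1·X1 + b2·X2 + Σ α_j G_j + c3·U + ε` with
direct SNP effects α on a configurable fraction of exposure-1 SNPs
(normal with configurable mean/sd: directional when the mean is nonzero,
balanced at zero).  `simulate_mediation_cohort` chains
X → M → Y with the mediator's own instruments, keeping the identity
total = b_direct + b_XM·b_MY exact by standardising only the mediator's
non-causal component.  Binary outcomes replace the outcome noise with a
Bernoulli draw on a logistic (optionally probit) latent scale whose
intercept is solved by root-finding to hit a target prevalence to 1e-6.
A single seed is split into per-stage streams, so cohorts are bit-
reproducible and a continuous and a binary cohort from the same seed share
identical exposure and mediator columns.

Deliberate simplifications: SNPs are mutually independent (no LD
structure beyond constructions the tests build explicitly), allele
frequencies are uniform rather than realistic site-frequency spectra,
confounders and noise are Gaussian (chosen so closed-form oracles exist),
and there is no assortative mating or family structure.  Passing tests
therefore demonstrate correctness of the estimators under the assumed
statistical structure, not robustness to everything real cohort data can
do.

## Study regimes and problem sizes

The standing simulation studies (in `collidermr.studies`, driven by the
`analysis/` scripts and `scripts/acceptance.py`) use these conditions:

* **Two-exposure recovery** — n = 5 000, 30 SNPs per exposure,
  `gamma_scale` 0.07 giving per-SNP F around 5–10 (a weak-instrument
  regime), confounder loadings 0.5, directional pleiotropy on 20% of
  exposure-1 SNPs (α ~ N(0.25, 0.05)), generating effects β_X1 = 1.0,
  β_X2 = 0.5; 500 replicates.  The per-SNP effect magnitudes and loadings
  are the package's own calibration of the qualitative regime (weak
  conditional instruments, material naive-TSLS bias) since only the
  targets themselves are fixed a priori.
* **Mediation coverage** — n = 2 000, 15 SNPs per exposure, strong
  instruments (`gamma_scale` 0.2), chain (b_direct, b_XM, b_MY) =
  (0.2, 0.5, 0.4) so the true total is 0.4 and π_m = 0.5; 500 replicates
  at B = 400 Bayesian-bootstrap draws.
* **Sparse binary comparison** — prevalence 0.01 at n = 3 000 (about 30
  cases), both bootstrap flavours on identical cohorts, 150 replicates at
  B = 250.
* **Calibration** — Sargan null at 1 000 replicates (n = 2 000, 30 SNPs);
  Fisher-z null at 500 replicates of sex-stratified UVMR on homogeneous
  cohorts.

Replicate counts and cohort sizes are scaled so each study completes in
minutes on a single CPU while leaving Monte-Carlo error well below the
effects being checked.

## Known limitations

* Binary-outcome TSLS inherits the non-collapsibility of odds ratios; no
  correction is attempted, matching standard practice for this design.
* The analytic SE of the collider-corrected estimator treats the
  observational and summary stages as independent; the bootstrap mode is
  the reference when that assumption is in doubt.
* The robust summary stage assumes outlying pleiotropy is a minority of
  SNPs; with a majority of invalid instruments no loss function here (nor
  any) identifies the causal effect.
* `mr_raps_uv`'s τ² moment update is a pragmatic simplification; severe
  directional pleiotropy should be handled by the robust losses, not τ².
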