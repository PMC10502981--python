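# collidermr

One-sample Mendelian randomisation in Python: individual-level TSLS
estimators, a pleiotropy-robust multivariable **collider-correction**
estimator, difference-method **mediation** with Bayesian-bootstrap
uncertainty, instrument quality control, and moderation analyses — all
exercised on a synthetic cohort generator, since the individual-level
biobank data these designs target is access-controlled.

## Who this is for

Genetic epidemiologists running MR inside a single cohort (exposure,
genotypes and outcome measured on the same people).  In that design the
usual two-sample summary toolbox does not apply directly, weak-instrument
bias pulls TSLS toward the confounded observational estimate, and variants
with direct outcome effects (pleiotropy) violate the exclusion
restriction.  The centre of this package is an estimator that deals with
both at once.

## The core idea

For exposures X (n × K), instruments G (n × m) and outcome Y:

1. **Observational stage.** Fit Y ~ X₁..X_K + C; keep the (biased)
   coefficients β_obs.  For each SNP j, record the conditional SNP–outcome
   association α̂\*ⱼ (coefficient of Gⱼ in Y ~ Gⱼ + X + C) and the
   SNP–exposure associations γ̂ₖⱼ.
2. **Correction stage.** Under the model E[α̂\*ⱼ] = αⱼ + γⱼᵀ(β − β_obs),
   regress α̂\* on γ̂ with a robust summary-data estimator: minimise
   Σⱼ ρ(tⱼ), tⱼ = (α̂\*ⱼ − γⱼᵀΔ)/sⱼ(Δ), sⱼ² = se²\_αⱼ + Σₖ Δₖ² se²\_γₖⱼ.
   The Δ-dependent scale makes this an adjusted profile score (no
   weak-instrument dilution); Tukey/Huber losses down-weight pleiotropic
   outliers.  Then **β̂ = β_obs + Δ̂**.

Around it: TSLS UVMR/MVMR with mean/joint/conditional-F diagnostics and
the Sargan test, a RAPS-style weak-instrument-robust univariable summary
estimator, cis-PC MR for dense correlated regions, clumping/LD
pruning/Steiger filtering/risk scores, bootstrap mediation
(π_m = (total − direct)/total), and sex/age moderation with Fisher-z and
inverse-variance meta-regression.  `docs/methods.md` has the full account.

## Worked example

The headline simulation study: two correlated exposures with true effects
(1.0, 0.5), weak instruments (per-SNP F ≈ 5–10) and directional pleiotropy
on 20% of exposure-1 SNPs.

```bash
python analysis/03_collider_recovery.py --seed 1 --reps 500
```

prints

```
exposure  truth  cc_mean  cc_mc_se  tsls_mean  tsls_mc_se
      x1 1.0000   1.0020    0.0044     1.6466      0.0067
      x2 0.5000   0.5010    0.0042     0.5042      0.0050

Over 500 replicates the collider-corrected estimates sit within Monte-Carlo
error of the generating effects, while naive TSLS MVMR is off by +0.647 on
the pleiotropy-laden exposure.
```

Naive TSLS MVMR overshoots the pleiotropy-laden exposure by 65% of an SD;
the collider-corrected estimator centres on the generating values to
within Monte-Carlo error.  The same machinery is available
programmatically:

```python
from collidermr import SimulationConfig, simulate_two_exposure_cohort
from collidermr import collider_correction_mvmr, tsls_mvmr

cfg = SimulationConfig(seed=1)          # the weak/pleiotropic defaults
geno, cohort, truth = simulate_two_exposure_cohort(cfg)
cc = collider_correction_mvmr(geno, cohort[["x1", "x2"]], cohort["y"], loss="tukey")
print(cc.to_frame())                    # beta_obs, delta, beta = beta_obs + delta, CIs
```

The other analysis drivers follow the same pattern and say what they find:
`04_mediation_coverage.py` (95% bootstrap coverage for the mediated
proportion, Bayesian vs non-parametric at 1% outcome prevalence),
`05_test_calibration.py` (Sargan and Fisher-z type-I error at the nominal
5%), `06_moderation.py` (null sex/age moderation on a homogeneous cohort,
e.g. `Fisher z = 0.14 (p = 0.888)`).  A `collidermr` CLI exposes each step
(`simulate`, `clump`, `prune`, `grs`, `steiger`, `uvmr`, `mvmr`, `cispc`,
`cc-mvmr`, `mediate`, `stratify`, `pipeline`) over PLINK `.raw` dosage
text, phenotype CSVs and GWAS summary TSVs.

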