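"""Replicated simulation studies over the synthetic cohort generator.

These drivers define the package's standing evaluation of its estimators:

* two-exposure recovery under weak instruments and directional pleiotropy
  (collider correction vs naive TSLS MVMR, generating effects 1.0 / 0.5);
* calibration of the Sargan over-identification test and of the Fisher-z
  sex-heterogeneity test under their nulls;
* coverage of the bootstrap confidence interval for the mediated
  proportion (true pi_m = 0.5) in the well-behaved continuous regime, and
  the Bayesian-vs-non-parametric bootstrap comparison at sparse binary
  prevalence.

The same routines back the numbered analysis scripts, the acceptance
checks and the test suite, so every reported number comes from one code
path.  Problem sizes are chosen so each study runs in minutes on one CPU;
see docs/methods.md for the rationale behind each regime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._regression import FitError
from .collider import collider_correction_mvmr
from .estimators import sargan_test, tsls_mvmr, tsls_uvmr
from .mediate import MediationError, bootstrap_mediation
from .moderate import fisher_z_heterogeneity
from .simulate import (
    SimulationConfig,
    simulate_mediation_cohort,
    simulate_two_exposure_cohort,
)

#: Fig-S9-style regime: weak instruments (per-SNP F around 5-10) and
#: directional pleiotropy on 20% of exposure-1 SNPs.
WEAK_PLEIOTROPY_CONFIG = dict(
    n_individuals=5000,
    n_snps_per_exposure=30,
    gamma_scale=0.07,
    beta_x1=1.0,
    beta_x2=0.5,
    pleiotropy_fraction=0.2,
    pleiotropy_mean=0.25,
    pleiotropy_sd=0.05,
    confounder_effects=(0.5, 0.5, 0.5),
)

#: Mediation chain with true total 0.4 and true mediated proportion 0.5,
#: strong instruments, moderate confounding.
MEDIATION_CONFIG = dict(
    n_individuals=2000,
    n_snps_per_exposure=15,
    gamma_scale=0.2,
    beta_xy_direct=0.2,
    beta_xm=0.5,
    beta_my=0.4,
    confounder_effects=(0.3, 0.3, 0.3),
)


def _child_seeds(seed: int, k: int) -> np.ndarray:
    return (np.random.SeedSequence(seed).generate_state(k) % (2**31 - 1)).astype(np.int64)


def collider_recovery_study(
    n_reps: int = 500,
    seed: int = 0,
    loss: str = "tukey",
    config_overrides: dict | None = None,
) -> dict:
    """Mean collider-correction vs naive TSLS MVMR estimates over replicates.

    Under the weak-instrument + directional-pleiotropy regime the corrected
    estimator should centre on the generating effects (1.0, 0.5) while
    naive TSLS MVMR is materially biased.
    """
    base = dict(WEAK_PLEIOTROPY_CONFIG)
    base.update(config_overrides or {})
    seeds = _child_seeds(seed, n_reps)
    cc_rows, naive_rows = [], []
    n_failed = 0
    for r in range(n_reps):
        cfg = SimulationConfig(seed=int(seeds[r]), **base)
        geno, cohort, truth = simulate_two_exposure_cohort(cfg)
        exposures = cohort[["x1", "x2"]]
        try:
            est_cc = collider_correction_mvmr(geno, exposures, cohort["y"], loss=loss).beta
        except FitError:
            n_failed += 1
            continue
        naive_rows.append(tsls_mvmr(geno, exposures, cohort["y"], diagnostics=False).beta)
        cc_rows.append(est_cc)
    if n_failed > 0.02 * n_reps:
        raise FitError(
            f"collider-correction failed in {n_failed}/{n_reps} replicates; "
            "the regime is outside the estimator's working range"
        )
    cc = np.asarray(cc_rows)
    naive = np.asarray(naive_rows)
    n_reps = len(cc_rows)
    truth_vec = np.array([base["beta_x1"], base["beta_x2"]])
    return {
        "truth": truth_vec,
        "cc_mean": cc.mean(axis=0),
        "cc_mc_se": cc.std(axis=0, ddof=1) / np.sqrt(n_reps),
        "tsls_mean": naive.mean(axis=0),
        "tsls_mc_se": naive.std(axis=0, ddof=1) / np.sqrt(n_reps),
        "cc_bias": cc.mean(axis=0) - truth_vec,
        "tsls_bias": naive.mean(axis=0) - truth_vec,
        "n_reps": n_reps,
        "n_failed": n_failed,
        "loss": loss,
        "estimates": {"cc": cc, "tsls": naive},
    }


def sargan_calibration_study(
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    pleiotropy: bool = False,
    n_individuals: int = 2000,
) -> dict:
    """Rejection rate of the Sargan test for a univariable 30-SNP TSLS fit.

    ``pleiotropy=False`` is the null (no direct SNP-outcome paths);
    ``pleiotropy=True`` switches on large directional effects for 20% of
    SNPs, where the test should reject nearly always.
    """
    base = dict(
        n_individuals=n_individuals,
        n_snps_per_exposure=30,
        gamma_scale=0.15,
        beta_x1=0.3,
        beta_x2=0.0,
        confounder_effects=(0.5, 0.5, 0.5),
    )
    if pleiotropy:
        base.update(pleiotropy_fraction=0.2, pleiotropy_mean=0.3, pleiotropy_sd=0.05)
    seeds = _child_seeds(seed, n_reps)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        cfg = SimulationConfig(seed=int(seeds[r]), **base)
        geno, cohort, truth = simulate_two_exposure_cohort(cfg)
        G = geno.values()[:, [geno.ids.index(i) for i in truth.snp_ids_x1]]
        pvals[r] = sargan_test(G, cohort[["x1"]], cohort["y"])["p"]
    rate = float(np.mean(pvals < alpha))
    return {
        "rejection_rate": rate,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
        "n_reps": n_reps,
        "alpha": alpha,
        "pleiotropy": pleiotropy,
    }


def fisher_z_calibration_study(
    n_reps: int = 500, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Type-I error of the Fisher-z heterogeneity test between sex strata.

    Cohorts are homogeneous (sex has no effect anywhere), each replicate
    fits the univariable MR separately in the two strata and tests their
    difference; the rejection rate should sit at the nominal level.
    """
    base = dict(
        n_individuals=2000,
        n_snps_per_exposure=20,
        gamma_scale=0.2,
        beta_x1=0.3,
        beta_x2=0.0,
        confounder_effects=(0.5, 0.5, 0.5),
    )
    seeds = _child_seeds(seed, n_reps)
    rejections = np.empty(n_reps, dtype=bool)
    for r in range(n_reps):
        cfg = SimulationConfig(seed=int(seeds[r]), **base)
        geno, cohort, truth = simulate_two_exposure_cohort(cfg)
        G = geno.values()[:, [geno.ids.index(i) for i in truth.snp_ids_x1]]
        ests = []
        for sex in (0.0, 1.0):
            idx = np.flatnonzero(cohort["sex"].to_numpy() == sex)
            est = tsls_uvmr(
                G[idx], cohort["x1"].to_numpy()[idx], cohort["y"].to_numpy()[idx],
                diagnostics=False,
            )
            ests.append((float(est.beta[0]), float(est.se[0])))
        z, p = fisher_z_heterogeneity(ests[0][0], ests[0][1], ests[1][0], ests[1][1])
        rejections[r] = p < alpha
    rate = float(np.mean(rejections))
    return {
        "rejection_rate": rate,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
        "n_reps": n_reps,
        "alpha": alpha,
    }


def mediation_coverage_study(
    n_reps: int = 500,
    B: int = 400,
    seed: int = 0,
    method: str = "bb",
    outcome_type: str = "continuous",
    prevalence: float | None = None,
    config_overrides: dict | None = None,
) -> dict:
    """Coverage of the bootstrap pi_m interval at nominal 95%.

    Each replicate draws a fresh mediation cohort (true pi_m = 0.5), runs
    the full bootstrap, and checks whether the percentile interval covers
    the truth.  Replicates whose bootstrap exceeds the 5% refit-failure cap
    are counted separately and excluded from the coverage denominator.
    """
    base = dict(MEDIATION_CONFIG)
    base.update(config_overrides or {})
    base.update(outcome_type=outcome_type, prevalence=prevalence)
    seeds = _child_seeds(seed, 2 * n_reps)
    covered, widths = [], []
    n_error = 0
    pi_true = None
    for r in range(n_reps):
        cfg = SimulationConfig(seed=int(seeds[r]), **base)
        geno, cohort, truth = simulate_mediation_cohort(cfg)
        pi_true = truth.pi_m_true
        Gx = geno.values()[:, [geno.ids.index(i) for i in truth.snp_ids_x1]]
        Gm = geno.values()[:, [geno.ids.index(i) for i in truth.snp_ids_x2]]
        try:
            res = bootstrap_mediation(
                cohort, Gx, Gm,
                outcome_type=outcome_type,
                method=method,
                B=B,
                seed=int(seeds[n_reps + r]),
            )
        except (MediationError, FitError):
            n_error += 1
            continue
        lo, hi = res.pi_ci
        covered.append(lo <= pi_true <= hi)
        widths.append(hi - lo)
    n_ok = len(covered)
    coverage = float(np.mean(covered)) if n_ok else float("nan")
    return {
        "coverage": coverage,
        "mc_se": float(np.sqrt(0.95 * 0.05 / n_ok)) if n_ok else float("nan"),
        "pi_true": pi_true,
        "median_ci_width": float(np.median(widths)) if widths else float("nan"),
        "n_reps": n_reps,
        "n_used": n_ok,
        "n_failed_replicates": n_error,
        "B": B,
        "method": method,
        "outcome_type": outcome_type,
        "prevalence": prevalence,
    }


def sparse_binary_comparison(
    n_reps: int = 150,
    B: int = 250,
    seed: int = 0,
    prevalence: float = 0.01,
    n_individuals: int = 3000,
) -> dict:
    """Bayesian vs non-parametric bootstrap at sparse binary prevalence.

    Runs both methods on identical cohorts and reports their pi_m interval
    coverage and failed-replicate counts; the Bayesian bootstrap, which
    never loses the few cases to resampling, should be non-inferior.
    """
    out = {}
    for method in ("bb", "np"):
        out[method] = mediation_coverage_study(
            n_reps=n_reps,
            B=B,
            seed=seed,
            method=method,
            outcome_type="binary",
            prevalence=prevalence,
            config_overrides={"n_individuals": n_individuals},
        )
    return {
        "bb_coverage": out["bb"]["coverage"],
        "np_coverage": out["np"]["coverage"],
        "bb_failed_replicates": out["bb"]["n_failed_replicates"],
        "np_failed_replicates": out["np"]["n_failed_replicates"],
        "mc_se": out["bb"]["mc_se"],
        "n_reps": n_reps,
        "B": B,
        "prevalence": prevalence,
        "details": out,
    }
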