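"""Synthetic one-sample MR cohorts.

Generates individual-level data with the structure the downstream analyses
assume: two correlated continuous exposures instrumented by partially
overlapping SNP sets, an unmeasured confounder, direct (pleiotropic)
SNP-to-outcome paths, continuous or sparse binary outcomes, and an
exposure -> mediator -> outcome chain.  All randomness flows from a single
seed, split into per-stage streams so that e.g. a continuous and a binary
cohort built from the same seed share identical exposure and mediator
columns.

The data-generating mechanisms:

two-exposure (pleiotropy) design
    X1 = G1 gamma1 + c1 U + e1,  X2 = G2 gamma2 + c2 U + e2 (then
    z-standardised so causal effects are per 1 SD of exposure), and
    Y = bX1 X1 + bX2 X2 + sum_j alpha_j G_j + c3 U + eY with alpha_j
    nonzero for a configurable fraction of exposure-1 SNPs (directional
    when their mean is nonzero).

mediation design
    X  = standardised(G1 gamma1 + c1 U + e1)
    M  = bXM X + standardised(G2 gamma2 + c2 U + eM)
    Y  = bdir X + bMY M + c3 U + eY
    so the total effect of X on Y is exactly bdir + bXM * bMY.

Binary outcomes replace eY with a Bernoulli draw on a logistic (or probit)
latent scale whose intercept is solved to hit a target prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import GenotypeMatrix, ParameterError


class GenerationError(RuntimeError):
    """The requested cohort could not be generated (degenerate variance)."""


class DegenerateInputError(ValueError):
    """Input vector carries no usable variation."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Effects are per-allele on the exposure scale (``gamma_scale``), per 1 SD
    of exposure on the outcome (``beta_*``).  ``pleiotropy_mean`` != 0 gives
    directional pleiotropy, 0 gives balanced.  ``prevalence`` applies to
    binary outcomes only.
    """

    n_individuals: int = 5000
    n_snps_per_exposure: int = 30
    shared_snp_fraction: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_scale: float = 0.07
    beta_x1: float = 1.0
    beta_x2: float = 0.5
    beta_xm: float = 0.5
    beta_my: float = 0.4
    beta_xy_direct: float = 0.2
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    confounder_effects: tuple[float, float, float] = (0.5, 0.5, 0.5)
    outcome_type: str = "continuous"
    prevalence: float | None = None
    link: str = "logistic"
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ParameterError("n_individuals must be >= 1")
        if self.n_snps_per_exposure < 1:
            raise ParameterError("n_snps_per_exposure must be >= 1")
        if not 0.0 <= self.shared_snp_fraction <= 1.0:
            raise ParameterError("shared_snp_fraction must lie in [0, 1]")
        if not 0.0 <= self.pleiotropy_fraction <= 1.0:
            raise ParameterError("pleiotropy_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.outcome_type not in ("continuous", "binary"):
            raise ParameterError("outcome_type must be 'continuous' or 'binary'")
        if self.outcome_type == "binary":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ParameterError("binary outcomes need prevalence in (0, 1)")
        elif self.prevalence is not None:
            raise ParameterError("prevalence applies to binary outcomes only")
        if self.pleiotropy_sd < 0:
            raise ParameterError("pleiotropy_sd must be >= 0")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


@dataclass
class SimulationTruth:
    """Generating parameters realised for one synthetic cohort."""

    config: SimulationConfig
    snp_ids_x1: list[str]
    snp_ids_x2: list[str]
    gamma1: np.ndarray
    gamma2: np.ndarray
    alpha: np.ndarray
    beta_x1: float
    beta_x2: float
    beta_xm: float | None = None
    beta_my: float | None = None
    beta_xy_direct: float | None = None
    total_effect: float | None = None
    pi_m_true: float | None = None
    binary_intercept: float | None = None


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    id_prefix: str = "rs",
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages: two Bernoulli(maf) alleles per person per SNP.

    SNPs are mutually independent, spread over chromosomes 1-22 at 1 Mb
    spacing, with the drawn MAF stored as the effect-allele frequency.
    """
    if n < 1 or m < 1:
        raise ParameterError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if rng is None:
        rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(1, maf, size=(n, m)) + rng.binomial(1, maf, size=(n, m))
    ids = [f"{id_prefix}{j + 1}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "id": ids,
            "chrom": [str(j % 22 + 1) for j in range(m)],
            "pos": [1_000_000 * (j // 22 + 1) for j in range(m)],
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": maf,
        }
    )
    return GenotypeMatrix(pd.DataFrame(dosages.astype(float), columns=ids), variants)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = float(np.std(x))
    if sd == 0.0:
        raise GenerationError("degenerate (zero-variance) generated variable")
    return (x - float(np.mean(x))) / sd


def _stage_rngs(seed: int, k: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(k)]


def _split_snp_sets(m: int, shared_fraction: float, total_ids: list[str]):
    """Indices of the two (partially overlapping) instrument sets."""
    n_shared = int(round(shared_fraction * m))
    idx1 = np.arange(m)
    idx2 = np.arange(m - n_shared, 2 * m - n_shared)
    return idx1, idx2


def _draw_gammas(rng: np.random.Generator, m: int, scale: float) -> np.ndarray:
    if scale == 0.0:
        return np.zeros(m)
    g = scale * rng.uniform(0.5, 1.5, size=m)
    if np.all(g == 0.0):
        raise GenerationError("all SNP-exposure effects are zero at gamma_scale > 0")
    return g


def binary_from_latent(
    linear_predictor: np.ndarray,
    prevalence: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    link: str = "logistic",
    return_intercept: bool = False,
):
    """Bernoulli outcome on a latent linear predictor, intercept solved so the
    expected prevalence hits the target (to 1e-6 or better)."""
    if not 0.0 < prevalence < 1.0:
        raise ParameterError("prevalence must lie strictly in (0, 1)")
    eta = np.asarray(linear_predictor, dtype=float)
    if link == "logistic":
        cdf = special.expit
    elif link == "probit":
        cdf = stats.norm.cdf
    else:
        raise ParameterError("link must be 'logistic' or 'probit'")

    def gap(c: float) -> float:
        return float(np.mean(cdf(c + eta))) - prevalence

    intercept = optimize.brentq(gap, -60.0, 60.0, xtol=1e-12)
    if rng is None:
        rng = np.random.default_rng(seed)
    y = (rng.random(eta.shape[0]) < cdf(intercept + eta)).astype(int)
    if return_intercept:
        return y, intercept
    return y


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform.

    Maps value ranks through Phi^{-1}((rank - 3/8) / (n + 1/4)); ties get
    the average rank, so the output is order-isomorphic to the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ParameterError("expected a 1-D vector")
    if np.unique(x).size < 2:
        raise DegenerateInputError("inverse-normal transform needs >= 2 distinct values")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def _covariate_columns(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    # inert demographics for stratified analyses: no effect on any variable
    return {
        "age": rng.uniform(40.0, 74.0, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
    }


def simulate_two_exposure_cohort(config: SimulationConfig):
    """Cohort for the two-exposure pleiotropy design (see module docstring).

    Returns ``(GenotypeMatrix, cohort DataFrame, SimulationTruth)``; the
    cohort carries columns x1, x2, y, confounder, age, sex.
    """
    cfg = config
    n, m = cfg.n_individuals, cfg.n_snps_per_exposure
    rng_g, rng_gamma, rng_conf, rng_noise, rng_pleio, rng_y, rng_bin, rng_cov = _stage_rngs(
        cfg.seed, 8
    )
    n_shared = int(round(cfg.shared_snp_fraction * m))
    m_total = 2 * m - n_shared
    geno = simulate_genotypes(n, m_total, cfg.maf_range, rng=rng_g)
    G = geno.values()
    idx1, idx2 = _split_snp_sets(m, cfg.shared_snp_fraction, geno.ids)

    gamma1 = _draw_gammas(rng_gamma, m, cfg.gamma_scale)
    gamma2 = _draw_gammas(rng_gamma, m, cfg.gamma_scale)
    c1, c2, c3 = cfg.confounder_effects
    u = rng_conf.standard_normal(n)
    x1 = _standardize(G[:, idx1] @ gamma1 + c1 * u + rng_noise.standard_normal(n))
    x2 = _standardize(G[:, idx2] @ gamma2 + c2 * u + rng_noise.standard_normal(n))

    alpha = np.zeros(m_total)
    n_pleio = int(round(cfg.pleiotropy_fraction * m))
    if n_pleio > 0:
        # pleiotropic paths attach to exposure-1 instruments
        which = rng_pleio.choice(idx1, size=n_pleio, replace=False)
        alpha[which] = rng_pleio.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_pleio)

    eta = cfg.beta_x1 * x1 + cfg.beta_x2 * x2 + G @ alpha + c3 * u
    intercept = None
    if cfg.outcome_type == "binary":
        y, intercept = binary_from_latent(
            eta, cfg.prevalence, rng=rng_bin, link=cfg.link, return_intercept=True
        )
    else:
        y = eta + rng_y.standard_normal(n)

    cohort = pd.DataFrame({"x1": x1, "x2": x2, "y": y, "confounder": u})
    for name, col in _covariate_columns(rng_cov, n).items():
        cohort[name] = col
    truth = SimulationTruth(
        config=cfg,
        snp_ids_x1=[geno.ids[i] for i in idx1],
        snp_ids_x2=[geno.ids[i] for i in idx2],
        gamma1=gamma1,
        gamma2=gamma2,
        alpha=alpha,
        beta_x1=cfg.beta_x1,
        beta_x2=cfg.beta_x2,
        binary_intercept=intercept,
    )
    return geno, cohort, truth


def simulate_mediation_cohort(config: SimulationConfig):
    """Cohort for the exposure -> mediator -> outcome chain.

    Returns ``(GenotypeMatrix, cohort DataFrame, SimulationTruth)``; the
    cohort carries columns x, mediator, y, confounder, age, sex.  The truth
    record includes the exact identity total = bdir + bXM * bMY and the true
    mediated proportion.
    """
    cfg = config
    n, m = cfg.n_individuals, cfg.n_snps_per_exposure
    rng_g, rng_gamma, rng_conf, rng_noise, rng_m, rng_y, rng_bin, rng_cov = _stage_rngs(
        cfg.seed, 8
    )
    n_shared = int(round(cfg.shared_snp_fraction * m))
    m_total = 2 * m - n_shared
    geno = simulate_genotypes(n, m_total, cfg.maf_range, rng=rng_g)
    G = geno.values()
    idx1, idx2 = _split_snp_sets(m, cfg.shared_snp_fraction, geno.ids)

    gamma1 = _draw_gammas(rng_gamma, m, cfg.gamma_scale)
    gamma2 = _draw_gammas(rng_gamma, m, cfg.gamma_scale)
    c1, c2, c3 = cfg.confounder_effects
    u = rng_conf.standard_normal(n)
    x = _standardize(G[:, idx1] @ gamma1 + c1 * u + rng_noise.standard_normal(n))
    # mediator = causal part + standardised own (instrumented) component, so
    # the chain effect bXM * bMY is exact in the stated units
    m_own = _standardize(G[:, idx2] @ gamma2 + c2 * u + rng_m.standard_normal(n))
    mediator = cfg.beta_xm * x + m_own

    eta = cfg.beta_xy_direct * x + cfg.beta_my * mediator + c3 * u
    intercept = None
    if cfg.outcome_type == "binary":
        y, intercept = binary_from_latent(
            eta, cfg.prevalence, rng=rng_bin, link=cfg.link, return_intercept=True
        )
    else:
        y = eta + rng_y.standard_normal(n)

    total = cfg.beta_xy_direct + cfg.beta_xm * cfg.beta_my
    cohort = pd.DataFrame({"x": x, "mediator": mediator, "y": y, "confounder": u})
    for name, col in _covariate_columns(rng_cov, n).items():
        cohort[name] = col
    truth = SimulationTruth(
        config=cfg,
        snp_ids_x1=[geno.ids[i] for i in idx1],
        snp_ids_x2=[geno.ids[i] for i in idx2],
        gamma1=gamma1,
        gamma2=gamma2,
        alpha=np.zeros(m_total),
        beta_x1=total,
        beta_x2=cfg.beta_xy_direct,
        beta_xm=cfg.beta_xm,
        beta_my=cfg.beta_my,
        beta_xy_direct=cfg.beta_xy_direct,
        total_effect=total,
        pi_m_true=(cfg.beta_xm * cfg.beta_my) / total if total != 0 else None,
        binary_intercept=intercept,
    )
    return geno, cohort, truth
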