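"""Pleiotropy-robust multivariable MR by collider correction.

The procedure splits one-sample MVMR into two stages:

1. Fit the observational (confounded, hence "collider-biased") outcome
   model Y ~ X1..XK + covariates to get ``beta_obs``, and collect per-SNP
   summary associations: the *conditional* SNP-outcome association
   ``alpha*_j`` (coefficient of SNP j in Y ~ G_j + X1..XK + covariates) and
   the SNP-exposure associations ``gamma_kj``.
2. Regress ``alpha*`` on ``gamma`` with a summary-data estimator to obtain
   the correction ``Delta``; the causal effects are ``beta_obs + Delta``.

Because stage 2 works on summary associations, any pleiotropy-robust
summary estimator can be plugged in even though the data are one-sample.
The robust stage here minimises sum_j rho(t_j) over Delta where

    t_j = (alpha*_j - gamma_j . Delta) / s_j(Delta),
    s_j(Delta)^2 = se_alpha_j^2 + sum_k Delta_k^2 se_gamma_kj^2,

i.e. an adjusted-profile-score objective whose Delta-dependent scale makes
it consistent under weak instruments; rho is squared error (equivalent to
multi-exposure IVW when the gamma uncertainty is negligible), Huber
(k = 1.345) or Tukey biweight (c = 4.685), the latter two down-weighting
outlying (pleiotropic) SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._regression import FitError, add_intercept, logistic_irls, residualize, wls
from .containers import DataError, GenotypeMatrix, ParameterError

HUBER_K = 1.345
TUKEY_C = 4.685


# ---------------------------------------------------------------- losses


def _psi(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "squared":
        return t
    if loss == "huber":
        return np.clip(t, -HUBER_K, HUBER_K)
    if loss == "tukey":
        u = t / TUKEY_C
        out = t * (1.0 - u**2) ** 2
        out[np.abs(t) > TUKEY_C] = 0.0
        return out
    raise ParameterError(f"unknown loss '{loss}'")


def _rho(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "squared":
        return 0.5 * t**2
    if loss == "huber":
        a = np.abs(t)
        return np.where(a <= HUBER_K, 0.5 * t**2, HUBER_K * a - 0.5 * HUBER_K**2)
    if loss == "tukey":
        u = np.minimum(np.abs(t) / TUKEY_C, 1.0)
        return (TUKEY_C**2 / 6.0) * (1.0 - (1.0 - u**2) ** 3)
    raise ParameterError(f"unknown loss '{loss}'")


def _psi_prime(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "squared":
        return np.ones_like(t)
    if loss == "huber":
        return (np.abs(t) <= HUBER_K).astype(float)
    if loss == "tukey":
        u = t / TUKEY_C
        out = (1.0 - u**2) * (1.0 - 5.0 * u**2)
        out[np.abs(t) > TUKEY_C] = 0.0
        return out
    raise ParameterError(f"unknown loss '{loss}'")


def _loss_consistency_delta(loss: str) -> float:
    """E[psi(t) t] under t ~ N(0,1): Fisher-consistency factor for scale."""
    if loss == "squared":
        return 1.0
    grid = np.linspace(-8.0, 8.0, 4001)
    return float(np.trapezoid(_psi(grid, loss) * grid * stats.norm.pdf(grid), grid))


# ---------------------------------------------------- summary containers


@dataclass
class SummaryAssociations:
    """Per-SNP summary associations feeding the correction stage."""

    gamma: np.ndarray  # SNPs x exposures
    gamma_se: np.ndarray
    alpha: np.ndarray  # conditional SNP-outcome associations
    alpha_se: np.ndarray
    snp_ids: list[str] | None = None
    exposure_names: list[str] | None = None
    overlap_corr: float = 0.0

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if self.gamma.shape[0] == 1 and np.asarray(self.alpha).size > 1:
            self.gamma = self.gamma.T
        self.gamma_se = np.atleast_2d(np.asarray(self.gamma_se, dtype=float))
        if self.gamma_se.shape != self.gamma.shape:
            self.gamma_se = self.gamma_se.T
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.alpha_se = np.asarray(self.alpha_se, dtype=float)
        m, k = self.gamma.shape
        if self.alpha.shape != (m,) or self.alpha_se.shape != (m,):
            raise DataError("inconsistent dimensions in summary associations")
        if np.any(self.alpha_se <= 0) or np.any(self.gamma_se <= 0):
            raise DataError("standard errors must be positive")
        if self.exposure_names is None:
            self.exposure_names = [f"x{j+1}" for j in range(k)]

    @property
    def m(self) -> int:
        return self.gamma.shape[0]

    @property
    def k(self) -> int:
        return self.gamma.shape[1]


@dataclass
class RobustSummaryResult:
    delta: np.ndarray
    se: np.ndarray
    snp_weights: np.ndarray
    loss: str
    converged: bool
    objective: float
    exposure_names: list[str]


@dataclass
class ColliderCorrectionResult:
    """Corrected causal effects: beta = beta_obs + Delta (exact by construction)."""

    exposure_names: list[str]
    beta_obs: np.ndarray
    beta_obs_se: np.ndarray
    delta: np.ndarray
    delta_se: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    snp_weights: np.ndarray
    loss: str
    se_method: str
    outcome_type: str
    n: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> np.ndarray:
        return self.beta - 1.959963984540054 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.beta + 1.959963984540054 * self.se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposure_names,
                "beta_obs": self.beta_obs,
                "delta": self.delta,
                "beta": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


# ------------------------------------------------------- stage 1


def collider_conditional_associations(
    dosages,
    exposures: pd.DataFrame,
    outcome,
    covariates=None,
    outcome_type: str = "continuous",
):
    """Stage 1 of collider correction.

    Returns ``(SummaryAssociations, beta_obs, beta_obs_se)``.  ``alpha*_j``
    is the coefficient of SNP j in Y ~ G_j + X1..XK + covariates (one SNP at
    a time); ``gamma_kj`` comes from X_k ~ G_j + covariates.
    """
    G = dosages.values() if isinstance(dosages, GenotypeMatrix) else np.asarray(
        dosages, dtype=float
    )
    X = exposures.to_numpy(dtype=float) if isinstance(exposures, pd.DataFrame) else np.atleast_2d(
        np.asarray(exposures, dtype=float)
    )
    if X.shape[0] != G.shape[0]:
        X = X.T
    names = (
        list(exposures.columns)
        if isinstance(exposures, pd.DataFrame)
        else [f"x{j+1}" for j in range(X.shape[1])]
    )
    y = np.asarray(outcome, dtype=float)
    n, m = G.shape
    k = X.shape[1]
    if np.any(X.std(axis=0) == 0):
        raise FitError("zero-variance exposure column")
    C = add_intercept(
        None if covariates is None else np.asarray(covariates, dtype=float), n
    )
    c = C.shape[1]

    # SNP-exposure associations, vectorised (exposures are continuous)
    Gr = residualize(G, C)
    Xr = residualize(X, C)
    g2 = np.sum(Gr**2, axis=0)
    if np.any(g2 == 0):
        raise DataError("monomorphic SNP column")
    gamma = (Gr.T @ Xr) / g2[:, None]  # m x k
    rss_x = np.sum(Xr**2, axis=0)[None, :] - gamma**2 * g2[:, None]
    gamma_se = np.sqrt(rss_x / (n - c - 1)) / np.sqrt(g2)[:, None]

    if outcome_type == "continuous":
        beta_full, cov_full, _ = wls(np.hstack([C, X]), y)
        beta_obs = beta_full[-k:]
        beta_obs_se = np.sqrt(np.diag(cov_full)[-k:])
        # Frisch-Waugh: residualise SNPs on the observed exposures, then the
        # conditional SNP-outcome coefficient is a simple regression
        yr = residualize(y[:, None], C)[:, 0]
        Gt = residualize(Gr, add_intercept(Xr, n))
        yt = residualize(yr[:, None], add_intercept(Xr, n))[:, 0]
        gt2 = np.sum(Gt**2, axis=0)
        if np.any(gt2 == 0):
            raise DataError("SNP collinear with exposures")
        alpha = (Gt.T @ yt) / gt2
        rss_y = float(yt @ yt) - alpha**2 * gt2
        alpha_se = np.sqrt(rss_y / (n - c - k - 1)) / np.sqrt(gt2)
    elif outcome_type == "binary":
        D = np.hstack([C, X])
        beta_full, cov_full = logistic_irls(D, y)
        beta_obs = beta_full[-k:]
        beta_obs_se = np.sqrt(np.diag(cov_full)[-k:])
        alpha = np.empty(m)
        alpha_se = np.empty(m)
        for j in range(m):
            bj, cj = logistic_irls(np.hstack([D, G[:, [j]]]), y)
            alpha[j] = bj[-1]
            alpha_se[j] = np.sqrt(cj[-1, -1])
    else:
        raise ParameterError("outcome_type must be 'continuous' or 'binary'")

    assoc = SummaryAssociations(
        gamma=gamma,
        gamma_se=gamma_se,
        alpha=alpha,
        alpha_se=alpha_se,
        snp_ids=list(dosages.ids) if isinstance(dosages, GenotypeMatrix) else None,
        exposure_names=names,
    )
    return assoc, np.asarray(beta_obs, dtype=float), np.asarray(beta_obs_se, dtype=float)


# ------------------------------------------------------- stage 2


def _scales(assoc: SummaryAssociations, delta: np.ndarray, extra_var: float = 0.0):
    s2 = (
        assoc.alpha_se**2
        + (assoc.gamma_se**2) @ (delta**2)
        + extra_var
        - 2.0 * assoc.overlap_corr * (assoc.alpha_se[:, None] * assoc.gamma_se) @ delta
    )
    return np.sqrt(np.maximum(s2, 1e-300))


def _objective_and_grad(delta, assoc, loss, extra_var=0.0):
    r = assoc.alpha - assoc.gamma @ delta
    s = _scales(assoc, delta, extra_var)
    t = r / s
    obj = float(np.sum(_rho(t, loss)))
    psi = _psi(t, loss)
    # dt/ddelta_k = -gamma_jk / s_j - t_j * delta_k * se_gamma_jk^2 / s_j^2
    grad = -(assoc.gamma / s[:, None]).T @ psi - (
        (assoc.gamma_se**2 / s[:, None] ** 2).T @ (psi * t)
    ) * delta
    if assoc.overlap_corr != 0.0:
        grad += ((assoc.alpha_se[:, None] * assoc.gamma_se / s[:, None] ** 2).T @ (psi * t)) * (
            assoc.overlap_corr
        )
    return obj, grad


def _fixed_point(
    assoc: SummaryAssociations,
    start: np.ndarray,
    loss: str,
    extra_var: float,
    use_correction: bool,
    max_iter: int = 200,
    damping: float = 0.8,
    tol: float = 1e-12,
) -> np.ndarray:
    """Damped fixed-point solve of the (robust) summary-stage score.

    Given the previous iterate's weights the score is linear in Delta:
    Delta = (A - D)^{-1} b with A = sum m_j gamma_j gamma_j'/s_j^2,
    b = sum m_j gamma_j alpha_j/s_j^2 and, when ``use_correction`` is on,
    D = diag_k sum_j psi(t_j) t_j se_gamma_jk^2 / s_j^2 — the
    errors-in-variables term of the profile score that removes
    weak-instrument dilution.  Raises :class:`FitError` on divergence or
    non-convergence.
    """
    start = np.asarray(start, dtype=float)
    runaway = 100.0 * (1.0 + float(np.linalg.norm(start)))
    # the corrected score can have spurious far-away roots (the profile
    # objective flattens at large |Delta|); keep the solve local to the
    # warm start with a step cap and a locality guard at the end
    locality = 2.0 * (1.0 + float(np.linalg.norm(start)))
    delta = start.copy()
    for _ in range(max_iter):
        r = assoc.alpha - assoc.gamma @ delta
        s = _scales(assoc, delta, extra_var)
        t = r / s
        with np.errstate(invalid="ignore", divide="ignore"):
            mw = np.where(np.abs(t) > 1e-12, _psi(t, loss) / t, 1.0)
        w = mw / s**2
        A = (assoc.gamma * w[:, None]).T @ assoc.gamma
        if use_correction:
            A = A - np.diag(((assoc.gamma_se**2) * (mw * t**2 / s**2)[:, None]).sum(axis=0))
        b = (assoc.gamma * w[:, None]).T @ assoc.alpha
        try:
            new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular summary-stage score system") from exc
        if not np.all(np.isfinite(new)) or np.linalg.norm(new) > runaway:
            raise FitError("summary-stage fixed point diverged")
        step = new - delta
        cap = 0.5 * (1.0 + float(np.linalg.norm(delta)))
        norm = float(np.linalg.norm(step))
        if norm > cap:
            step = step * (cap / norm)
        delta = delta + damping * step
        if float(np.max(np.abs(step))) < tol:
            if use_correction and float(np.linalg.norm(delta - start)) > locality:
                raise FitError("corrected summary-stage score left the local basin")
            return delta
    raise FitError("summary-stage fixed point did not converge")


def _ivw_start(assoc: SummaryAssociations) -> np.ndarray:
    w = 1.0 / assoc.alpha_se**2
    Gw = assoc.gamma * w[:, None]
    A = assoc.gamma.T @ Gw
    b = Gw.T @ assoc.alpha
    return np.linalg.solve(A, b)


def robust_summary_mvmr(
    assoc: SummaryAssociations,
    loss: str = "tukey",
    max_iter: int = 200,
    extra_var: float = 0.0,
) -> RobustSummaryResult:
    """Estimate the correction Delta from summary associations.

    Minimises the adjusted-profile-score objective described in the module
    docstring.  Squared loss with negligible gamma uncertainty reproduces
    multi-exposure IVW exactly; Huber/Tukey losses down-weight outlying
    SNPs (per-SNP weights psi(t)/t in [0, 1] are returned).  Standard
    errors come from a sandwich formula with the scale fixed at the
    solution.
    """
    if assoc.m <= assoc.k:
        raise ParameterError(
            "robust summary stage needs more SNPs than exposures (over-identification)"
        )
    start = _ivw_start(assoc)
    # The stationarity condition of the profile objective,
    #   sum_j psi(t_j) [gamma_jk / s_j + t_j Delta_k se_gamma_jk^2 / s_j^2] = 0,
    # is solved by a damped fixed point that is linear in Delta given the
    # previous iterate's weights: Delta = (A - D)^{-1} b with
    #   A = sum m_j gamma_j gamma_j'/s_j^2,  b = sum m_j gamma_j alpha_j/s_j^2,
    #   D = diag_k sum m_j t_j^2 se_gamma_jk^2 / s_j^2,  m_j = psi(t_j)/t_j.
    # The -D term is the errors-in-variables correction that removes
    # weak-instrument dilution; solving the score locally (rather than
    # descending on the objective) avoids the spurious flat minimum the
    # profile objective develops at large |Delta|, where the Delta-dependent
    # scale saturates every residual.  Non-convex losses are warm-started
    # progressively: squared -> huber -> tukey.
    chain = {"squared": ["squared"], "huber": ["squared", "huber"], "tukey": ["squared", "huber", "tukey"]}
    if loss not in chain:
        raise ParameterError(f"unknown loss '{loss}'")
    # Phase A: the uncorrected reweighted-IVW chain is stable under gross
    # contamination; it settles the outlier weights at the price of some
    # weak-instrument dilution.  Phase B then applies the
    # errors-in-variables correction for the target loss from that point,
    # where the corrected score is well behaved; if it still leaves the
    # local basin the uncorrected (diluted) solution is kept and flagged.
    delta = start.copy()
    for step_loss in chain[loss]:
        delta = _fixed_point(
            assoc, delta, step_loss, extra_var, use_correction=False, max_iter=max_iter
        )
    try:
        delta = _fixed_point(
            assoc, delta, loss, extra_var, use_correction=True, max_iter=max_iter
        )
        corrected = True
    except FitError:
        corrected = False
    converged = True
    res_obj = _objective_and_grad(delta, assoc, loss, extra_var)[0]
    r = assoc.alpha - assoc.gamma @ delta
    s = _scales(assoc, delta, extra_var)
    t = r / s
    psi = _psi(t, loss)
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(np.abs(t) > 1e-12, psi / t, 1.0)
    x = assoc.gamma / s[:, None]
    dpsi = _psi_prime(t, loss)
    A = (x * dpsi[:, None]).T @ x
    B = (x * psi[:, None] ** 2).T @ x
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular sandwich bread matrix in robust summary stage") from exc
    V = Ainv @ B @ Ainv
    return RobustSummaryResult(
        delta=delta,
        se=np.sqrt(np.diag(V)),
        snp_weights=weights,
        loss=loss,
        converged=converged,
        objective=res_obj,
        exposure_names=list(assoc.exposure_names),
    )


def collider_correction_mvmr(
    dosages,
    exposures: pd.DataFrame,
    outcome,
    covariates=None,
    outcome_type: str = "continuous",
    loss: str = "tukey",
    se_method: str = "analytic",
    boot_reps: int = 200,
    seed: int | None = None,
) -> ColliderCorrectionResult:
    """Full multivariable collider correction: stage 1 + robust stage 2.

    ``se_method='analytic'`` combines the observational and summary-stage
    variances (treating the stages as independent); ``'bootstrap'``
    resamples individuals and re-runs both stages.
    """
    from .instruments import conditional_f

    assoc, beta_obs, beta_obs_se = collider_conditional_associations(
        dosages, exposures, outcome, covariates, outcome_type
    )
    stage2 = robust_summary_mvmr(assoc, loss=loss)
    beta = beta_obs + stage2.delta
    diagnostics: dict = {}
    if assoc.k >= 2:
        X = exposures if isinstance(exposures, pd.DataFrame) else pd.DataFrame(np.asarray(exposures))
        try:
            diagnostics["conditional_f"] = conditional_f(dosages, X, covariates)
        except (FitError, ParameterError):  # diagnostics never block estimation
            pass
    if se_method == "analytic":
        se = np.sqrt(beta_obs_se**2 + stage2.se**2)
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        G = dosages.values() if isinstance(dosages, GenotypeMatrix) else np.asarray(
            dosages, dtype=float
        )
        Xm = exposures.to_numpy(dtype=float) if isinstance(exposures, pd.DataFrame) else np.asarray(
            exposures, dtype=float
        )
        y = np.asarray(outcome, dtype=float)
        Cm = None if covariates is None else np.asarray(covariates, dtype=float)
        draws = []
        names = list(assoc.exposure_names)
        for _ in range(boot_reps):
            idx = rng.integers(0, G.shape[0], size=G.shape[0])
            try:
                a, b_obs, _ = collider_conditional_associations(
                    G[idx],
                    pd.DataFrame(Xm[idx], columns=names),
                    y[idx],
                    None if Cm is None else Cm[idx],
                    outcome_type,
                )
                draws.append(b_obs + robust_summary_mvmr(a, loss=loss).delta)
            except (FitError, DataError):
                continue
        if len(draws) < boot_reps // 2:
            raise FitError("bootstrap SE failed: too many failed refits")
        se = np.std(np.asarray(draws), axis=0, ddof=1)
        diagnostics["bootstrap_draws"] = len(draws)
    else:
        raise ParameterError("se_method must be 'analytic' or 'bootstrap'")
    return ColliderCorrectionResult(
        exposure_names=list(assoc.exposure_names),
        beta_obs=beta_obs,
        beta_obs_se=beta_obs_se,
        delta=stage2.delta,
        delta_se=stage2.se,
        beta=beta,
        se=se,
        snp_weights=stage2.snp_weights,
        loss=loss,
        se_method=se_method,
        outcome_type=outcome_type,
        n=int(np.asarray(outcome).shape[0]),
        diagnostics=diagnostics,
    )


# ------------------------------------------------------- univariable RAPS


def ivw_uv(beta_exposure, se_exposure, beta_outcome, se_outcome):
    """Plain univariable inverse-variance-weighted estimate (fixed effect)."""
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    w = bx**2 / sy**2
    est = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return est, se


def mr_raps_uv(
    beta_exposure,
    se_exposure,
    beta_outcome,
    se_outcome,
    loss: str = "huber",
    max_outer: int = 30,
):
    """Weak-instrument-robust univariable summary MR (adjusted profile score).

    Estimates the causal effect by minimising the profile objective with an
    additive overdispersion variance tau^2 >= 0 for systematic (balanced)
    pleiotropy; tau^2 is updated by moment-matching the (robustly weighted)
    standardised residuals, truncated at zero.  Returns
    ``(estimate, se, tau2)``.
    """
    bx = np.asarray(beta_exposure, dtype=float)
    sx = np.asarray(se_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    m = bx.shape[0]
    if m < 3:
        raise ParameterError("mr_raps needs at least 3 SNPs")
    assoc = SummaryAssociations(
        gamma=bx[:, None], gamma_se=sx[:, None], alpha=by, alpha_se=sy
    )
    delta_consist = _loss_consistency_delta(loss)
    tau2 = 0.0
    est = np.array([_ivw_start(assoc)[0]])
    for _ in range(max_outer):
        fit = robust_summary_mvmr(assoc, loss=loss, extra_var=tau2)
        new_est = fit.delta
        # moment update for tau^2: E[psi(t) t] = delta_consist under the model
        def moment_gap(t2: float) -> float:
            s = np.sqrt(sy**2 + new_est[0] ** 2 * sx**2 + t2)
            t = (by - bx * new_est[0]) / s
            return float(np.sum(_psi(t, loss) * t) - delta_consist * (m - 1))

        if moment_gap(0.0) <= 0.0:
            new_tau2 = 0.0
        else:
            hi = float(np.var(by) + 1.0)
            while moment_gap(hi) > 0.0 and hi < 1e6:
                hi *= 4.0
            new_tau2 = optimize.brentq(moment_gap, 0.0, hi, xtol=1e-12)
        if abs(new_tau2 - tau2) < 1e-12 and abs(new_est[0] - est[0]) < 1e-12:
            est, tau2 = new_est, new_tau2
            break
        est, tau2 = new_est, new_tau2
    final = robust_summary_mvmr(assoc, loss=loss, extra_var=tau2)
    return float(final.delta[0]), float(final.se[0]), float(tau2)
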