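"""Individual-level one-sample MR estimators.

Observational baseline regressions, univariable and multivariable two-stage
least squares (with a logistic second stage for binary outcomes, i.e.
two-stage predictor substitution), the Sargan over-identification test, and
principal-component MR for dense correlated cis instruments.

Continuous-outcome TSLS uses proper instrumental-variable standard errors
(residuals taken from the observed, not predicted, exposures).  Binary
second stages report the logistic fit's standard errors without first-stage
propagation, the standard two-stage-predictor-substitution practice; a
bootstrap SE mode is available on the estimators that need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import FitError, add_intercept, logistic_irls, residualize, wls
from .containers import DataError, GenotypeMatrix, ParameterError


@dataclass
class MREstimate:
    """A per-exposure causal-effect estimate with diagnostics.

    Effects are per 1 SD of exposure; on the log-odds scale for binary
    outcomes.
    """

    method: str
    exposures: list[str]
    beta: np.ndarray
    se: np.ndarray
    n: int
    outcome_type: str = "continuous"
    ci_level: float = 0.95
    diagnostics: dict = field(default_factory=dict)
    heterogeneity: dict | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.se = np.atleast_1d(np.asarray(self.se, dtype=float))
        z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        self.ci_low = self.beta - z * self.se
        self.ci_high = self.beta + z * self.se
        self.p = 2.0 * stats.norm.sf(np.abs(self.beta) / np.where(self.se > 0, self.se, np.inf))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "exposure": self.exposures,
                "beta": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
                "n": self.n,
                "outcome_type": self.outcome_type,
            }
        )


def _as_matrix(data, n=None) -> np.ndarray:
    if isinstance(data, GenotypeMatrix):
        return data.values()
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _cov_matrix(covariates, n: int) -> np.ndarray:
    return add_intercept(
        None if covariates is None else np.asarray(covariates, dtype=float), n
    )


def observational_association(
    exposure,
    outcome,
    covariates=None,
    outcome_type: str = "continuous",
    exposure_names: list[str] | None = None,
) -> MREstimate:
    """Covariate-adjusted regression of the outcome on observed exposure(s):
    the confounded baseline the MR analyses are compared against."""
    X = _as_matrix(exposure)
    y = np.asarray(outcome, dtype=float)
    n = X.shape[0]
    names = exposure_names or [f"x{k+1}" for k in range(X.shape[1])]
    C = _cov_matrix(covariates, n)
    D = np.hstack([C, X])
    k = X.shape[1]
    if outcome_type == "binary":
        beta, cov = logistic_irls(D, y)
    elif outcome_type == "continuous":
        beta, cov, _ = wls(D, y)
    else:
        raise ParameterError("outcome_type must be 'continuous' or 'binary'")
    return MREstimate(
        method="observational",
        exposures=names,
        beta=beta[-k:],
        se=np.sqrt(np.diag(cov)[-k:]),
        n=n,
        outcome_type=outcome_type,
    )


def _tsls_core(
    G: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    outcome_type: str,
    weights: np.ndarray | None = None,
):
    """Weighted TSLS / two-stage predictor substitution on prepared matrices.

    Returns ``(beta, se)`` for the exposure block only.  Continuous outcomes
    get IV standard errors (sigma^2 from observed-exposure residuals).
    """
    n, k = X.shape
    Z = np.hstack([C, G])
    if weights is None:
        w = None
        sw = None
    else:
        w = np.asarray(weights, dtype=float)
        sw = np.sqrt(w)
    # first stage: predict each exposure from all instruments + covariates
    if w is None:
        coef, _, _, _ = np.linalg.lstsq(Z, X, rcond=None)
    else:
        Zw = Z * sw[:, None]
        coef, _, _, _ = np.linalg.lstsq(Zw, X * sw[:, None], rcond=None)
    Xhat = Z @ coef
    D_hat = np.hstack([C, Xhat])
    if outcome_type == "binary":
        beta, cov = logistic_irls(D_hat, y, w)
        return beta[-k:], np.sqrt(np.diag(cov)[-k:])
    # linear IV: point estimate from the second-stage projection, residual
    # variance from the observed exposures
    if w is None:
        DtD = D_hat.T @ D_hat
        Dty = D_hat.T @ y
    else:
        Dw = D_hat * w[:, None]
        DtD = D_hat.T @ Dw
        Dty = Dw.T @ y
    try:
        beta = np.linalg.solve(DtD, Dty)
    except np.linalg.LinAlgError as exc:
        raise FitError("rank-deficient second-stage design") from exc
    D_obs = np.hstack([C, X])
    resid = y - D_obs @ beta
    if w is None:
        rss = float(resid @ resid)
    else:
        rss = float(resid @ (w * resid))
    sigma2 = rss / (n - D_obs.shape[1])
    cov = sigma2 * np.linalg.inv(DtD)
    return beta[-k:], np.sqrt(np.diag(cov)[-k:])


def tsls_uvmr(
    instruments,
    exposure,
    outcome,
    covariates=None,
    outcome_type: str = "continuous",
    weights=None,
    exposure_name: str = "x",
    diagnostics: bool = True,
) -> MREstimate:
    """Univariable TSLS MR: total causal effect of one exposure.

    ``instruments`` may be a dosage matrix/GenotypeMatrix or a single
    genetic risk score column.  With a single instrument the estimate
    equals the Wald ratio cov(G, Y)/cov(G, X).
    """
    from .instruments import mean_f_statistic

    G = _as_matrix(instruments)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = G.shape[0]
    C = _cov_matrix(covariates, n)
    if np.any(G.std(axis=0) == 0):
        raise FitError("degenerate (zero-variance) instrument column")
    beta, se = _tsls_core(G, x[:, None], y, C, outcome_type, weights)
    diag = {}
    het = None
    if diagnostics and weights is None:
        diag = mean_f_statistic(G, x, covariates)
        diag.pop("per_instrument_f", None)
        if G.shape[1] > 1 and outcome_type == "continuous":
            het = sargan_test(G, x[:, None], y, covariates)
    return MREstimate(
        method="tsls_uvmr",
        exposures=[exposure_name],
        beta=beta,
        se=se,
        n=n,
        outcome_type=outcome_type,
        diagnostics=diag,
        heterogeneity=het,
    )


def tsls_mvmr(
    instruments,
    exposures: pd.DataFrame,
    outcome,
    covariates=None,
    outcome_type: str = "continuous",
    weights=None,
    diagnostics: bool = True,
) -> MREstimate:
    """Multivariable TSLS MR: direct effects of jointly instrumented exposures.

    All exposures are predicted from the full instrument set in the first
    stage; the second stage regresses the outcome on all predictions
    jointly.  Conditional F statistics are attached as diagnostics.
    """
    from .instruments import conditional_f

    G = _as_matrix(instruments)
    X = exposures.to_numpy(dtype=float) if isinstance(exposures, pd.DataFrame) else _as_matrix(
        exposures
    )
    names = (
        list(exposures.columns)
        if isinstance(exposures, pd.DataFrame)
        else [f"x{k+1}" for k in range(X.shape[1])]
    )
    y = np.asarray(outcome, dtype=float)
    n, k = X.shape
    if G.shape[1] < k:
        raise ParameterError("need at least as many instruments as exposures")
    C = _cov_matrix(covariates, n)
    beta, se = _tsls_core(G, X, y, C, outcome_type, weights)
    diag = {}
    het = None
    if diagnostics and weights is None and k >= 2:
        diag["conditional_f"] = conditional_f(G, pd.DataFrame(X, columns=names), covariates)
        if G.shape[1] > k and outcome_type == "continuous":
            het = sargan_test(G, X, y, covariates)
    return MREstimate(
        method="tsls_mvmr",
        exposures=names,
        beta=beta,
        se=se,
        n=n,
        outcome_type=outcome_type,
        diagnostics=diag,
        heterogeneity=het,
    )


def sargan_test(instruments, exposures, outcome, covariates=None) -> dict:
    """Sargan over-identification test for a (continuous-outcome) TSLS fit.

    n R^2 from regressing the TSLS residuals on the instruments
    (covariate-adjusted), against chi^2 with (#instruments - #exposures)
    degrees of freedom.  Requires over-identification.
    """
    G = _as_matrix(instruments)
    X = _as_matrix(exposures)
    y = np.asarray(outcome, dtype=float)
    n, k = X.shape
    m = G.shape[1]
    if m <= k:
        raise ParameterError("Sargan test undefined for a just-identified model")
    C = _cov_matrix(covariates, n)
    beta, _ = _tsls_core(G, X, y, C, "continuous", None)
    # residuals from observed exposures at the IV estimate (covariate part refit)
    Xr = residualize(X, C)
    yr = residualize(y[:, None], C)[:, 0]
    u = yr - Xr @ beta
    Gr = residualize(G, C)
    bu, _, _, _ = np.linalg.lstsq(Gr, u, rcond=None)
    fitted = Gr @ bu
    ss_tot = float(u @ u)
    r2 = float(fitted @ fitted) / ss_tot if ss_tot > 0 else 0.0
    statistic = n * r2
    df = m - k
    return {"statistic": float(statistic), "df": int(df), "p": float(stats.chi2.sf(statistic, df))}


@dataclass
class CisSummary:
    """Summary inputs for principal-component MR on a dense cis region."""

    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    ld: np.ndarray
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        self.ld = np.asarray(self.ld, dtype=float)
        m = self.beta_exposure.shape[0]
        if not (
            self.se_exposure.shape[0] == self.beta_outcome.shape[0] == self.se_outcome.shape[0] == m
            and self.ld.shape == (m, m)
        ):
            raise DataError("inconsistent dimensions in cis summary data")
        if not np.allclose(self.ld, self.ld.T, atol=1e-8) or not np.allclose(
            np.diag(self.ld), 1.0, atol=1e-6
        ):
            raise DataError("LD matrix must be symmetric with unit diagonal")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise DataError("standard errors must be positive")


def cis_pc_mr(
    summary: CisSummary,
    k: int | None = None,
    var_threshold: float = 0.99,
    ridge: float = 1e-6,
) -> MREstimate:
    """MR over the principal components of a dense correlated cis region.

    The weighted LD matrix psi_ij = bx_i bx_j R_ij / (sy_i sy_j) is
    eigen-decomposed; SNP-exposure and SNP-outcome association vectors are
    projected onto the top-k components and combined by inverse-variance
    weighting with the correlation-adjusted outcome covariance.  ``k=None``
    retains components explaining ``var_threshold`` of the variance.
    """
    bx, sx = summary.beta_exposure, summary.se_exposure
    by, sy = summary.beta_outcome, summary.se_outcome
    R = summary.ld + ridge * np.eye(summary.ld.shape[0])
    m = bx.shape[0]
    psi = np.outer(bx, bx) * R / np.outer(sy, sy)
    evals, evecs = np.linalg.eigh(psi)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = float(evals.sum())
    if k is None:
        if total <= 0:
            raise DataError("weighted LD matrix has no variance to decompose")
        cum = np.cumsum(evals) / total
        k = int(np.searchsorted(cum, var_threshold) + 1)
    if k < 1:
        raise ParameterError("k must be >= 1")
    rank = int(np.sum(evals > max(1e-12 * evals[0], 0.0))) if evals.size else 0
    if k > rank:
        raise ParameterError(f"k={k} exceeds numerical rank {rank} of the weighted LD matrix")
    V = evecs[:, :k]
    bx_p = V.T @ bx
    by_p = V.T @ by
    Sigma = np.outer(sy, sy) * R
    Om = V.T @ Sigma @ V
    Om_inv = np.linalg.inv(Om)
    denom = float(bx_p @ Om_inv @ bx_p)
    if denom <= 0:
        raise FitError("degenerate projected exposure associations")
    beta = float(bx_p @ Om_inv @ by_p) / denom
    se = 1.0 / np.sqrt(denom)
    return MREstimate(
        method="cis_pc_mr",
        exposures=["exposure"],
        beta=np.array([beta]),
        se=np.array([se]),
        n=m,
        outcome_type="continuous",
        diagnostics={"k": k, "m_snps": m, "eigenvalue_share": float(evals[:k].sum() / total)},
    )
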