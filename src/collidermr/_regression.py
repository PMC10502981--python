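"""Light-weight weighted regression kernels.

These are the inner-loop primitives shared by the estimators and the
bootstrap machinery.  They use plain numpy linear algebra so that a
mediation bootstrap (hundreds of replicates x hundreds of weight draws)
stays cheap; the one-off model fits elsewhere in the package go through
statsmodels, and the unit tests check these kernels against statsmodels.
"""

from __future__ import annotations

import numpy as np


class FitError(RuntimeError):
    """A regression fit failed (rank deficiency, separation, non-convergence)."""


def add_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    """Column-stack an intercept onto ``X`` (or return a lone intercept)."""
    one = np.ones((n, 1))
    if X is None or X.size == 0:
        return one
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    return np.hstack([one, X])


def wls(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    """Weighted least squares.

    Returns ``(beta, cov, resid)`` with the classical covariance
    ``sigma^2 (X'WX)^{-1}`` where ``sigma^2`` uses the weighted residual
    sum of squares and ``n - p`` degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise FitError(f"not enough observations ({n}) for {p} parameters")
    if w is None:
        XtX = X.T @ X
        Xty = X.T @ y
    else:
        w = np.asarray(w, dtype=float)
        Xw = X * w[:, None]
        XtX = X.T @ Xw
        Xty = Xw.T @ y
    try:
        beta = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise FitError("rank-deficient design matrix") from exc
    resid = y - X @ beta
    if w is None:
        rss = float(resid @ resid)
    else:
        rss = float(resid @ (w * resid))
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtX)
    return beta, cov, resid


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
):
    """Weighted logistic regression by iteratively reweighted least squares.

    ``w`` are observation weights (e.g. Bayesian-bootstrap Dirichlet draws);
    the score equations match statsmodels GLM Binomial with ``var_weights``.
    Returns ``(beta, cov)``; raises :class:`FitError` on non-convergence or
    (quasi-)separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if w is None:
        w = np.ones(n)
    else:
        w = np.asarray(w, dtype=float)
    beta = np.zeros(p)
    # start the intercept at the weighted logit of the mean outcome
    ybar = min(max(float(np.average(y, weights=w)), 1e-10), 1 - 1e-10)
    beta[0] = np.log(ybar / (1.0 - ybar))
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = mu * (1.0 - mu)
        wv = w * v
        if not np.all(np.isfinite(wv)) or wv.max() < 1e-12:
            raise FitError("logistic IRLS degenerate working weights")
        Xw = X * wv[:, None]
        H = X.T @ Xw
        g = X.T @ (w * (y - mu))
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix in logistic fit") from exc
        beta = beta + step
        if float(np.max(np.abs(step))) < tol:
            break
    else:
        raise FitError("logistic IRLS did not converge")
    if np.max(np.abs(beta[1:] if p > 1 else beta)) > 1e3:
        raise FitError("logistic fit diverged (possible separation)")
    cov = np.linalg.inv(H)
    return beta, cov


def residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``M`` after OLS projection on ``C``."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != C.shape[0]:
        M = M.T
    coef, _, _, _ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef
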