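"""Effect moderation: stratified MR, sex heterogeneity, age meta-regression.

Causal estimates are computed separately within strata (e.g. males/females,
or 5-year age bins), pairwise heterogeneity is tested with Fisher's z, and
trends across ordered strata are assessed by fixed-effect (inverse-variance
weighted) meta-regression of the stratum estimates on the (centred) stratum
moderator value, optionally with a centred quadratic term.  Q statistics
are weighted residual sums of squares; the model-comparison statistic
Q_diff = Q(reduced) - Q(full) is chi-squared with one degree of freedom per
added term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import FitError
from .containers import ParameterError
from .estimators import MREstimate


@dataclass
class StratumEstimate:
    """An MR estimate inside one stratum of a moderator."""

    label: str
    moderator_value: float
    n: int
    estimate: MREstimate | None
    error: str | None = None


@dataclass
class MetaRegressionResult:
    """IVW meta-regression of stratum effects on a moderator."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    q_full: float
    df_full: int
    p_full: float
    q_reduced: float
    q_diff: float
    df_diff: int
    p_diff: float

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        z = np.where(self.se > 0, self.coef / self.se, np.inf)
        self.p_terms = 2.0 * stats.norm.sf(np.abs(z))


def stratified_estimates(
    cohort: pd.DataFrame,
    by: str,
    estimator,
    cutpoints: list[float] | None = None,
    moderator_values: dict | None = None,
) -> list[StratumEstimate]:
    """Run an MR estimator within each stratum of ``cohort[by]``.

    With ``cutpoints`` the stratifying variable is binned into
    [c0, c1), [c1, c2), ...; without, each distinct value forms a stratum.
    ``estimator`` is called as ``estimator(index)`` with the stratum's
    positional row indices and must return an :class:`MREstimate`; a
    failing stratum is recorded with its error and the rest proceed.
    """
    v = cohort[by].to_numpy()
    strata: list[tuple[str, float, np.ndarray]] = []
    if cutpoints is not None:
        edges = list(cutpoints)
        if len(edges) < 2:
            raise ParameterError("need at least two cutpoints to form bins")
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (v >= lo) & (v < hi)
            strata.append((f"[{lo:g},{hi:g})", (lo + hi) / 2.0, np.flatnonzero(mask)))
    else:
        for val in np.unique(v):
            mask = v == val
            strata.append((str(val), float(val), np.flatnonzero(mask)))
    out: list[StratumEstimate] = []
    for label, midpoint, idx in strata:
        if idx.size == 0:
            out.append(StratumEstimate(label, midpoint, 0, None, "empty stratum"))
            continue
        try:
            est = estimator(idx)
            out.append(StratumEstimate(label, midpoint, idx.size, est))
        except (FitError, ParameterError, np.linalg.LinAlgError) as exc:
            out.append(StratumEstimate(label, midpoint, idx.size, None, str(exc)))
    return out


def fisher_z_heterogeneity(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Two-group heterogeneity test: z = (b1 - b2)/sqrt(se1^2 + se2^2)."""
    if se1 <= 0 or se2 <= 0:
        raise ParameterError("standard errors must be positive")
    z = (b1 - b2) / np.hypot(se1, se2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def meta_regression(
    betas,
    ses,
    moderator,
    quadratic: bool = False,
) -> MetaRegressionResult:
    """Fixed-effect meta-regression of stratum estimates on a moderator.

    Weighted least squares with weights 1/se^2 on the centred moderator
    (plus its centred square if ``quadratic``).  Q statistics: weighted RSS
    of the full model (chi^2, df = k - p) and of the intercept-only model;
    their difference tests whether the moderator improves fit.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    x = np.asarray(moderator, dtype=float)
    k = b.shape[0]
    if np.any(s <= 0):
        raise ParameterError("standard errors must be positive")
    n_par = 3 if quadratic else 2
    if k < n_par + 1:
        raise ParameterError(
            f"need at least {n_par + 1} strata for {'a quadratic' if quadratic else 'a linear'} "
            "meta-regression"
        )
    w = 1.0 / s**2
    xc = x - np.average(x, weights=w)
    cols = [np.ones(k), xc]
    terms = ["intercept", "moderator"]
    if quadratic:
        x2 = xc**2
        cols.append(x2 - np.average(x2, weights=w))
        terms.append("moderator^2")
    X = np.column_stack(cols)
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ b)
    resid = b - X @ coef
    q_full = float(np.sum(w * resid**2))
    cov = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    mu = np.average(b, weights=w)
    q_red = float(np.sum(w * (b - mu) ** 2))
    df_full = k - X.shape[1]
    df_diff = X.shape[1] - 1
    q_diff = q_red - q_full
    return MetaRegressionResult(
        terms=terms,
        coef=coef,
        se=se,
        q_full=q_full,
        df_full=df_full,
        p_full=float(stats.chi2.sf(q_full, df_full)) if df_full > 0 else float("nan"),
        q_reduced=q_red,
        q_diff=q_diff,
        df_diff=df_diff,
        p_diff=float(stats.chi2.sf(max(q_diff, 0.0), df_diff)),
    )


def meta_regression_from_strata(
    strata: list[StratumEstimate], exposure_index: int = 0, quadratic: bool = False
) -> MetaRegressionResult:
    """Convenience wrapper pulling effect/SE/moderator out of stratum records."""
    ok = [s for s in strata if s.estimate is not None]
    if len(ok) < 3:
        raise ParameterError("need at least 3 successful strata")
    return meta_regression(
        [s.estimate.beta[exposure_index] for s in ok],
        [s.estimate.se[exposure_index] for s in ok],
        [s.moderator_value for s in ok],
        quadratic=quadratic,
    )
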