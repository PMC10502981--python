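"""Difference-method MR mediation with bootstrap uncertainty.

The total effect of an exposure X on an outcome Y comes from univariable
MR, the direct effect from multivariable MR that also genetically proxies
the mediator M, and the indirect effect is their difference.  The mediated
proportion pi_m = (total - direct) / total is interpretable as a proportion
when the indirect and total effects share a sign.

Uncertainty in pi_m comes from re-estimating all stages under bootstrap
weights: either the classical non-parametric bootstrap (multinomial
resampling expressed as integer weights / n) or Rubin's Bayesian bootstrap,
where every draw reweights the complete data by a flat Dirichlet(1,...,1)
vector.  Because every Bayesian-bootstrap draw keeps all observations with
strictly positive weight, sparse binary outcomes never lose their few cases
to resampling, which is where the Bayesian variant earns its keep.

Summaries follow the median / (2.5th, 97.5th) percentile rule applied to
the distribution of per-draw estimates; pi_m is computed per draw (a ratio
per draw, not a ratio of medians) and is not truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._regression import FitError, add_intercept, logistic_irls
from .containers import GenotypeMatrix, ParameterError


class MediationError(RuntimeError):
    """The bootstrap failed too often to summarise (see diagnostics)."""


@dataclass
class MediationResult:
    """Mediation decomposition with bootstrap summaries.

    ``beta_*`` are full-data point estimates; ``pi_m`` is the median of the
    per-draw mediated proportions with its percentile CI.  The identity
    indirect = total - direct holds exactly, per draw and at the point.
    """

    exposure: str
    beta_total: float
    beta_direct: float
    beta_indirect: float
    pi_m: float
    pi_ci: tuple[float, float]
    method: str
    n_draws: int
    n_failed: int
    sign_consistent: bool
    draws: pd.DataFrame | None = None
    ci_level: float = 0.95


def pi_m(beta_total: float, beta_direct: float) -> tuple[float, bool]:
    """Mediated proportion (total - direct)/total and its sign-consistency flag.

    The flag is True when the indirect and total effects share a sign (the
    only regime where the ratio reads as a proportion).
    """
    if beta_total == 0:
        raise ParameterError("mediated proportion undefined when the total effect is 0")
    indirect = beta_total - beta_direct
    return indirect / beta_total, bool(indirect * beta_total >= 0)


def draw_np_bootstrap(n: int, B: int, seed: int) -> np.ndarray:
    """Non-parametric bootstrap weights: multinomial counts / n, shape (B, n)."""
    if B < 1:
        raise ParameterError("B must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, np.full(n, 1.0 / n), size=B) / n


def draw_bayesian_bootstrap(n: int, B: int, seed: int) -> np.ndarray:
    """Bayesian bootstrap weights: flat Dirichlet(1,...,1) draws, shape (B, n).

    Implemented as normalised unit-rate exponentials; every weight is
    strictly positive, so each draw uses the complete data.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    rng = np.random.default_rng(seed)
    e = rng.standard_exponential(size=(B, n))
    return e / e.sum(axis=1, keepdims=True)


def _instrument_block(instruments, n: int) -> np.ndarray:
    if isinstance(instruments, GenotypeMatrix):
        arr = instruments.values()
    else:
        arr = np.asarray(instruments, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n:
        raise ParameterError("instrument rows do not match cohort size")
    if np.any(arr.std(axis=0) == 0):
        raise FitError("degenerate (zero-variance) instrument column")
    return arr


class MediationEngine:
    """Weighted TSLS mediation fits from sufficient statistics.

    Stacks [covariates | instruments | exposures | outcome] once; every
    weighted refit then reduces to one weighted cross-product matrix plus
    small solves, which keeps the bootstrap loop cheap.  Totals come from
    univariable TSLS per exposure (each exposure's own instruments), the
    direct effects from one joint MVMR on all exposures with the pooled
    instrument set.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        instrument_blocks: dict[str, np.ndarray],
        exposure_cols: list[str],
        y: str,
        covariates: list[str] | None = None,
        outcome_type: str = "continuous",
    ) -> None:
        n = len(cohort)
        self.outcome_type = outcome_type
        self.exposures = exposure_cols
        C = add_intercept(
            None if not covariates else cohort[covariates].to_numpy(dtype=float), n
        )
        blocks = [_instrument_block(instrument_blocks[e], n) for e in exposure_cols]
        X = cohort[exposure_cols].to_numpy(dtype=float)
        yv = np.asarray(cohort[y], dtype=float)
        self.n = n
        self.c = C.shape[1]
        self.F = np.hstack([C] + blocks + [X, yv[:, None]])
        p = self.F.shape[1]
        sizes = [b.shape[1] for b in blocks]
        self.g_slices = []
        off = self.c
        for s in sizes:
            self.g_slices.append(np.arange(off, off + s))
            off += s
        self.x_idx = np.arange(off, off + len(exposure_cols))
        self.y_idx = p - 1
        self.c_idx = np.arange(self.c)
        self.yv = yv
        self._C = C

    def _moments(self, w: np.ndarray | None) -> np.ndarray:
        if w is None:
            return self.F.T @ self.F
        return (self.F * w[:, None]).T @ self.F

    def _stage1(self, M: np.ndarray, z_idx: np.ndarray, x_idx: np.ndarray) -> np.ndarray:
        return np.linalg.solve(M[np.ix_(z_idx, z_idx)], M[np.ix_(z_idx, x_idx)])

    def _second_stage_linear(self, M, z_idx, coef, k):
        # regress y on [C, Zhat] using cross-moments only
        cz = np.ix_(self.c_idx, z_idx)
        Mcz = M[cz] @ coef  # C' Zhat  (c x k)
        Mzz = coef.T @ M[np.ix_(z_idx, z_idx)] @ coef  # Zhat'Zhat
        Mcy = M[self.c_idx, self.y_idx]
        Mzy = coef.T @ M[z_idx, self.y_idx]
        A = np.block([[M[np.ix_(self.c_idx, self.c_idx)], Mcz], [Mcz.T, Mzz]])
        b = np.concatenate([Mcy, Mzy])
        beta = np.linalg.solve(A, b)
        return beta[-k:]

    def _second_stage_logistic(self, z_idx, coef, w, k):
        Z = self.F[:, z_idx]
        Xhat = Z @ coef
        beta, _ = logistic_irls(np.hstack([self._C, Xhat]), self.yv, w)
        return beta[-k:]

    def fit(self, w: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Weighted totals (per exposure, UVMR) and directs (joint MVMR)."""
        M = self._moments(w)
        k = len(self.exposures)
        totals = np.empty(k)
        for j in range(k):
            z_idx = np.concatenate([self.c_idx, self.g_slices[j]])
            coef = self._stage1(M, z_idx, self.x_idx[[j]])
            if self.outcome_type == "binary":
                totals[j] = self._second_stage_logistic(z_idx, coef, w, 1)[0]
            else:
                totals[j] = self._second_stage_linear(M, z_idx, coef, 1)[0]
        z_all = np.concatenate([self.c_idx] + self.g_slices)
        coef_all = self._stage1(M, z_all, self.x_idx)
        if self.outcome_type == "binary":
            directs = self._second_stage_logistic(z_all, coef_all, w, k)
        else:
            directs = self._second_stage_linear(M, z_all, coef_all, k)
        return totals, directs


def estimate_mediation(
    cohort: pd.DataFrame,
    instruments_x,
    instruments_m,
    x: str = "x",
    m: str = "mediator",
    y: str = "y",
    covariates: list[str] | None = None,
    outcome_type: str = "continuous",
    weights: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """One (optionally weighted) mediation decomposition.

    Returns ``(beta_total, beta_direct, beta_indirect)`` with the subtraction
    identity exact.  ``weights`` (if given) apply to every regression stage.
    """
    engine = MediationEngine(
        cohort,
        {x: instruments_x, m: instruments_m},
        [x, m],
        y,
        covariates,
        outcome_type,
    )
    totals, directs = engine.fit(weights)
    total, direct = float(totals[0]), float(directs[0])
    return total, direct, total - direct


def _summarise_draws(
    exposure: str,
    point: tuple[float, float],
    records: list[tuple[float, float]],
    n_failed: int,
    B: int,
    method: str,
    keep_draws: bool,
) -> MediationResult:
    if n_failed > 0.05 * B:
        raise MediationError(
            f"{n_failed}/{B} bootstrap refits failed (cap is 5%); "
            "the weighted fits are too unstable to summarise"
        )
    arr = np.asarray(records, dtype=float)
    totals, directs = arr[:, 0], arr[:, 1]
    indirects = totals - directs
    with np.errstate(divide="ignore", invalid="ignore"):
        pis = indirects / totals
    pi_point = float(np.median(pis))
    lo, hi = np.percentile(pis, [2.5, 97.5])
    total_pt, direct_pt = point
    med_t, med_i = float(np.median(totals)), float(np.median(indirects))
    draws = None
    if keep_draws:
        draws = pd.DataFrame(
            {"beta_total": totals, "beta_direct": directs, "beta_indirect": indirects, "pi_m": pis}
        )
    return MediationResult(
        exposure=exposure,
        beta_total=total_pt,
        beta_direct=direct_pt,
        beta_indirect=total_pt - direct_pt,
        pi_m=pi_point,
        pi_ci=(float(lo), float(hi)),
        method=method,
        n_draws=len(records),
        n_failed=n_failed,
        sign_consistent=bool(med_i * med_t >= 0),
        draws=draws,
    )


def bootstrap_mediation(
    cohort: pd.DataFrame,
    instruments_x,
    instruments_m,
    x: str = "x",
    m: str = "mediator",
    y: str = "y",
    covariates: list[str] | None = None,
    outcome_type: str = "continuous",
    method: str = "bb",
    B: int = 1000,
    seed: int = 0,
    keep_draws: bool = False,
) -> MediationResult:
    """Bootstrap distribution of the mediated proportion.

    ``method='bb'`` uses Bayesian-bootstrap Dirichlet weights, ``'np'`` the
    non-parametric resampling bootstrap.  Failed refits (e.g. separation in
    sparse weighted logistic fits) are dropped and counted; more than 5% of
    B failing raises :class:`MediationError`.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    if method == "bb":
        W = draw_bayesian_bootstrap(len(cohort), B, seed)
    elif method == "np":
        W = draw_np_bootstrap(len(cohort), B, seed)
    else:
        raise ParameterError("method must be 'bb' or 'np'")
    engine = MediationEngine(
        cohort, {x: instruments_x, m: instruments_m}, [x, m], y, covariates, outcome_type
    )
    totals_pt, directs_pt = engine.fit(None)
    records: list[tuple[float, float]] = []
    n_failed = 0
    for b in range(B):
        try:
            t, d = engine.fit(W[b])
            records.append((float(t[0]), float(d[0])))
        except (FitError, np.linalg.LinAlgError):
            n_failed += 1
    return _summarise_draws(
        x,
        (float(totals_pt[0]), float(directs_pt[0])),
        records,
        n_failed,
        B,
        method,
        keep_draws,
    )


def three_exposure_mediation(
    cohort: pd.DataFrame,
    instruments_x1,
    instruments_x2,
    mediator_grs,
    x1: str,
    x2: str,
    m: str,
    y: str,
    covariates: list[str] | None = None,
    outcome_type: str = "continuous",
    method: str = "bb",
    B: int = 1000,
    seed: int = 0,
    keep_draws: bool = False,
) -> dict[str, MediationResult]:
    """Mediation with two exposures and a genetically proxied mediator.

    The mediator enters the MVMR as a third exposure instrumented by a
    genetic risk score; per-exposure mediated proportions through the
    mediator are returned with bootstrap CIs.
    """
    grs = np.asarray(mediator_grs, dtype=float)
    if grs.ndim == 1 and np.std(grs) == 0:
        raise FitError("mediator genetic risk score carries no variance")
    engine = MediationEngine(
        cohort,
        {x1: instruments_x1, x2: instruments_x2, m: grs},
        [x1, x2, m],
        y,
        covariates,
        outcome_type,
    )
    if method == "bb":
        W = draw_bayesian_bootstrap(len(cohort), B, seed)
    elif method == "np":
        W = draw_np_bootstrap(len(cohort), B, seed)
    else:
        raise ParameterError("method must be 'bb' or 'np'")
    totals_pt, directs_pt = engine.fit(None)
    records: list[tuple[np.ndarray, np.ndarray]] = []
    n_failed = 0
    for b in range(B):
        try:
            records.append(engine.fit(W[b]))
        except (FitError, np.linalg.LinAlgError):
            n_failed += 1
    out: dict[str, MediationResult] = {}
    for j, name in enumerate((x1, x2)):
        recs = [(float(t[j]), float(d[j])) for t, d in records]
        out[name] = _summarise_draws(
            name,
            (float(totals_pt[j]), float(directs_pt[j])),
            recs,
            n_failed,
            B,
            method,
            keep_draws,
        )
    return out
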