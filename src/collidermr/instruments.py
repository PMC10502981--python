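"""Instrument selection and quality control.

Clumping (greedy distance/LD selection of the most significant variants),
pairwise LD pruning on individual-level dosages, genetic risk scores,
instrument-strength diagnostics (per-instrument mean F, joint F and the
Sanderson-Windmeijer conditional F for multivariable models), and Steiger
directionality filtering.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats

from ._regression import FitError, add_intercept, residualize, wls
from .containers import DataError, GenotypeMatrix, InstrumentSet, ParameterError


def _ld_lookup(ld, a: str, b: str):
    """r^2 between two variants from a dict keyed by frozenset/tuple or a callable."""
    if callable(ld):
        return ld(a, b)
    if isinstance(ld, pd.DataFrame):
        try:
            return float(ld.loc[a, b])
        except KeyError:
            return None
    for key in ((a, b), (b, a), frozenset((a, b))):
        if key in ld:
            return float(ld[key])
    return None


def clump(
    variants: pd.DataFrame,
    ld,
    window_kb: float = 50.0,
    r2_threshold: float = 0.001,
    provenance: str = "",
) -> InstrumentSet:
    """Greedy LD clumping: keep the most significant variant, drop anything
    within ``window_kb`` of it with r^2 above the threshold, repeat.

    ``variants`` needs columns id, chrom, pos, p_ext; ``ld`` is a pairwise
    r^2 lookup (dict keyed by id pairs, DataFrame, or callable).  Ties in p
    break on (chrom, pos, id) so the output is deterministic.
    """
    if "p_ext" not in variants.columns:
        raise DataError("clumping needs a p_ext column")
    order = variants.sort_values(
        ["p_ext", "chrom", "pos", "id"], kind="mergesort"
    ).reset_index(drop=True)
    selected: list[dict] = []
    for _, row in order.iterrows():
        keep = True
        for sel in selected:
            if sel["chrom"] != row["chrom"]:
                continue
            if abs(sel["pos"] - row["pos"]) > window_kb * 1000.0:
                continue
            r2 = _ld_lookup(ld, sel["id"], row["id"])
            if r2 is None:
                raise DataError(
                    f"missing LD entry for in-window pair ({sel['id']}, {row['id']})"
                )
            if r2 > r2_threshold:
                keep = False
                break
        if keep:
            selected.append(row.to_dict())
    table = pd.DataFrame(selected, columns=list(variants.columns))
    return InstrumentSet(table.reset_index(drop=True), provenance)


def ld_prune_pairwise(
    instrument: InstrumentSet,
    dosages: GenotypeMatrix,
    r2_threshold: float = 0.05,
    literal: bool = False,
) -> InstrumentSet:
    """Drop one of each same-chromosome pair whose squared sample dosage
    correlation exceeds the threshold, until no violating pair remains.

    By default the variant with the smaller discovery p is kept.  The
    source protocol's sentence reads the other way round ("the SNP with the
    largest p-value was retained"), which contradicts its own clumping rule;
    ``literal=True`` reproduces that reading.
    """
    tab = instrument.table
    ids = list(tab["id"])
    if not ids:
        return instrument
    X = dosages.values(ids)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [i for i, s in zip(ids, sd) if s == 0]
        raise DataError(f"monomorphic dosage column(s): {bad}")
    corr2 = np.corrcoef(X, rowvar=False) ** 2
    chrom = tab["chrom"].to_numpy()
    pvals = tab["p_ext"].to_numpy(dtype=float)
    # greedy pass in p order (ascending by default): a retained variant
    # knocks out every in-LD same-chromosome variant ranked after it
    order = np.argsort(pvals, kind="mergesort")
    if literal:
        order = order[::-1]
    keep_mask = np.ones(len(ids), dtype=bool)
    kept: list[int] = []
    for j in order:
        if not keep_mask[j]:
            continue
        for k in kept:
            if chrom[k] == chrom[j] and corr2[k, j] > r2_threshold:
                keep_mask[j] = False
                break
        if keep_mask[j]:
            kept.append(j)
    keep_ids = [ids[j] for j in sorted(kept)]
    return instrument.subset(keep_ids)


def genetic_risk_score(dosages: GenotypeMatrix, weights: InstrumentSet) -> np.ndarray:
    """Per-person weighted allele score: score_i = sum_j w_j dosage_ij.

    Assumes alleles have already been harmonised (see
    :func:`collidermr.io.harmonize_weights`).
    """
    ids = weights.ids
    missing = [i for i in ids if i not in set(dosages.ids)]
    if missing:
        raise DataError(f"weighted variants absent from dosage matrix: {missing}")
    return dosages.values(ids) @ weights.weights


def _f_from_rss(rss0: float, rss1: float, df_num: int, df_den: int):
    if df_num <= 0 or df_den <= 0:
        raise FitError("non-positive degrees of freedom in F statistic")
    f = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    p = stats.f.sf(f, df_num, df_den)
    return float(f), float(p)


def mean_f_statistic(
    instruments: np.ndarray | GenotypeMatrix,
    exposure: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> dict:
    """First-stage instrument-strength diagnostics.

    Per-instrument F from exposure ~ single instrument (+ covariates),
    averaged; plus the joint first-stage F of all instruments together.
    """
    G = instruments.values() if isinstance(instruments, GenotypeMatrix) else np.asarray(
        instruments, dtype=float
    )
    if G.ndim == 1:
        G = G[:, None]
    x = np.asarray(exposure, dtype=float)
    n, m = G.shape
    C = add_intercept(
        None if covariates is None else np.asarray(covariates, dtype=float), n
    )
    c = C.shape[1]
    if n <= m + c + 1:
        raise FitError("too few observations for instrument diagnostics")
    # residualise on covariates once; per-SNP F is then a simple-regression t^2
    xr = residualize(x[:, None], C)[:, 0]
    Gr = residualize(G, C)
    rss0 = float(xr @ xr)
    g2 = np.sum(Gr**2, axis=0)
    if np.any(g2 == 0):
        raise FitError("monomorphic instrument column")
    bhat = (Gr.T @ xr) / g2
    rss1 = rss0 - bhat**2 * g2
    per_f = (bhat**2 * g2) / (rss1 / (n - c - 1))
    # joint F
    beta_j, _, resid_j = wls(np.hstack([Gr, C]), x)
    rss_joint = float(resid_j @ resid_j)
    joint_f, joint_p = _f_from_rss(rss0, rss_joint, m, n - m - c)
    return {
        "mean_f": float(np.mean(per_f)),
        "per_instrument_f": per_f,
        "joint_f": joint_f,
        "joint_f_p": joint_p,
        "n": n,
        "m": m,
    }


def conditional_f(
    dosages: np.ndarray | GenotypeMatrix,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> dict:
    """Sanderson-Windmeijer conditional F statistic per exposure.

    For each exposure, the other exposures are partialled out by a TSLS
    regression on their genetically predicted values (so the fitted
    coefficients are not attenuated by first-stage noise), and the
    instruments' F on the remaining variation is computed with numerator
    degrees of freedom m - (K - 1).  Values near zero indicate the
    genetically predicted exposures are collinear; that case is reported
    with a warning rather than raised.
    """
    G = dosages.values() if isinstance(dosages, GenotypeMatrix) else np.asarray(
        dosages, dtype=float
    )
    X = exposures.to_numpy(dtype=float) if isinstance(exposures, pd.DataFrame) else np.asarray(
        exposures, dtype=float
    )
    if X.ndim != 2 or X.shape[1] < 2:
        raise ParameterError("conditional F needs at least two exposures")
    names = (
        list(exposures.columns)
        if isinstance(exposures, pd.DataFrame)
        else [f"x{k+1}" for k in range(X.shape[1])]
    )
    n, m = G.shape
    K = X.shape[1]
    C = add_intercept(
        None if covariates is None else np.asarray(covariates, dtype=float), n
    )
    c = C.shape[1]
    Gr = residualize(G, C)
    Xr = residualize(X, C)
    # first-stage predictions of every exposure from the full instrument set
    coef, _, _, _ = np.linalg.lstsq(Gr, Xr, rcond=None)
    Xhat = Gr @ coef
    out: dict[str, float] = {}
    for k in range(K):
        others_hat = np.delete(Xhat, k, axis=1)
        others_obs = np.delete(Xr, k, axis=1)
        # TSLS fit of X_k on the other observed exposures (instrumented),
        # residual taken against the observed values
        Dh = add_intercept(others_hat, n)
        coef, _, _, _ = np.linalg.lstsq(Dh, Xr[:, k], rcond=None)
        e = Xr[:, k] - add_intercept(others_obs, n) @ coef
        rss0 = float(e @ e)
        eg = residualize(e[:, None], add_intercept(Gr, n))[:, 0]
        rss1 = float(eg @ eg)
        df_num = m - (K - 1)
        df_den = n - m - c - (K - 1)
        if rss1 <= 1e-12 * rss0 or rss0 <= 1e-12:
            warnings.warn(
                f"conditional F for '{names[k]}' is degenerate (collinear predicted exposures)"
            )
            out[names[k]] = 0.0
            continue
        f, _ = _f_from_rss(rss0, rss1, df_num, df_den)
        out[names[k]] = f
        if f < 1.0:
            warnings.warn(
                f"conditional F for '{names[k]}' below 1: collinear genetically "
                "predicted exposures / weak conditional instruments"
            )
    return out


def snp_r2_individual(
    dosage: np.ndarray, trait: np.ndarray, covariates=None
) -> float:
    """Squared (covariate-adjusted) correlation between one SNP and a trait."""
    g = np.asarray(dosage, dtype=float)
    t = np.asarray(trait, dtype=float)
    C = add_intercept(
        None if covariates is None else np.asarray(covariates, dtype=float), g.shape[0]
    )
    gr = residualize(g[:, None], C)[:, 0]
    tr = residualize(t[:, None], C)[:, 0]
    denom = float(np.sqrt((gr @ gr) * (tr @ tr)))
    if denom == 0.0:
        raise DataError("zero variance in SNP or trait when computing r^2")
    return float((gr @ tr) / denom) ** 2


def snp_r2_summary(eaf: float, beta: float, trait_var: float = 1.0) -> float:
    """Variance explained from summary data: 2 f (1 - f) beta^2 / Var(trait)."""
    if not 0.0 < eaf < 1.0:
        raise ParameterError("eaf must lie in (0, 1)")
    if trait_var <= 0:
        raise ParameterError("trait variance must be positive")
    return 2.0 * eaf * (1.0 - eaf) * beta**2 / trait_var


def steiger_filter(
    instrument: InstrumentSet,
    target_r2: dict[str, float] | pd.Series,
    competitor_r2: dict[str, dict[str, float]] | pd.DataFrame,
) -> InstrumentSet:
    """Directionality filter: keep a SNP only if it explains more variance in
    the target trait than in every competing trait.

    ``target_r2`` maps variant id -> r^2 with the target; ``competitor_r2``
    maps competitor trait -> {variant id -> r^2} (or a DataFrame indexed by
    variant id with one column per competitor).
    """
    if isinstance(competitor_r2, pd.DataFrame):
        competitor_r2 = {c: competitor_r2[c].to_dict() for c in competitor_r2.columns}
    keep: list[str] = []
    for vid in instrument.ids:
        try:
            rt = float(target_r2[vid])
        except KeyError as exc:
            raise DataError(f"missing target r^2 for variant {vid}") from exc
        ok = True
        for trait, table in competitor_r2.items():
            try:
                rc = float(table[vid])
            except KeyError as exc:
                raise DataError(
                    f"missing r^2 for variant {vid} on competitor trait {trait}"
                ) from exc
            if rt <= rc:
                ok = False
                break
        if ok:
            keep.append(vid)
    return instrument.subset(keep)
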