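"""End-to-end analysis pipeline: configuration, staging, manifest.

Binds the stages together in the standard order — load & harmonise,
instrument QC, observational baseline, UVMR, MVMR, collider-corrected
MVMR, mediation, stratified/moderation analyses — driven by a YAML
configuration.  Every run writes a manifest with per-stage row counts
(in = out + excluded), the seed, a config hash and the package version, so
results are attributable and reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collider import collider_correction_mvmr
from .containers import DataError, GenotypeMatrix
from .estimators import observational_association, tsls_mvmr, tsls_uvmr
from .io import read_dosage_raw, read_summary_stats
from .mediate import bootstrap_mediation
from .moderate import fisher_z_heterogeneity, meta_regression_from_strata, stratified_estimates
from .simulate import inverse_normal_transform


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run (usually loaded from YAML)."""

    dosages: str
    phenotypes: str
    exposures: list[str]
    outcome: str
    outcome_type: str = "continuous"
    mediator: str | None = None
    covariates: list[str] = field(default_factory=list)
    instruments: dict[str, list[str]] = field(default_factory=dict)
    summary_stats: dict[str, str] = field(default_factory=dict)
    inverse_normalise_exposures: bool = True
    run_observational: bool = True
    run_uvmr: bool = True
    run_mvmr: bool = True
    run_cc_mvmr: bool = True
    run_mediation: bool = False
    stratify_by: str | None = None
    stratify_cutpoints: list[float] | None = None
    loss: str = "tukey"
    bootstrap_method: str = "bb"
    bootstrap_reps: int = 500
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-stage accounting for one pipeline run."""

    config_hash: str
    seed: int
    version: str = __version__
    timestamp: str = ""
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_excluded: int = 0, note: str = "") -> None:
        if n_excluded < 0 or n_excluded > n_in:
            raise DataError(f"stage '{stage}': exclusion count out of range")
        self.stages.append(
            {
                "stage": stage,
                "n_in": int(n_in),
                "n_excluded": int(n_excluded),
                "n_out": int(n_in - n_excluded),
                "note": note,
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _check_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{what} missing column(s): {missing}")


def run_pipeline(config: AnalysisConfig) -> RunManifest:
    """Execute the configured stages in order; returns the manifest.

    Results are written as TSV + JSON side by side under ``config.out_dir``.
    Any stage error is re-raised as :class:`PipelineError` naming the stage,
    after the partial manifest has been written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.content_hash(),
        seed=config.seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stage = "load"
    try:
        gm, imputed = read_dosage_raw(config.dosages)
        pheno = pd.read_csv(config.phenotypes)
        # fail fast: every referenced column must exist before any computation
        needed = list(config.exposures) + [config.outcome] + list(config.covariates)
        if config.mediator:
            needed.append(config.mediator)
        if config.stratify_by:
            needed.append(config.stratify_by)
        _check_columns(pheno, needed, "phenotype table")
        if len(pheno) != gm.n:
            raise DataError(
                f"phenotype rows ({len(pheno)}) do not match dosage rows ({gm.n})"
            )
        complete = pheno[needed].notna().all(axis=1)
        n_in = len(pheno)
        pheno = pheno.loc[complete].reset_index(drop=True)
        gm = GenotypeMatrix(
            gm.dosages.loc[complete.to_numpy()].reset_index(drop=True), gm.variants
        )
        manifest.record(
            "load",
            n_in,
            n_in - len(pheno),
            f"complete cases; {int(imputed.sum())} dosages mean-imputed",
        )

        stage = "instruments"
        inst: dict[str, list[str]] = {}
        for exp in config.exposures + ([config.mediator] if config.mediator else []):
            if exp in config.instruments:
                ids = list(config.instruments[exp])
            elif exp in config.summary_stats:
                ext = read_summary_stats(config.summary_stats[exp])
                ids = [i for i in ext["id"] if i in set(gm.ids)]
            else:
                raise DataError(f"no instruments configured for exposure '{exp}'")
            absent = [i for i in ids if i not in set(gm.ids)]
            if absent:
                raise DataError(f"instrument(s) absent from dosage data: {absent}")
            inst[exp] = ids
            manifest.record(f"instruments:{exp}", len(ids), 0)

        if config.inverse_normalise_exposures:
            for exp in config.exposures:
                pheno[exp] = inverse_normal_transform(pheno[exp].to_numpy())

        cov = pheno[config.covariates] if config.covariates else None
        y = pheno[config.outcome].to_numpy()
        results: list[pd.DataFrame] = []

        if config.run_observational:
            stage = "observational"
            est = observational_association(
                pheno[config.exposures],
                y,
                cov,
                config.outcome_type,
                exposure_names=config.exposures,
            )
            results.append(est.to_frame())
            manifest.record("observational", len(pheno), 0)

        if config.run_uvmr:
            stage = "uvmr"
            for exp in config.exposures:
                est = tsls_uvmr(
                    gm.values(inst[exp]),
                    pheno[exp].to_numpy(),
                    y,
                    cov,
                    config.outcome_type,
                    exposure_name=exp,
                )
                results.append(est.to_frame())
            manifest.record("uvmr", len(pheno), 0)

        all_ids = sorted({i for exp in config.exposures for i in inst[exp]})
        if config.run_mvmr and len(config.exposures) >= 2:
            stage = "mvmr"
            est = tsls_mvmr(
                gm.values(all_ids), pheno[config.exposures], y, cov, config.outcome_type
            )
            results.append(est.to_frame())
            manifest.record("mvmr", len(pheno), 0)

        if config.run_cc_mvmr and len(config.exposures) >= 2:
            stage = "cc_mvmr"
            cc = collider_correction_mvmr(
                gm.values(all_ids),
                pheno[config.exposures],
                y,
                cov,
                config.outcome_type,
                loss=config.loss,
            )
            frame = cc.to_frame()
            frame.insert(0, "method", f"cc_mvmr[{config.loss}]")
            results.append(frame)
            manifest.record("cc_mvmr", len(pheno), 0)
            pd.DataFrame(
                {"id": all_ids, "outlier_weight": cc.snp_weights}
            ).to_csv(out / "cc_snp_weights.tsv", sep="\t", index=False)

        if config.run_mediation:
            stage = "mediation"
            if not config.mediator:
                raise DataError("mediation requested but no mediator configured")
            med = bootstrap_mediation(
                pheno,
                gm.values(inst[config.exposures[0]]),
                gm.values(inst[config.mediator]),
                x=config.exposures[0],
                m=config.mediator,
                y=config.outcome,
                covariates=config.covariates or None,
                outcome_type=config.outcome_type,
                method=config.bootstrap_method,
                B=config.bootstrap_reps,
                seed=config.seed,
            )
            with open(out / "mediation.json", "w") as fh:
                json.dump(
                    {
                        "exposure": med.exposure,
                        "beta_total": med.beta_total,
                        "beta_direct": med.beta_direct,
                        "beta_indirect": med.beta_indirect,
                        "pi_m": med.pi_m,
                        "pi_ci": list(med.pi_ci),
                        "method": med.method,
                        "n_draws": med.n_draws,
                        "n_failed": med.n_failed,
                        "sign_consistent": med.sign_consistent,
                        "seed": config.seed,
                    },
                    fh,
                    indent=2,
                )
            manifest.record("mediation", len(pheno), 0, f"B={med.n_draws}")
        else:
            manifest.record("mediation", len(pheno), 0, "skipped (disabled)")

        if config.stratify_by:
            stage = "stratify"
            exp = config.exposures[0]
            ids = inst[exp]
            G = gm.values(ids)
            xv = pheno[exp].to_numpy()
            cov_cols = [c for c in config.covariates if c != config.stratify_by]

            def _estimator(idx):
                return tsls_uvmr(
                    G[idx],
                    xv[idx],
                    y[idx],
                    pheno[cov_cols].iloc[idx] if cov_cols else None,
                    config.outcome_type,
                    exposure_name=exp,
                    diagnostics=False,
                )

            strata = stratified_estimates(
                pheno, config.stratify_by, _estimator, cutpoints=config.stratify_cutpoints
            )
            rows = []
            for s in strata:
                row = {"stratum": s.label, "moderator": s.moderator_value, "n": s.n}
                if s.estimate is not None:
                    row.update(beta=float(s.estimate.beta[0]), se=float(s.estimate.se[0]))
                else:
                    row.update(beta=np.nan, se=np.nan, error=s.error)
                rows.append(row)
            pd.DataFrame(rows).to_csv(out / "strata.tsv", sep="\t", index=False)
            ok = [s for s in strata if s.estimate is not None]
            extras = {}
            if len(ok) == 2:
                z, p = fisher_z_heterogeneity(
                    float(ok[0].estimate.beta[0]),
                    float(ok[0].estimate.se[0]),
                    float(ok[1].estimate.beta[0]),
                    float(ok[1].estimate.se[0]),
                )
                extras = {"fisher_z": z, "p": p}
            elif len(ok) >= 4:
                mr = meta_regression_from_strata(strata, quadratic=len(ok) >= 5)
                extras = {
                    "terms": mr.terms,
                    "coef": [float(v) for v in mr.coef],
                    "se": [float(v) for v in mr.se],
                    "q_diff": mr.q_diff,
                    "p_diff": mr.p_diff,
                }
            with open(out / "moderation.json", "w") as fh:
                json.dump(extras, fh, indent=2)
            manifest.record("stratify", len(pheno), 0, f"{len(ok)} strata fitted")

        if results:
            table = pd.concat(results, ignore_index=True)
            table.insert(0, "seed", config.seed)
            table.to_csv(out / "mr_estimates.tsv", sep="\t", index=False)
            with open(out / "mr_estimates.json", "w") as fh:
                json.dump(json.loads(table.to_json(orient="records")), fh, indent=2)
    except Exception as exc:
        manifest.record(f"error:{stage}", 0, 0, str(exc))
        manifest.write(out / "manifest.yaml")
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    manifest.write(out / "manifest.yaml")
    return manifest
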