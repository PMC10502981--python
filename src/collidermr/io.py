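"""Readers and writers for the pipeline's text formats.

Dosages travel as PLINK ``.raw``-style whitespace-delimited text (header
``FID IID PAT MAT SEX PHENOTYPE`` then one ``SNP_EA`` column per variant,
the effect allele in the suffix); GWAS summary statistics as TSV with
columns SNP/CHR/POS/EA/NEA/EAF/BETA/SE/P; phenotypes and covariates as CSV;
simulation truth records as YAML sidecars.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .containers import DataError, GenotypeMatrix, InstrumentSet

RAW_META_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
SUMMARY_REQUIRED = ["SNP", "EA", "NEA", "BETA", "SE", "P"]
SUMMARY_OPTIONAL = ["CHR", "POS", "EAF"]

#: palindromic-variant ambiguity window on the effect-allele frequency
PALINDROME_EAF_WINDOW = (0.42, 0.58)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def read_dosage_raw(path, variants: pd.DataFrame | None = None):
    """Parse a PLINK .raw-style dosage file into a :class:`GenotypeMatrix`.

    Missing dosages (NA) are imputed to the per-SNP mean; the second return
    value reports the imputation count per variant.  Variant metadata
    (chrom/pos/other allele/eaf) may be supplied; otherwise placeholders
    are used, with the effect allele taken from the ``SNP_EA`` suffix and
    eaf from the observed dosage mean.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:
        raise DataError(f"cannot parse dosage file {path}: {exc}") from exc
    missing_meta = [c for c in RAW_META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise DataError(f"malformed .raw header: missing column(s) {missing_meta}")
    snp_cols = [c for c in df.columns if c not in RAW_META_COLUMNS]
    ids, eas = [], []
    for col in snp_cols:
        if "_" not in col:
            raise DataError(f"dosage column '{col}' lacks the SNP_EA allele suffix")
        vid, ea = col.rsplit("_", 1)
        ids.append(vid)
        eas.append(ea)
    dos = df[snp_cols].apply(pd.to_numeric, errors="coerce")
    bad = dos.isna() & df[snp_cols].notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric dosage at line {r + 2}, column '{snp_cols[c]}'"
        )
    n_imputed = dos.isna().sum()
    dos = dos.fillna(dos.mean())
    dos.columns = ids
    if variants is None:
        variants = pd.DataFrame(
            {
                "id": ids,
                "chrom": "0",
                "pos": 0,
                "effect_allele": eas,
                "other_allele": "N",
                "eaf": dos.mean().to_numpy() / 2.0,
            }
        )
    else:
        variants = variants.set_index("id", drop=False).loc[ids].reset_index(drop=True)
        flipped = variants["effect_allele"].to_numpy() != np.asarray(eas)
        if flipped.any():
            raise DataError(
                "dosage column allele suffix disagrees with variant metadata for "
                f"{[i for i, f in zip(ids, flipped) if f]}; harmonise first"
            )
    gm = GenotypeMatrix(dos.reset_index(drop=True), variants)
    counts = pd.Series(n_imputed.to_numpy(), index=ids, name="n_imputed")
    return gm, counts


def write_dosage_raw(gm: GenotypeMatrix, path, iids=None) -> None:
    """Write a :class:`GenotypeMatrix` as PLINK .raw-style text."""
    n = gm.n
    meta = pd.DataFrame(
        {
            "FID": iids if iids is not None else [f"F{i+1}" for i in range(n)],
            "IID": iids if iids is not None else [f"I{i+1}" for i in range(n)],
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": -9,
        }
    )
    dos = gm.dosages.copy()
    dos.columns = [
        f"{vid}_{ea}"
        for vid, ea in zip(gm.variants["id"], gm.variants["effect_allele"])
    ]
    pd.concat([meta, dos.reset_index(drop=True)], axis=1).to_csv(path, sep=" ", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    """Read GWAS summary statistics (TSV) into the package's variant schema.

    Requires SNP/EA/NEA/BETA/SE/P; CHR/POS/EAF are optional.  Duplicate SNP
    ids are rejected.  Output columns follow the internal naming
    (id/chrom/pos/effect_allele/other_allele/eaf/beta_ext/se_ext/p_ext).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"summary statistics missing required column(s): {missing}")
    if df["SNP"].duplicated().any():
        dups = df.loc[df["SNP"].duplicated(), "SNP"].tolist()
        raise DataError(f"duplicated SNP id(s) in summary statistics: {dups}")
    out = pd.DataFrame(
        {
            "id": df["SNP"].astype(str),
            "chrom": df["CHR"].astype(str) if "CHR" in df.columns else "0",
            "pos": df["POS"].astype(int) if "POS" in df.columns else 0,
            "effect_allele": df["EA"].astype(str).str.upper(),
            "other_allele": df["NEA"].astype(str).str.upper(),
            "eaf": df["EAF"].astype(float) if "EAF" in df.columns else np.nan,
            "beta_ext": df["BETA"].astype(float),
            "se_ext": df["SE"].astype(float),
            "p_ext": df["P"].astype(float),
        }
    )
    if (out["se_ext"] <= 0).any():
        raise DataError("summary statistics contain non-positive standard errors")
    if (out["effect_allele"] == out["other_allele"]).any():
        raise DataError("summary statistics contain identical effect/other alleles")
    return out


def _is_palindromic(ea: str, nea: str) -> bool:
    return _COMPLEMENT.get(ea) == nea


def harmonize_weights(
    external: pd.DataFrame,
    gm: GenotypeMatrix,
    drop_ambiguous_palindromes: bool = True,
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Align external per-allele weights to the cohort's effect alleles.

    Matching alleles keep their sign; swapped alleles flip the weight sign;
    strand flips are resolved through the complement; palindromic variants
    with eaf inside the ambiguity window are dropped by default.  Returns
    the harmonised :class:`InstrumentSet` and a log of actions per variant.
    """
    cohort = gm.variants.set_index("id")
    rows, log = [], []
    for _, rec in external.iterrows():
        vid = rec["id"]
        if vid not in cohort.index:
            log.append({"id": vid, "action": "absent"})
            continue
        ea_c = str(cohort.loc[vid, "effect_allele"]).upper()
        oa_c = str(cohort.loc[vid, "other_allele"]).upper()
        ea_e, oa_e = rec["effect_allele"], rec["other_allele"]
        pal = _is_palindromic(ea_e, oa_e)
        if pal and drop_ambiguous_palindromes:
            eaf = rec.get("eaf", np.nan)
            lo, hi = PALINDROME_EAF_WINDOW
            if not np.isfinite(eaf) or lo < eaf < hi:
                log.append({"id": vid, "action": "dropped_palindromic"})
                continue
        flip = None
        if (ea_e, oa_e) == (ea_c, oa_c):
            flip = False
        elif (ea_e, oa_e) == (oa_c, ea_c):
            flip = True
        elif not pal:
            ce, co = _COMPLEMENT.get(ea_e), _COMPLEMENT.get(oa_e)
            if (ce, co) == (ea_c, oa_c):
                flip = False
            elif (ce, co) == (oa_c, ea_c):
                flip = True
        if flip is None:
            log.append({"id": vid, "action": "allele_mismatch"})
            continue
        out = rec.to_dict()
        out["effect_allele"], out["other_allele"] = ea_c, oa_c
        sign = -1.0 if flip else 1.0
        out["beta_ext"] = sign * rec["beta_ext"]
        out["weight"] = out["beta_ext"]
        if np.isfinite(rec.get("eaf", np.nan)) and flip:
            out["eaf"] = 1.0 - rec["eaf"]
        rows.append(out)
        log.append({"id": vid, "action": "flipped" if flip else "kept"})
    if not rows:
        raise DataError("no variants could be harmonised")
    table = pd.DataFrame(rows).reset_index(drop=True)
    return InstrumentSet(table, provenance="harmonized"), pd.DataFrame(log)


def write_truth_yaml(truth, path) -> None:
    """Write a SimulationTruth record (numpy arrays as lists) as YAML."""
    d = asdict(truth)
    d["config"] = asdict(truth.config)

    def clean(v):
        if isinstance(v, np.ndarray):
            return [float(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return float(v)
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        return v

    with open(path, "w") as fh:
        yaml.safe_dump(clean(d), fh, sort_keys=False)
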