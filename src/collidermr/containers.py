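"""Core data containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Columns every variant-metadata table carries.
VARIANT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]


class DataError(ValueError):
    """Input data violates a structural requirement (missing LD, columns, ...)."""


class ParameterError(ValueError):
    """A parameter is outside its valid range."""


@dataclass
class GenotypeMatrix:
    """An n x m effect-allele dosage matrix with per-variant metadata.

    ``dosages`` is a DataFrame (individuals x variants, columns = variant
    ids); ``variants`` is a DataFrame with :data:`VARIANT_COLUMNS` (plus any
    extras such as external weights), one row per dosage column, same order.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        ids = list(self.variants["id"])
        if list(self.dosages.columns) != ids:
            raise DataError("dosage columns and variant metadata ids disagree")
        if len(set(ids)) != len(ids):
            raise DataError("duplicate variant ids")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def ids(self) -> list[str]:
        return list(self.variants["id"])

    def values(self, ids: list[str] | None = None) -> np.ndarray:
        if ids is None:
            return self.dosages.to_numpy(dtype=float)
        return self.dosages.loc[:, list(ids)].to_numpy(dtype=float)

    def subset(self, ids: list[str]) -> "GenotypeMatrix":
        ids = list(ids)
        variants = self.variants.set_index("id", drop=False).loc[ids].reset_index(drop=True)
        return GenotypeMatrix(self.dosages.loc[:, ids].copy(), variants)


@dataclass
class InstrumentSet:
    """An ordered set of instrument variants with per-variant weights.

    ``table`` carries one row per variant (id, chrom, pos, alleles, eaf,
    external beta/se/p) and a ``weight`` column used for genetic risk
    scores; ``provenance`` names the discovery study the weights came from.
    """

    table: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = list(self.table["id"])
        if len(set(ids)) != len(ids):
            raise DataError("duplicate variant ids in instrument set")
        if "weight" in self.table.columns and not np.all(
            np.isfinite(self.table["weight"].to_numpy(dtype=float))
        ):
            raise DataError("non-finite instrument weights")

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def weights(self) -> np.ndarray:
        if "weight" in self.table.columns:
            return self.table["weight"].to_numpy(dtype=float)
        return self.table["beta_ext"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, ids: list[str]) -> "InstrumentSet":
        keep = self.table[self.table["id"].isin(set(ids))].copy()
        keep = keep.set_index("id", drop=False).loc[[i for i in ids if i in set(keep["id"])]]
        return InstrumentSet(keep.reset_index(drop=True), self.provenance)
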