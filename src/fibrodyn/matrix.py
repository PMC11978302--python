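"""Protein intensity matrices with an explicit missingness mask.

Values are log2 MS intensities (proteins in rows, samples in columns).  The
boolean ``mask`` records which cells were actually observed; after imputation
the values are complete but the mask still identifies the originally observed
cells, which downstream induced-protein detection relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class IntensityMatrix:
    values: pd.DataFrame            # log2 intensities; NaN where missing (pre-imputation)
    mask: pd.DataFrame              # True where observed
    provenance: str = "raw"         # raw | normalized | imputed
    seed: int | None = None         # imputation seed, if imputed

    def __post_init__(self):
        if not self.values.index.equals(self.mask.index) or \
           not self.values.columns.equals(self.mask.columns):
            raise ValueError("values and mask must share index and columns")
        # missing => no observed value
        bad = (~self.mask.to_numpy()) & np.isfinite(self.values.to_numpy())
        if self.provenance != "imputed" and bad.any():
            raise ValueError("mask marks cells missing but values are present")

    @classmethod
    def from_values(cls, values: pd.DataFrame, provenance: str = "raw") -> "IntensityMatrix":
        return cls(values=values, mask=values.notna(), provenance=provenance)

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset(self, proteins=None, samples=None) -> "IntensityMatrix":
        v, m = self.values, self.mask
        if proteins is not None:
            v, m = v.loc[proteins], m.loc[proteins]
        if samples is not None:
            v, m = v[samples], m[samples]
        return replace(self, values=v, mask=m)

    def copy(self) -> "IntensityMatrix":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())
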