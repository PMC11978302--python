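"""Valid-value filtering, normalization, down-shifted imputation, z-scoring.

The filter keeps proteins with enough observed replicates in at least one
(model, time point) group; missing values are then imputed by drawing from a
normal distribution down-shifted from the observed distribution (mean minus
1.8 standard deviations, width 0.3 standard deviations) — the standard
left-censored imputation for intensity-dependent missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import validate_design
from .matrix import IntensityMatrix


@dataclass
class FilterRule:
    min_valid: int = 5
    scope: str = "any_group_per_model"    # or "any_group_joint"

    def __post_init__(self):
        if self.min_valid < 1:
            raise ValueError("min_valid must be >= 1")
        if self.scope not in ("any_group_per_model", "any_group_joint"):
            raise ValueError(f"unknown scope {self.scope!r}")


def filter_by_valid_values(matrix: IntensityMatrix, design: pd.DataFrame,
                           rule: FilterRule = FilterRule()) -> IntensityMatrix:
    """Keep proteins with >= min_valid observed values in at least one group.

    Groups are (model, time point) when scope is ``any_group_per_model``, or
    time points pooled across models when ``any_group_joint``.
    """
    validate_design(design)
    lookup = design.set_index("sample_id")
    unmapped = [c for c in matrix.samples if c not in lookup.index]
    if unmapped:
        raise ValueError(f"samples not in design: {unmapped[:5]}")
    meta = lookup.loc[matrix.samples]
    if rule.scope == "any_group_per_model":
        keys = [f"{m}|{t}" for m, t in zip(meta["model"], meta["timepoint"])]
    else:
        keys = list(meta["timepoint"])
    counts = matrix.mask.T.groupby(pd.Index(keys, name="group")).sum().T
    keep = (counts >= rule.min_valid).any(axis=1)
    return matrix.subset(proteins=matrix.proteins[keep])


def normalize_columns(matrix: IntensityMatrix,
                      method: str = "median_center") -> IntensityMatrix:
    """Median-center each sample column, re-adding the grand median."""
    if method == "none":
        return matrix.copy()
    if method != "median_center":
        raise ValueError(f"unknown normalization {method!r}")
    med = matrix.values.median(axis=0, skipna=True)
    if med.isna().any():
        bad = med.index[med.isna()].tolist()
        raise ValueError(f"all-missing columns cannot be normalized: {bad[:5]}")
    grand = np.nanmedian(matrix.values.to_numpy())
    values = matrix.values.sub(med, axis=1) + grand
    return replace(matrix, values=values, mask=matrix.mask.copy(),
                   provenance="normalized")


def impute_downshift(matrix: IntensityMatrix, shift: float = 1.8,
                     width: float = 0.3, per: str = "column",
                     seed: int = 0) -> IntensityMatrix:
    """Replace missing cells by draws from Normal(m - shift*s, (width*s)^2).

    ``m`` and ``s`` are the observed mean and SD of the column (default) or
    of the whole matrix.  Observed cells are untouched; draws are consumed in
    row-major order over missing cells so the output is reproducible.
    """
    if shift <= 0 or width <= 0:
        raise ValueError("shift and width must be > 0")
    if per not in ("column", "matrix"):
        raise ValueError(f"unknown scope {per!r}")
    vals = matrix.values.to_numpy(copy=True)
    obs = matrix.mask.to_numpy()
    miss = ~obs
    if not miss.any():
        return replace(matrix, values=matrix.values.copy(),
                       mask=matrix.mask.copy(), provenance="imputed", seed=seed)
    if per == "column":
        n_obs = obs.sum(axis=0)
        if (n_obs < 2).any():
            bad = matrix.samples[n_obs < 2].tolist()
            raise ValueError(f"columns with <2 observed values: {bad[:5]}")
        m = np.nanmean(vals, axis=0)
        s = np.nanstd(vals, axis=0, ddof=1)
        mu_cell = np.broadcast_to(m - shift * s, vals.shape)
        sd_cell = np.broadcast_to(width * s, vals.shape)
    else:
        if obs.sum() < 2:
            raise ValueError("fewer than 2 observed values in matrix")
        m = np.nanmean(vals)
        s = np.nanstd(vals, ddof=1)
        mu_cell = np.full(vals.shape, m - shift * s)
        sd_cell = np.full(vals.shape, width * s)
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal(int(miss.sum()))     # row-major order
    vals[miss] = mu_cell[miss] + sd_cell[miss] * draws
    values = pd.DataFrame(vals, index=matrix.proteins, columns=matrix.samples)
    return IntensityMatrix(values=values, mask=matrix.mask.copy(),
                           provenance="imputed", seed=seed)


def zscore_rows(matrix: IntensityMatrix) -> tuple[IntensityMatrix, list]:
    """Row-wise z-scores with population (1/n) SD.

    Requires a complete (imputed) matrix.  Constant rows cannot be scaled;
    they are excluded and their ids returned as diagnostics.
    """
    vals = matrix.values.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("z-scoring requires a complete (imputed) matrix")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    constant = (sd[:, 0] == 0.0)
    excluded = matrix.proteins[constant].tolist()
    z = (vals[~constant] - mean[~constant]) / sd[~constant]
    values = pd.DataFrame(z, index=matrix.proteins[~constant],
                          columns=matrix.samples)
    out = IntensityMatrix(values=values, mask=matrix.mask.loc[values.index].copy(),
                          provenance=matrix.provenance, seed=matrix.seed)
    return out, excluded
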