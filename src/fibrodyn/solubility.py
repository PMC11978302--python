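"""Insoluble-fraction (E) solubility profiling.

For each protein, every E-fraction replicate is expressed as a log2 ratio to
the protein's median S-fraction intensity.  Proteins at least threefold
enriched in E over S in at least one time point AND changing significantly in
time (one-way ANOVA on E intensities, BH FDR < 0.05) form the insoluble
E-fraction proteome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import select_samples
from .diffexpr import anova_time_course, detect_induced
from .matrix import IntensityMatrix


@dataclass
class SolubilitySelection:
    selected: set
    table: pd.DataFrame           # per protein: max_enrichment_log2, anova q, gates
    fold_min: float
    q: float


def es_ratio(e_matrix: IntensityMatrix, s_matrix: IntensityMatrix,
             design: pd.DataFrame, model: str,
             scope: str = "global") -> pd.DataFrame:
    """log2(E replicate) - log2(median S) per protein.

    ``global`` scope takes the S median over all S samples of the model;
    ``per_timepoint`` matches each E replicate to the S median of its own
    time point.
    """
    if scope not in ("global", "per_timepoint"):
        raise ValueError(f"unknown scope {scope!r}")
    missing = e_matrix.proteins.difference(s_matrix.proteins)
    if len(missing):
        raise ValueError(f"proteins absent from S matrix: {list(missing[:5])}")
    s_vals = s_matrix.values.loc[e_matrix.proteins]
    e_cols = [c for c in select_samples(design, model=model, fraction="E")
              if c in e_matrix.samples]
    e_vals = e_matrix.values[e_cols]
    meta = design.set_index("sample_id")
    if scope == "global":
        s_cols = [c for c in select_samples(design, model=model, fraction="S")
                  if c in s_vals.columns]
        med = s_vals[s_cols].median(axis=1)
        return e_vals.sub(med, axis=0)
    out = {}
    for c in e_cols:
        tp = meta.loc[c, "timepoint"]
        s_cols = [s for s in select_samples(design, model=model, timepoint=tp,
                                            fraction="S") if s in s_vals.columns]
        out[c] = e_vals[c] - s_vals[s_cols].median(axis=1)
    return pd.DataFrame(out)


def select_insolubilized(ratios: pd.DataFrame, e_matrix: IntensityMatrix,
                         design: pd.DataFrame, model: str,
                         fold_min: float = 3.0, q: float = 0.05,
                         gate1_mode: str = "mean") -> SolubilitySelection:
    """Two-gate selection of proteins shifting into the insoluble fraction.

    Gate 1: mean E/S log2 ratio >= log2(fold_min) in at least one time-point
    group (inclusive; ``gate1_mode='any'`` uses any single replicate).
    Gate 2: one-way ANOVA of E intensities across time points, BH q <= q.
    """
    meta = design.set_index("sample_id")
    tps = [t for t in design["timepoint"].unique()]
    thr = math.log2(fold_min)
    per_tp = {}
    for tp in tps:
        cols = [c for c in ratios.columns if meta.loc[c, "timepoint"] == tp]
        if not cols:
            continue
        if gate1_mode == "mean":
            per_tp[tp] = ratios[cols].mean(axis=1)
        elif gate1_mode == "any":
            per_tp[tp] = ratios[cols].max(axis=1)
        else:
            raise ValueError(f"unknown gate1_mode {gate1_mode!r}")
    enrich = pd.DataFrame(per_tp)
    gate1 = (enrich >= thr).any(axis=1)

    anova = anova_time_course(e_matrix, design, model, q=q, fraction="E",
                              timepoints=tps)
    gate2 = anova["significant"].reindex(ratios.index, fill_value=False)

    table = pd.DataFrame({
        "max_enrichment_log2": enrich.max(axis=1),
        "anova_q": anova["q"].reindex(ratios.index),
        "gate_fold": gate1, "gate_anova": gate2,
        "selected": gate1 & gate2,
    })
    return SolubilitySelection(selected=set(table.index[table["selected"]]),
                               table=table, fold_min=fold_min, q=q)


def induced_in_efraction(mask: pd.DataFrame, design: pd.DataFrame, model: str,
                         min_detect_frac: float = 0.5) -> set:
    """Induced-protein rule applied to the E-fraction detection mask."""
    return detect_induced(mask, design, model, min_detect_frac, fraction="E")
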