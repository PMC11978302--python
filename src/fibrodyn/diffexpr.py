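"""Differential abundance on the Total proteome.

A protein is called differential when its peak-fibrosis (T2) abundance
differs from the control mean by at least 1.5-fold AND the pooled t-test
survives Benjamini-Hochberg at FDR < 0.05.  A time-course one-way ANOVA and
detection-mask-based induced-protein calling complete the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import select_samples
from .matrix import IntensityMatrix
from .stats import benjamini_hochberg


@dataclass
class DeRule:
    fold_change_min: float = 1.5     # linear scale
    q: float = 0.05
    timepoint: str = "T2"
    reference: str = "Ctrl"

    def __post_init__(self):
        if self.fold_change_min < 1:
            raise ValueError("fold_change_min must be >= 1")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")


def _group_values(matrix: IntensityMatrix, design, model, timepoint, fraction):
    cols = select_samples(design, model=model, timepoint=timepoint, fraction=fraction)
    cols = [c for c in cols if c in matrix.samples]
    if len(cols) < 2:
        raise ValueError(f"group ({model}, {timepoint}, {fraction}) has n < 2")
    return matrix.values[cols].to_numpy()


def de_contrast(matrix: IntensityMatrix, design: pd.DataFrame, model: str,
                rule: DeRule = DeRule(), fraction: str = "Total") -> pd.DataFrame:
    """Fold-change + t-test + BH contrast of one time point vs control.

    The log2 fold change is mean(T2) - mean(Ctrl) on the imputed log2 scale
    (a geometric-mean intensity ratio); significance requires both the BH
    q-value gate and the fold-change gate.
    """
    a = _group_values(matrix, design, model, rule.timepoint, fraction)
    b = _group_values(matrix, design, model, rule.reference, fraction)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t, p = sps.ttest_ind(a, b, axis=1, equal_var=True)
    # constant-in-both-groups rows: t undefined; identical means -> p = 1
    degen = ~np.isfinite(t)
    t[degen] = 0.0
    p[degen] = np.where(log2fc[degen] == 0.0, 1.0, 0.0)
    fdr = benjamini_hochberg(p, rule.q)
    fc_gate = np.abs(log2fc) >= math.log2(rule.fold_change_min)
    significant = fdr.rejected & fc_gate
    return pd.DataFrame({
        "log2fc": log2fc, "t": t, "p": p, "q": fdr.p_adjusted,
        "significant": significant,
        "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
    }, index=matrix.proteins)


def anova_time_course(matrix: IntensityMatrix, design: pd.DataFrame, model: str,
                      q: float = 0.05, fraction: str = "Total",
                      timepoints=None) -> pd.DataFrame:
    """Per-protein one-way ANOVA across time points, BH-corrected."""
    if timepoints is None:
        timepoints = [t for t in design["timepoint"].unique()]
    groups = [_group_values(matrix, design, model, tp, fraction) for tp in timepoints]
    if len(groups) < 2:
        raise ValueError("need >= 2 time-point groups")
    f, p = sps.f_oneway(*groups, axis=1)
    degen = ~np.isfinite(f)
    if degen.any():
        means = np.stack([g.mean(axis=1) for g in groups])
        same = np.ptp(means, axis=0) == 0.0
        f[degen] = 0.0
        p[degen & same] = 1.0
        p[degen & ~same] = 0.0
    fdr = benjamini_hochberg(p, q)
    return pd.DataFrame({"F": f, "p": p, "q": fdr.p_adjusted,
                         "significant": fdr.rejected}, index=matrix.proteins)


def detect_induced(mask: pd.DataFrame, design: pd.DataFrame, model: str,
                   min_detect_frac: float = 0.5,
                   fraction: str = "Total") -> set:
    """Proteins never detected in controls but detected at T1 and at T2.

    ``mask`` is the pre-imputation detection mask (True = observed).  A
    protein qualifies with zero control detections and at least
    ceil(min_detect_frac * n) detections at both fibrosis time points.
    """
    def cols(tp):
        return [c for c in select_samples(design, model=model, timepoint=tp,
                                          fraction=fraction) if c in mask.columns]
    ctrl = mask[cols("Ctrl")].sum(axis=1)
    out = pd.Series(True, index=mask.index)
    out &= ctrl == 0
    for tp in ("T1", "T2"):
        c = cols(tp)
        need = math.ceil(min_detect_frac * len(c))
        out &= mask[c].sum(axis=1) >= need
    return set(mask.index[out])
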