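"""Proteome-histology correlation.

Each protein's control-baselined abundance profile across individual mice is
regressed on the mice's control-baselined fibrosis areas (sirius-red-positive
%).  The slope's p-value is BH-corrected per compartment, and significant
correlates are partitioned by sign across the Total and insoluble (E)
compartments — the "positive in both" set is the behaviour of interest for
proteins tracking scar formation and resolution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import select_samples
from .matrix import IntensityMatrix
from .stats import benjamini_hochberg


def mass_pearson(x: np.ndarray, y: np.ndarray):
    """Row-wise least-squares slope, Pearson r and slope p of y rows on x.

    ``x`` has shape (n,), ``y`` shape (m, n).  The slope p-value is the
    two-sided t-test with n-2 df, identical per row to the scalar
    ``stats.pearson_slope``.  Rows with zero variance get r=0, slope from the
    least-squares formula (0) and p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (xc ** 2).sum()
    sxy = yc @ xc
    syy = (yc ** 2).sum(axis=1)
    slope = sxy / sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    r = np.where(syy == 0, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2 * sps.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    p = np.where(syy == 0, 1.0, p)
    return slope, r, p


def baseline_deltas(matrix: IntensityMatrix, design: pd.DataFrame, model: str,
                    fraction: str = "Total") -> pd.DataFrame:
    """Per-sample log2 deltas from the protein's control-group mean."""
    cols = [c for c in select_samples(design, model=model, fraction=fraction)
            if c in matrix.samples]
    ctrl = [c for c in select_samples(design, model=model, timepoint="Ctrl",
                                      fraction=fraction) if c in matrix.samples]
    if not ctrl:
        raise ValueError(f"no control samples for model {model!r}")
    vals = matrix.values[cols]
    return vals.sub(vals[ctrl].mean(axis=1), axis=0)


def fibrosis_deltas(fibrosis: pd.DataFrame, model: str) -> pd.Series:
    """Per-mouse fibrosis-area deltas from the mean control area."""
    sub = fibrosis[fibrosis["model"] == model]
    ctrl = sub.loc[sub["timepoint"] == "Ctrl", "sr_area_pct"]
    if ctrl.empty:
        raise ValueError(f"no control areas for model {model!r}")
    out = sub.set_index("mouse_id")["sr_area_pct"] - ctrl.mean()
    out.name = "area_delta"
    return out


def correlate_proteome_fibrosis(protein_deltas: pd.DataFrame,
                                area_deltas: pd.Series,
                                design: pd.DataFrame,
                                include_controls: bool = False,
                                q: float = 0.05) -> pd.DataFrame:
    """Per-protein Pearson correlation and slope of abundance vs fibrosis area.

    Pairing is by mouse (terminal sampling: one time point per mouse).
    Controls are excluded by default since their deltas are centered at zero
    by construction.  Returns one record per protein with slope, r, the
    slope's p-value, and the BH-adjusted significance flag.
    """
    meta = design.set_index("sample_id")
    cols = [c for c in protein_deltas.columns if c in meta.index]
    mice = meta.loc[cols, "mouse"]
    tps = meta.loc[cols, "timepoint"]
    if not include_controls:
        cols = [c for c in cols if tps[c] != "Ctrl"]
        mice = mice[cols]
    x = area_deltas.reindex(mice.to_numpy()).to_numpy(dtype=float)
    ok = np.isfinite(x)
    cols = [c for c, k in zip(cols, ok) if k]
    x = x[ok]
    if len(cols) < 3:
        raise ValueError("need >= 3 paired (mouse, time) points")
    if np.var(x) == 0:
        raise ValueError("fibrosis-area deltas have zero variance")

    y = protein_deltas[cols].to_numpy(dtype=float)
    n = len(cols)
    slope, r, p = mass_pearson(x, y)
    fdr = benjamini_hochberg(p, q)
    return pd.DataFrame({
        "slope": slope, "r": r, "p": p, "q_value": fdr.p_adjusted,
        "significant": fdr.rejected,
        "direction": np.where(slope > 0, "positive", "negative"),
        "n": n,
    }, index=protein_deltas.index)


def classify_correlates(records_total: pd.DataFrame,
                        records_e: pd.DataFrame) -> dict[str, set]:
    """Partition significant correlates by sign across the two compartments."""
    def sig(records, direction):
        m = records["significant"] & (records["direction"] == direction)
        return set(records.index[m])

    pos_t, pos_e = sig(records_total, "positive"), sig(records_e, "positive")
    neg_t, neg_e = sig(records_total, "negative"), sig(records_e, "negative")
    any_t = pos_t | neg_t
    any_e = pos_e | neg_e
    return {
        "positive_both": pos_t & pos_e,
        "negative_both": neg_t & neg_e,
        "total_specific": any_t - any_e,
        "e_specific": any_e - any_t,
    }
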