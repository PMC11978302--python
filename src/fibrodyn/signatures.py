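"""Cell-type signature dynamics from published marker sets.

Each signature's score in a mouse is the mean z-scored intensity of its
resolved marker proteins; group statistics (one-way ANOVA across time points
with a Bonferroni post-test against controls) are computed on the six
mouse-level scores per group so the degrees of freedom reflect animals, not
pooled replicates.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .matrix import IntensityMatrix
from .stats import bonferroni_posttest, one_way_anova


def signature_scores(zmatrix: IntensityMatrix, design: pd.DataFrame,
                     signatures: dict[str, list],
                     fraction: str = "Total") -> pd.DataFrame:
    """Long-format table of per-mouse signature scores.

    Columns: signature, model, timepoint, mouse, score, n_resolved.
    Signatures with no resolved proteins are skipped with a warning.
    """
    meta = design.set_index("sample_id")
    cols = [c for c in zmatrix.samples
            if c in meta.index and meta.loc[c, "fraction"] == fraction]
    rows = []
    for name, members in signatures.items():
        resolved = [p for p in members if p in zmatrix.proteins]
        if not resolved:
            warnings.warn(f"signature {name!r}: no members resolved; skipped")
            continue
        sub = zmatrix.values.loc[resolved, cols]
        means = sub.mean(axis=0)
        for c in cols:
            rows.append({"signature": name, "model": meta.loc[c, "model"],
                         "timepoint": meta.loc[c, "timepoint"],
                         "mouse": meta.loc[c, "mouse"],
                         "score": means[c], "n_resolved": len(resolved)})
    return pd.DataFrame(rows)


def signature_tests(scores: pd.DataFrame, reference: str = "Ctrl",
                    timepoints=None) -> pd.DataFrame:
    """ANOVA across time points plus Bonferroni post-test vs control.

    One row per (signature, model, timepoint != reference) with the omnibus
    ANOVA p and the Bonferroni-adjusted pairwise p against the reference.
    """
    rows = []
    for (sig, model), grp in scores.groupby(["signature", "model"], sort=False):
        tps = timepoints or [t for t in grp["timepoint"].unique()]
        groups = [grp.loc[grp["timepoint"] == t, "score"].to_numpy() for t in tps]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            continue
        omnibus = one_way_anova(groups)
        ref_idx = tps.index(reference)
        posts = bonferroni_posttest(groups, reference=ref_idx)
        for res in posts:
            tp = tps[res.extra["group"]]
            rows.append({"signature": sig, "model": model, "timepoint": tp,
                         "anova_F": omnibus.statistic, "anova_p": omnibus.p_value,
                         "diff_vs_ctrl": res.effect, "p_raw": res.extra["p_raw"],
                         "p_adjusted": res.p_value})
    return pd.DataFrame(rows)
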