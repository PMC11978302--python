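"""Study design: mapping intensity columns to (model, time point, fraction, mouse).

The experimental layout is two mouse liver-fibrosis models (hepatotoxic
"CCl4like" and cholestatic "DDClike"), sampled terminally at five time points
(untreated controls, two fibrosis-progression points T1/T2 and two resolution
points T3/T4), with three protein compartments per animal: the whole lysate
("Total"), the detergent-soluble supernatant ("S") and the detergent-insoluble
ECM-enriched pellet ("E").
"""

from __future__ import annotations

import pandas as pd

MODELS = ("CCl4like", "DDClike")
TIMEPOINTS = ("Ctrl", "T1", "T2", "T3", "T4")
FRACTIONS = ("Total", "S", "E")

DESIGN_COLUMNS = ["sample_id", "model", "timepoint", "fraction", "mouse"]


def make_design(models=MODELS, timepoints=TIMEPOINTS, fractions=FRACTIONS,
                n_mice: int = 6) -> pd.DataFrame:
    """Build a full-factorial design table with terminal sampling.

    Each mouse belongs to exactly one (model, time point) group and
    contributes one sample per fraction.
    """
    rows = []
    for model in models:
        for tp in timepoints:
            for m in range(1, n_mice + 1):
                mouse = f"{model}_{tp}_m{m}"
                for frac in fractions:
                    rows.append({
                        "sample_id": f"{mouse}_{frac}",
                        "model": model,
                        "timepoint": tp,
                        "fraction": frac,
                        "mouse": mouse,
                    })
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def validate_design(design: pd.DataFrame) -> None:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table lacks columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design table")


def select_samples(design: pd.DataFrame, model: str | None = None,
                   timepoint: str | None = None,
                   fraction: str | None = None) -> list[str]:
    """Sample ids matching the given (model, timepoint, fraction) slice."""
    sel = pd.Series(True, index=design.index)
    if model is not None:
        sel &= design["model"] == model
    if timepoint is not None:
        sel &= design["timepoint"] == timepoint
    if fraction is not None:
        sel &= design["fraction"] == fraction
    return design.loc[sel, "sample_id"].tolist()


def group_samples(design: pd.DataFrame, by: list[str],
                  fraction: str | None = None) -> dict[tuple, list[str]]:
    """Group sample ids by the given design columns (e.g. ["model", "timepoint"])."""
    d = design if fraction is None else design[design["fraction"] == fraction]
    return {key if isinstance(key, tuple) else (key,): grp["sample_id"].tolist()
            for key, grp in d.groupby(by, sort=False)}
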