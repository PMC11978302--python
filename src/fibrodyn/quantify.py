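"""Fraction-aware label-free protein quantification.

Per-sample proportional coefficients are estimated from peptides shared
between samples — the delayed-normalization construction: for every sample
pair the median log-ratio of commonly observed unique+razor peptides defines
a pairwise target, and the per-sample log coefficients are the least-squares
solution of that pairwise system, gauged so the coefficients' geometric mean
is 1.  Protein intensity is then the sum of coefficient-normalized peptide
intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

DEFAULT_EVIDENCE_CLASSES = frozenset({"unique", "razor"})
KNOWN_EVIDENCE_CLASSES = frozenset({"unique", "razor", "other"})


class DisconnectedDesignError(ValueError):
    """No pair of samples shares any peptide: coefficients are unidentifiable."""


@dataclass
class ProportionalCoefficients:
    coefficients: pd.Series       # sample id -> positive multiplier
    connected: pd.Series          # sample id -> bool (False: defaulted to 1)
    gauge: str = "geometric_mean_1"


def _peptide_intensity_block(peptides: pd.DataFrame, samples,
                             classes) -> pd.DataFrame:
    unknown = set(classes) - KNOWN_EVIDENCE_CLASSES
    if unknown:
        raise ValueError(f"unknown evidence class requested: {sorted(unknown)}")
    sel = peptides["evidence_class"].isin(classes)
    return peptides.loc[sel, list(samples)].astype(float)


def estimate_proportional_coefficients(
        peptides: pd.DataFrame, samples,
        classes=DEFAULT_EVIDENCE_CLASSES,
        min_shared: int = 1) -> ProportionalCoefficients:
    """Least-squares proportional coefficients from pairwise median log-ratios.

    Parameters
    ----------
    peptides
        Peptide table with columns ``peptide_id``, ``protein_id``,
        ``evidence_class`` and one linear-scale intensity column per sample
        (NaN for missing).
    samples
        The sample ids to solve jointly (e.g. one S/E pair, or all samples of
        a fraction).
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    block = _peptide_intensity_block(peptides, samples, classes)
    logs = np.log2(block.where(block > 0)).to_numpy()

    n = len(samples)
    rows, rhs = [], []
    adj = np.zeros((n, n), dtype=bool)
    for i, j in combinations(range(n), 2):
        both = np.isfinite(logs[:, i]) & np.isfinite(logs[:, j])
        if both.sum() < min_shared:
            continue
        m_ij = np.median(logs[both, j] - logs[both, i])
        row = np.zeros(n)
        row[i], row[j] = 1.0, -1.0
        rows.append(row)
        rhs.append(m_ij)
        adj[i, j] = adj[j, i] = True

    if not rows:
        raise DisconnectedDesignError("no shared peptides between any sample pair")

    a = np.vstack(rows)
    x, *_ = np.linalg.lstsq(a, np.asarray(rhs), rcond=None)

    # gauge each connected component to geometric mean 1; isolated samples -> 1
    comp = _components(adj)
    connected = pd.Series(True, index=samples)
    for members in comp:
        if len(members) == 1:
            x[members[0]] = 0.0
            connected.iloc[members[0]] = False
            warnings.warn(
                f"sample {samples[members[0]]!r} shares no peptides; coefficient set to 1")
        else:
            x[members] -= x[members].mean()
    coeffs = pd.Series(np.exp2(x), index=samples, name="coefficient")
    return ProportionalCoefficients(coefficients=coeffs, connected=connected)


def _components(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, members = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            members.append(u)
            for v in np.nonzero(adj[u])[0]:
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        comps.append(sorted(members))
    return comps


def assemble_protein_intensity(peptides: pd.DataFrame,
                               coeffs: ProportionalCoefficients,
                               classes=DEFAULT_EVIDENCE_CLASSES) -> pd.DataFrame:
    """Protein intensity = sum of coefficient-normalized peptide intensities.

    Linear scale; a protein with no observed peptide in a sample is missing
    (NaN), never zero.
    """
    samples = coeffs.coefficients.index.tolist()
    block = _peptide_intensity_block(peptides, samples, classes)
    scaled = block.mul(coeffs.coefficients, axis=1)
    scaled.insert(0, "protein_id", peptides.loc[scaled.index, "protein_id"])
    grouped = scaled.groupby("protein_id", sort=True)
    sums = grouped.sum(min_count=1)   # all-NaN stays NaN, not 0
    sums.index.name = "protein_id"
    return sums
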