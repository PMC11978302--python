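"""Statistical primitives shared by every analysis stage.

Thin, defensively wrapped versions of the classical tests the pipeline needs:
pooled-variance Student t-test, one-way ANOVA with a pooled-variance
Bonferroni post-test, Kruskal-Wallis with Dunn's post-test, Fisher's exact
test, Pearson correlation with the least-squares slope and its p-value, and
Benjamini-Hochberg step-up FDR control.

Degenerate inputs (zero variance, empty margins) never raise from inside a
per-protein loop; they return boundary p-values with a warning so that a
genome-scale scan survives constant rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult", "FdrResult", "benjamini_hochberg", "student_t_test",
    "one_way_anova", "bonferroni_posttest", "kruskal_wallis_dunn",
    "fisher_exact", "pearson_slope",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | tuple | None = None
    effect: float | None = None      # mean difference, slope, r, or odds ratio
    extra: dict = field(default_factory=dict)


@dataclass
class FdrResult:
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray
    q: float


def benjamini_hochberg(pvalues, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up FDR control at level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return FdrResult(p, np.array([]), np.array([], dtype=bool), q)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FdrResult(p, p_adj, rejected, q)


def student_t_test(a, b, two_sided: bool = True, equal_var: bool = True) -> TestResult:
    """Unpaired Student t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    diff = a.mean() - b.mean()
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if equal_var and pooled == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, df, 0.0)
        warnings.warn("zero pooled variance with unequal means; p set to 0")
        return TestResult(np.inf * np.sign(diff), 0.0, df, diff)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if not two_sided:
        p = p / 2 if t > 0 else 1 - p / 2
    return TestResult(float(t), float(p), df, float(diff))


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA across >= 2 groups."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    n = sum(g.size for g in gs)
    k = len(gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df = (k - 1, n - k)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(0.0, 1.0, df, 0.0)
        warnings.warn("zero within-group variance with unequal means; p set to 0")
        return TestResult(np.inf, 0.0, df, ss_between)
    f, p = sps.f_oneway(*gs)
    return TestResult(float(f), float(p), df, float(ss_between / (k - 1)))


def bonferroni_posttest(groups, reference: int = 0) -> list[TestResult]:
    """Pairwise t-tests of each group vs the reference group.

    Uses the pooled within-group variance of *all* groups (the classical
    post-ANOVA comparison) with N-k degrees of freedom; raw p-values are
    multiplied by the number of comparisons and capped at 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if not 0 <= reference < len(gs):
        raise IndexError("reference group index out of range")
    n = sum(g.size for g in gs)
    k = len(gs)
    df = n - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in gs) / df
    n_comp = k - 1
    ref = gs[reference]
    out = []
    for i, g in enumerate(gs):
        if i == reference:
            continue
        diff = g.mean() - ref.mean()
        se = np.sqrt(msw * (1.0 / g.size + 1.0 / ref.size))
        if se == 0.0:
            t, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        else:
            t = diff / se
            p = 2 * sps.t.sf(abs(t), df)
        out.append(TestResult(float(t), float(min(1.0, p * n_comp)), df,
                              float(diff), {"group": i, "p_raw": float(p)}))
    return out


def kruskal_wallis_dunn(groups, adjust: str = "bonferroni",
                        reference: int | None = None):
    """Kruskal-Wallis H test (tie-corrected) with Dunn's pairwise post-test.

    Dunn z statistics compare mean ranks from the joint ranking; the p
    adjustment is Bonferroni by default (BH available).  When ``reference``
    is given only comparisons against that group are made.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(gs)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        omnibus = TestResult(0.0, 1.0, len(gs) - 1, 0.0)
        pairs = _dunn_pairs(gs, reference)
        return omnibus, [TestResult(0.0, 1.0, None, 0.0, {"pair": pr}) for pr in pairs]
    h, p = sps.kruskal(*gs)
    omnibus = TestResult(float(h), float(p), len(gs) - 1, float(h))

    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in gs]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(len(gs))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    pairs = _dunn_pairs(gs, reference)
    raw = []
    for (i, j) in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        raw.append((z, 2 * sps.norm.sf(abs(z))))
    m = len(pairs)
    results = []
    if adjust == "bonferroni":
        adj = [min(1.0, pr * m) for _, pr in raw]
    elif adjust == "bh":
        adj = benjamini_hochberg([pr for _, pr in raw], 0.05).p_adjusted.tolist()
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for (pair, (z, pr), pa) in zip(pairs, raw, adj):
        results.append(TestResult(float(z), float(pa), None, float(z),
                                  {"pair": pair, "p_raw": float(pr)}))
    return omnibus, results


def _dunn_pairs(gs, reference):
    if reference is None:
        return list(combinations(range(len(gs)), 2))
    if not 0 <= reference < len(gs):
        raise IndexError("reference group index out of range")
    return [(i, reference) for i in range(len(gs)) if i != reference]


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Two-sided p sums the probabilities of all tables (with the observed
    margins) whose hypergeometric probability does not exceed the observed
    table's.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        # a zero margin carries no information
        odds = np.nan
        return TestResult(odds, 1.0, (2, 2), odds)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(float(odds), float(p), (2, 2), float(odds))


def pearson_slope(x, y) -> TestResult:
    """Pearson r plus the least-squares slope and its two-sided p-value.

    The slope p-value is the t-test of slope/SE with n-2 df, which for
    simple linear regression coincides with the test of r = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    if np.var(y) == 0:
        warnings.warn("y has zero variance; returning r=0, slope=0, p=1")
        return TestResult(0.0, 1.0, x.size - 2, 0.0,
                          {"r": 0.0, "slope": 0.0, "intercept": float(y.mean())})
    res = sps.linregress(x, y)
    return TestResult(float(res.rvalue), float(res.pvalue), x.size - 2,
                      float(res.slope),
                      {"r": float(res.rvalue), "slope": float(res.slope),
                       "intercept": float(res.intercept),
                       "stderr": float(res.stderr)})
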