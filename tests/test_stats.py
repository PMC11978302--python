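"""Statistical primitives against independently coded textbook oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb
from scipy.stats import f as f_dist
from scipy.stats import norm, t as t_dist

from fibrodyn.stats import (benjamini_hochberg, bonferroni_posttest,
                            fisher_exact, kruskal_wallis_dunn, one_way_anova,
                            pearson_slope, student_t_test)

# ---------------------------------------------------------------- oracles


def bh_oracle(p, q):
    """Literal step-up: reject the largest k with p_(k) <= k*q/m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    adj = np.empty(m)
    running = 1.0
    for k in range(m, 0, -1):
        running = min(running, p[order[k - 1]] * m / k)
        adj[order[k - 1]] = running
    return reject, adj


def t_oracle(a, b):
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


def anova_oracle(groups):
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return f, f_dist.sf(f, k - 1, n - k)


def fisher_oracle(table):
    """Two-sided p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(1.0, total)


def kw_oracle(groups):
    """Tie-corrected H by the rank formula."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    s = pooled[order]
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    idx = np.cumsum([0] + [len(g) for g in groups])
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * ranks[idx[i]:idx[i + 1]].mean() ** 2
        for i, g in enumerate(groups)) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie


# ---------------------------------------------------------------- BH


def test_bh_matches_stepup_oracle_on_random_vectors(rng):
    for _ in range(1000):
        m = int(rng.integers(1, 201))
        p = rng.random(m) ** rng.uniform(0.5, 3)
        q = float(rng.uniform(0.01, 0.2))
        res = benjamini_hochberg(p, q)
        rej, adj = bh_oracle(p, q)
        assert np.array_equal(res.rejected, rej)
        assert np.allclose(res.p_adjusted, adj, atol=1e-12)


@pytest.mark.parametrize("p, q, n_rej, adj0", [
    ([0.01, 0.02, 0.03, 0.04, 0.05], 0.05, 5, 0.05),
    ([0.04], 0.05, 1, 0.04),
    ([1.0, 1.0, 1.0], 0.05, 0, 1.0),
])
def test_bh_known_cases(p, q, n_rej, adj0):
    res = benjamini_hochberg(p, q)
    assert res.rejected.sum() == n_rej
    assert res.p_adjusted[0] == pytest.approx(adj0)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
       st.floats(0.01, 0.3), st.floats(0.01, 0.3))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_bh_monotone_in_q(p, q1, q2):
    lo, hi = sorted([q1, q2])
    assert benjamini_hochberg(p, lo).rejected.sum() <= \
        benjamini_hochberg(p, hi).rejected.sum()


def test_bh_adjusted_at_least_raw(rng):
    p = rng.random(100)
    res = benjamini_hochberg(p, 0.05)
    assert (res.p_adjusted >= res.p_raw - 1e-15).all()


# ---------------------------------------------------------------- t-test


def test_t_test_matches_textbook_formula(rng):
    for _ in range(100):
        a = rng.normal(size=int(rng.integers(2, 12)))
        b = rng.normal(size=int(rng.integers(2, 12)))
        res = student_t_test(a, b)
        t, p = t_oracle(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


def test_t_test_degenerate_branches():
    res = student_t_test([1, 2, 3], [1, 2, 3])
    assert res.p_value == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        res = student_t_test([0, 0, 0], [1, 1, 1])
    assert res.p_value == 0.0


# ---------------------------------------------------------------- ANOVA


def test_anova_matches_textbook_formula(rng):
    for _ in range(100):
        k = int(rng.integers(2, 6))
        groups = [rng.normal(size=int(rng.integers(2, 9))) for _ in range(k)]
        res = one_way_anova(groups)
        f, p = anova_oracle(groups)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


def test_anova_two_groups_equals_t_squared(rng):
    a, b = rng.normal(size=6), rng.normal(size=6)
    res_f = one_way_anova([a, b])
    res_t = student_t_test(a, b)
    assert res_f.statistic == pytest.approx(res_t.statistic ** 2, abs=1e-10)
    assert res_f.p_value == pytest.approx(res_t.p_value, abs=1e-10)


def test_anova_identical_groups():
    res = one_way_anova([[1, 2, 3], [1, 2, 3]])
    assert res.statistic == 0.0 and res.p_value == 1.0


# ---------------------------------------------------------------- Bonferroni post-test


def test_bonferroni_posttest_scales_raw_p(rng):
    groups = [rng.normal(loc=i * 0.3, size=6) for i in range(5)]
    posts = bonferroni_posttest(groups, reference=0)
    assert len(posts) == 4
    for res in posts:
        assert res.p_value == pytest.approx(min(1.0, 4 * res.extra["p_raw"]))
        assert res.p_value >= res.extra["p_raw"]


def test_bonferroni_posttest_two_groups_unadjusted(rng):
    groups = [rng.normal(size=6), rng.normal(size=6)]
    (res,) = bonferroni_posttest(groups, reference=0)
    assert res.p_value == pytest.approx(res.extra["p_raw"])


def test_bonferroni_posttest_identical_groups():
    posts = bonferroni_posttest([[1, 2, 3]] * 4, reference=0)
    assert all(r.p_value == 1.0 for r in posts)


def test_bonferroni_posttest_bad_reference():
    with pytest.raises(IndexError):
        bonferroni_posttest([[1, 2], [3, 4]], reference=5)


# ---------------------------------------------------------------- Kruskal-Wallis / Dunn


def test_kruskal_matches_rank_formula_oracle(rng):
    for _ in range(100):
        k = int(rng.integers(2, 5))
        groups = [np.round(rng.normal(size=int(rng.integers(3, 9))), 1)
                  for _ in range(k)]
        if np.all(np.concatenate(groups) == np.concatenate(groups)[0]):
            continue
        omnibus, _ = kruskal_wallis_dunn(groups)
        assert omnibus.statistic == pytest.approx(kw_oracle(groups), abs=1e-8)


def test_kruskal_constant_groups_p_one():
    omnibus, dunn = kruskal_wallis_dunn([[2.0, 2.0], [2.0, 2.0, 2.0]])
    assert omnibus.p_value == 1.0
    assert all(r.p_value == 1.0 for r in dunn)


def test_dunn_hand_computed_z():
    # two groups of 3 with complete separation: mean ranks 2 and 5, N=6
    groups = [[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]]
    _, dunn = kruskal_wallis_dunn(groups)
    se = math.sqrt(6 * 7 / 12 * (1 / 3 + 1 / 3))
    z_expect = (2.0 - 5.0) / se
    assert dunn[0].statistic == pytest.approx(z_expect, abs=1e-10)
    assert dunn[0].extra["p_raw"] == pytest.approx(2 * norm.sf(abs(z_expect)), abs=1e-10)


def test_dunn_permutation_symmetry(rng):
    groups = [rng.normal(size=5), rng.normal(1, size=5), rng.normal(2, size=5)]
    _, d1 = kruskal_wallis_dunn(groups)
    _, d2 = kruskal_wallis_dunn(groups[::-1])
    p1 = sorted(round(r.p_value, 12) for r in d1)
    p2 = sorted(round(r.p_value, 12) for r in d2)
    assert p1 == p2


# ---------------------------------------------------------------- Fisher


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(100):
        table = rng.integers(0, 15, size=(2, 2))
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            continue
        res = fisher_exact(table)
        assert res.p_value == pytest.approx(fisher_oracle(table), abs=1e-10)


def test_fisher_balanced_and_symmetry():
    assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)
    t = [[3, 8], [9, 2]]
    assert fisher_exact(t).p_value == pytest.approx(
        fisher_exact(np.array(t).T).p_value, abs=1e-12)


def test_fisher_zero_margin():
    assert fisher_exact([[0, 0], [3, 4]]).p_value == 1.0


# ---------------------------------------------------------------- Pearson/slope


def test_pearson_exact_linearity():
    res = pearson_slope([1, 2, 3], [2, 4, 6])
    assert res.extra["r"] == pytest.approx(1.0)
    assert res.extra["slope"] == pytest.approx(2.0)


def test_pearson_slope_matches_definition(rng):
    x = rng.normal(size=30)
    y = 0.7 * x + rng.normal(size=30)
    res = pearson_slope(x, y)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    r = np.corrcoef(x, y)[0, 1]
    assert res.extra["slope"] == pytest.approx(slope, abs=1e-12)
    assert res.extra["r"] == pytest.approx(r, abs=1e-12)
    t = r * math.sqrt(28 / (1 - r ** 2))
    assert res.p_value == pytest.approx(2 * t_dist.sf(abs(t), 28), abs=1e-12)


def test_pearson_null_p_uniform(rng):
    ps = []
    for _ in range(300):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        ps.append(pearson_slope(x, y).p_value)
    from scipy.stats import kstest
    assert kstest(ps, "uniform").pvalue > 0.01


def test_pearson_degenerate_y():
    with pytest.warns(UserWarning):
        res = pearson_slope([1, 2, 3], [5, 5, 5])
    assert res.extra["r"] == 0.0 and res.p_value == 1.0
    with pytest.raises(ValueError):
        pearson_slope([1, 1, 1], [1, 2, 3])
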