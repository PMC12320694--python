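"""Nonparametric tests against brute-force enumeration oracles and scipy.

The oracles here recompute each statistic and exact p-value from first
principles (pair counting, explicit permutation/sign/labeling enumeration,
hand ANOVA) so they share no code with the implementation.
"""

import itertools

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st

from lymphoti.stats import (
    ConstantInputError,
    holm_adjust,
    icc_intrarater,
    kruskal_wallis,
    mann_whitney,
    spearman,
    wilcoxon_signed_rank,
)

rng = np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# oracles (independent implementations)
# ---------------------------------------------------------------------------

def oracle_midranks(x):
    x = list(x)
    return [1 + sum(xj < xi for xj in x) + 0.5 * (sum(xj == xi for xj in x) - 1) for xi in x]


def oracle_spearman_rho(x, y):
    rx, ry = oracle_midranks(x), oracle_midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def oracle_spearman_p(x, y):
    obs = abs(oracle_spearman_rho(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(oracle_spearman_rho(x, perm)) >= obs - 1e-12:
            hits += 1
    return hits / total


def oracle_u(a, b):
    return sum(1.0 if ai > bi else 0.5 if ai == bi else 0.0 for ai in a for bi in b)


def oracle_mw_p(a, b):
    pooled = list(a) + list(b)
    na = len(a)
    mu = na * len(b) / 2.0
    obs = abs(oracle_u(a, b) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(oracle_u(ga, gb) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def oracle_wilcoxon(pre, post):
    d = [p - q for p, q in zip(pre, post) if p != q]
    r = oracle_midranks([abs(x) for x in d])
    w_obs = sum(ri for ri, di in zip(r, d) if di > 0)
    mu = sum(r) / 2.0
    hits = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(ri for ri, s in zip(r, signs) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return w_obs, hits / total


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_perfect_monotone():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
    assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)


@pytest.mark.parametrize(
    "x, y",
    [
        ([1, 2, 2, 3, 4], [5, 3, 4, 4, 1]),
        ([1, 1, 2, 3], [2, 2, 2, 1]),
        ([3, 1, 4, 1, 5, 9], [2, 7, 1, 8, 2, 8]),
        ([1, 2, 3, 4, 5, 6, 7], [3, 1, 4, 1, 5, 9, 2]),
    ],
)
def test_spearman_exact_vs_enumeration_oracle(x, y):
    r = spearman(x, y)
    assert r.method == "spearman-exact"
    assert r.rho == pytest.approx(oracle_spearman_rho(x, y))
    assert r.p_value == pytest.approx(oracle_spearman_p(x, y))


def test_spearman_large_n_matches_scipy_t_approximation():
    x = rng.normal(size=40)
    y = x + rng.normal(size=40)
    r = spearman(x, y)
    ref = sps.spearmanr(x, y)
    assert r.rho == pytest.approx(ref.statistic)
    assert r.p_value == pytest.approx(ref.pvalue)


@given(st.lists(st.integers(0, 50), min_size=10, max_size=25))
def test_spearman_invariant_under_monotone_transform(xs):
    ys = [(x - 20) ** 3 for x in xs]  # strictly monotone transform of x
    if len(set(xs)) < 2:
        return
    a = spearman(xs, ys)
    b = spearman([np.exp(0.1 * x) for x in xs], ys)
    assert a.rho == pytest.approx(b.rho)
    assert a.p_value == pytest.approx(b.p_value)


def test_spearman_constant_vector_errors():
    with pytest.raises(ConstantInputError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mann_whitney_direct_count():
    r = mann_whitney([1, 2], [3, 4])
    assert r.statistic == 0.0


def test_mann_whitney_symmetric_configuration_p_one():
    assert mann_whitney([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)


@pytest.mark.parametrize(
    "a, b",
    [
        ([1, 2], [3, 4]),
        ([1, 2, 2], [2, 3, 4, 4]),
        ([5, 1, 3], [2, 2, 4, 6, 0]),
        ([1, 1, 1, 2], [1, 2, 2, 3]),
    ],
)
def test_mann_whitney_exact_vs_enumeration_oracle(a, b):
    r = mann_whitney(a, b)
    assert r.method == "mann-whitney-exact"
    assert r.statistic == pytest.approx(oracle_u(a, b))
    assert r.p_value == pytest.approx(oracle_mw_p(a, b))


def test_mann_whitney_large_n_matches_scipy_asymptotic():
    a = rng.normal(size=18)
    b = rng.normal(size=22) + 0.4
    r = mann_whitney(a, b)
    ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
    assert r.statistic == pytest.approx(ref.statistic)
    assert r.p_value == pytest.approx(ref.pvalue)


def test_mann_whitney_empty_group_errors():
    with pytest.raises(ValueError):
        mann_whitney([], [1, 2, 3])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_wilcoxon_identical_pairs_error():
    with pytest.raises(ConstantInputError):
        wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])


def test_wilcoxon_single_nonzero_difference():
    r = wilcoxon_signed_rank([1, 2, 3, 5], [1, 2, 3, 4])
    assert r.p_value == pytest.approx(1.0)  # two equally likely sign assignments


@pytest.mark.parametrize(
    "pre, post",
    [
        ([5, 3, 8, 4, 9, 2], [4, 4, 5, 4, 3, 3]),
        ([1.5, 2.5, 3.5, 2.0, 6.0], [1.0, 3.0, 1.0, 2.0, 2.0]),
        ([2, 2, 2, 5, 7, 9, 1], [1, 3, 4, 1, 1, 2, 2]),
    ],
)
def test_wilcoxon_exact_vs_sign_enumeration_oracle(pre, post):
    r = wilcoxon_signed_rank(pre, post)
    assert r.method == "wilcoxon-exact"
    w_oracle, p_oracle = oracle_wilcoxon(pre, post)
    assert r.statistic == pytest.approx(w_oracle)
    assert r.p_value == pytest.approx(p_oracle)


def test_wilcoxon_large_n_matches_scipy_normal_approximation():
    pre = rng.normal(size=30)
    post = pre + rng.normal(size=30) * 0.8 - 0.3
    r = wilcoxon_signed_rank(pre, post)
    ref = sps.wilcoxon(pre, post, correction=False, mode="approx")
    assert r.p_value == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kruskal_wallis_all_tied_is_null():
    r = kruskal_wallis([[2, 2], [2, 2, 2]])
    assert r.statistic == 0.0 and r.p_value == 1.0


def test_kruskal_wallis_hand_computed_three_groups():
    # groups (1,2), (3,4), (5,6): ranks 1..6, rank sums 3/7/11
    # H = 12/(6*7) * (3^2/2 + 7^2/2 + 11^2/2) - 3*7 = 32/7
    r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert r.statistic == pytest.approx(32 / 7)
    assert r.p_value == pytest.approx(float(sps.chi2.sf(32 / 7, 2)))


def test_kruskal_wallis_two_groups_equals_squared_normal_mann_whitney():
    a = rng.normal(size=12)
    b = rng.normal(size=14) + 0.6
    h = kruskal_wallis([a, b])
    u = mann_whitney(a, b)
    z = sps.norm.isf(u.p_value / 2.0)
    assert h.statistic == pytest.approx(z * z, rel=1e-9)


def test_kruskal_wallis_matches_scipy():
    groups = [rng.normal(size=9), rng.normal(size=11) + 0.3, rng.normal(size=8) - 0.2]
    r = kruskal_wallis(groups)
    ref = sps.kruskal(*groups)
    assert r.statistic == pytest.approx(ref.statistic)
    assert r.p_value == pytest.approx(ref.pvalue)


def test_kruskal_wallis_needs_two_groups():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_identical_readings_is_one():
    assert icc_intrarater([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == pytest.approx(1.0)


def test_icc_independent_noise_near_zero():
    n = 10_000
    r1 = rng.normal(size=n)
    r2 = rng.normal(size=n) * 10
    assert abs(icc_intrarater(r1, r2)) < 0.05


def test_icc_hand_anova_decomposition():
    r1 = [9.0, 6.0, 8.0, 7.0, 10.0, 6.0]
    r2 = [2.0, 1.0, 4.0, 1.0, 5.0, 2.0]
    y = np.array([r1, r2]).T
    n, k = y.shape
    grand = y.mean()
    msr = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = ((y - y.mean(axis=1, keepdims=True) - y.mean(axis=0) + grand) ** 2).sum() / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
    assert icc_intrarater(r1, r2) == pytest.approx(expected)


def test_icc_matches_pingouin_absolute_agreement_single():
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    r1 = rng.normal(loc=20, scale=8, size=25)
    r2 = r1 + rng.normal(scale=1.5, size=25)
    df = pd.DataFrame(
        {
            "subject": list(range(25)) * 2,
            "rater": ["a"] * 25 + ["b"] * 25,
            "score": np.concatenate([r1, r2]),
        }
    )
    table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    mask = table["Type"].isin(["ICC(A,1)", "ICC2"])  # absolute agreement, single measure
    ref = float(table.loc[mask, "ICC"].iloc[0])
    assert icc_intrarater(r1, r2) == pytest.approx(ref)


def test_icc_constant_ratings_error():
    with pytest.raises(ConstantInputError):
        icc_intrarater([3, 3, 3], [3, 3, 3])


# ---------------------------------------------------------------------------
# Holm adjustment
# ---------------------------------------------------------------------------

def test_holm_adjustment_step_down():
    p = [0.01, 0.04, 0.03, 0.50]
    adj = holm_adjust(p)
    assert adj == pytest.approx([0.04, 0.09, 0.09, 0.50])
    assert holm_adjust([0.9, 0.95]) == pytest.approx([1.0, 1.0])
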