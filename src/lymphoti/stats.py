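"""Nonparametric statistics for small clinical cohorts.

Implements the tests the analysis pipeline relies on — Spearman rank
correlation, Mann-Whitney U, Wilcoxon signed-rank, Kruskal-Wallis and the
intra-rater ICC — with exact small-sample p-values where enumeration is
cheap and tie-corrected normal/chi-square approximations otherwise.  The
exact/approximate switch points are fixed constants:

* Spearman: full permutation null for n <= 9, else the t approximation
  with n-2 degrees of freedom;
* Mann-Whitney: enumeration of all C(n, n_a) group labelings for combined
  n <= 10, else the tie-corrected normal approximation (no continuity
  correction, so the two-group case matches Kruskal-Wallis via H = z^2);
* Wilcoxon signed-rank: enumeration of all 2^n sign assignments for n <= 15
  non-zero differences, else the normal approximation.

All p-values are two-sided, defined by the symmetric "at least as extreme"
criterion |T - E[T]| >= |T_obs - E[T]| under the permutation null, so
perfectly balanced configurations give p = 1.  scipy supplies only ranking
and the reference distributions (norm, t, chi2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata, t as t_dist

__all__ = [
    "ConstantInputError",
    "CorrelationResult",
    "TestResult",
    "spearman",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "icc_intrarater",
    "holm_adjust",
    "SPEARMAN_EXACT_MAX_N",
    "MANN_WHITNEY_EXACT_MAX_N",
    "WILCOXON_EXACT_MAX_N",
]

SPEARMAN_EXACT_MAX_N = 9
MANN_WHITNEY_EXACT_MAX_N = 10   # combined n
WILCOXON_EXACT_MAX_N = 15       # non-zero differences

_EPS = 1e-12  # tolerance when comparing permutation statistics for "as extreme"
_TINY_P = np.finfo(float).tiny  # keeps p in (0, 1] for degenerate asymptotics


class ConstantInputError(ValueError):
    """A statistic is undefined because an input has no variation."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "spearman"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple
    method: str


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size and not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def _clip_p(p: float) -> float:
    return float(min(max(p, _TINY_P), 1.0))


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xc * xc).sum()), np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    return float((xc * yc).sum() / (sx * sy))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Tie-corrected Spearman correlation with an exact null for tiny n.

    rho is the Pearson correlation of mid-ranks.  The p-value is exact
    (full permutation of one margin) for n <= 9 and otherwise uses the
    t approximation with n - 2 degrees of freedom.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    n = xa.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    rx, ry = rankdata(xa), rankdata(ya)
    rho = _pearson(rx, ry)
    if n <= SPEARMAN_EXACT_MAX_N:
        # Permute one margin; the denominator is permutation-invariant.
        perms = np.array(list(itertools.permutations(range(n))))
        dots = ry[perms] @ (rx - rx.mean())
        denom = np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
        rhos = dots / denom  # ry mean term cancels against centred rx
        p = float(np.mean(np.abs(rhos) >= abs(rho) - _EPS))
        method = "spearman-exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            stat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(t_dist.sf(abs(stat), n - 2))
        method = "spearman-t"
    return CorrelationResult(rho=rho, p_value=_clip_p(p), n=n, method=method)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_from_ranksum(ranksum: np.ndarray, n_a: int) -> np.ndarray:
    return ranksum - n_a * (n_a + 1) / 2.0


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts**3 - counts).sum())


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Mann-Whitney U test (two independent groups), two-sided.

    Exact by enumeration of group labelings when the combined sample size
    is at most 10 (ties handled naturally by enumerating the observed
    pooled values); otherwise the tie-corrected normal approximation.
    The reported statistic is U for the first group.
    """
    aa, bb = _as_1d(a, "a"), _as_1d(b, "b")
    n_a, n_b = aa.size, bb.size
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups must be non-empty")
    if n_a + n_b < 3:
        raise ValueError("need a combined sample of at least 3")
    pooled = np.concatenate([aa, bb])
    ranks = rankdata(pooled)
    u_obs = float(_u_from_ranksum(ranks[:n_a].sum(), n_a))
    mu = n_a * n_b / 2.0
    n = n_a + n_b
    if n <= MANN_WHITNEY_EXACT_MAX_N:
        combs = np.array(list(itertools.combinations(range(n), n_a)))
        u_all = _u_from_ranksum(ranks[combs].sum(axis=1), n_a)
        p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - _EPS))
        method = "mann-whitney-exact"
    else:
        var = n_a * n_b / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
        if var <= 0:
            p = 1.0  # everything tied: no evidence either way
        else:
            z = (u_obs - mu) / np.sqrt(var)
            p = 2.0 * float(norm.sf(abs(z)))
        method = "mann-whitney-normal"
    return TestResult(statistic=u_obs, p_value=_clip_p(p), n=(n_a, n_b), method=method)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(pre: Sequence[float], post: Sequence[float]) -> TestResult:
    """Wilcoxon signed-rank test for paired samples, two-sided.

    Zero differences are dropped (all-zero input is an error).  Exact by
    enumeration of the 2^n sign assignments for n <= 15 non-zero
    differences, else the normal approximation with variance sum(r_i^2)/4
    (exact under mid-ranks, so ties need no separate correction).  The
    statistic is W+, the rank sum of positive differences.
    """
    pa, pb = _as_1d(pre, "pre"), _as_1d(post, "post")
    if pa.size != pb.size:
        raise ValueError(f"length mismatch: {pa.size} vs {pb.size}")
    d = pa - pb
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ConstantInputError("all paired differences are zero")
    r = rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    mu = r.sum() / 2.0
    if n <= WILCOXON_EXACT_MAX_N:
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_all = signs @ r
        p = float(np.mean(np.abs(w_all - mu) >= abs(w_plus - mu) - _EPS))
        method = "wilcoxon-exact"
    else:
        sd = np.sqrt((r * r).sum() / 4.0)
        z = (w_plus - mu) / sd
        p = 2.0 * float(norm.sf(abs(z)))
        method = "wilcoxon-normal"
    return TestResult(statistic=w_plus, p_value=_clip_p(p), n=(n,), method=method)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across k >= 2 groups.

    When every pooled observation is identical the tie correction
    degenerates; by convention H = 0 and p = 1.  Otherwise p is the
    chi-square tail with k - 1 degrees of freedom.
    """
    arrays = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    arrays = [g for g in arrays if g.size]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in arrays:
        rs = ranks[start : start + g.size].sum()
        h += rs * rs / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:
        return TestResult(statistic=0.0, p_value=1.0, n=tuple(g.size for g in arrays), method="kruskal-wallis")
    h /= correction
    h = max(h, 0.0)  # guard tiny negative round-off
    p = float(chi2.sf(h, k - 1))
    return TestResult(statistic=float(h), p_value=_clip_p(p), n=tuple(g.size for g in arrays), method="kruskal-wallis")


# ---------------------------------------------------------------------------
# Intra-rater ICC
# ---------------------------------------------------------------------------

def icc_intrarater(r1: Sequence[float], r2: Sequence[float]) -> float:
    """Single-measure, absolute-agreement ICC for two reading passes.

    Two-way mixed-effects model; computed from the ANOVA mean squares
    (rows = subjects, columns = readings):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with k = 2 readings.  Identical non-constant passes give exactly 1;
    constant ratings raise :class:`ConstantInputError`.
    """
    a, b = _as_1d(r1, "r1"), _as_1d(r2, "r2")
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    n = a.size
    if n < 3:
        raise ValueError(f"need at least 3 paired readings, got {n}")
    y = np.column_stack([a, b])
    k = 2
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    mse = ((y - row_means[:, None] - col_means[None, :] + grand) ** 2).sum() / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0:
        raise ConstantInputError("ICC undefined: ratings have no variance")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# Multiplicity
# ---------------------------------------------------------------------------

def holm_adjust(p_values: Sequence[float]) -> list:
    """Holm step-down adjustment of a family of p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank_idx, idx in enumerate(order):
        running = max(running, (m - rank_idx) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()
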