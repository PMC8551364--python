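"""Hypothesis tests and the multiple-testing correction used by the pipeline.

Every test is implemented here directly — exact Wilcoxon rank-sum by
enumeration of the Mann–Whitney null distribution, tie-corrected normal
approximations, Fisher's exact test by the sum-of-small-probabilities rule,
pooled two-sample t from summary statistics, Spearman rank correlation, the
Benjamini–Hochberg step-up, and the Jonckheere–Terpstra ordered-trend test
with both a tie-adjusted normal approximation and a seeded Monte-Carlo
permutation mode.  scipy supplies only distribution functions (normal, t,
hypergeometric pmf), never the tests themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as _dist


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_used: tuple[int, ...] = ()
    direction: int = 0  # sign of the effect: -1, 0, +1

    @property
    def valid(self) -> bool:
        return not np.isnan(self.p_value)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum / Mann-Whitney
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _mw_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of the Mann-Whitney U null distribution (no ties).

    ``counts[u]`` = number of arrangements with U statistic u; recursion
    f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u) built bottom-up.
    """
    max_u = n1 * n2
    # table[i][j] = polynomial coefficients over u for i of x, j of y
    prev = [np.ones(1, dtype=float) for _ in range(n2 + 1)]
    for i in range(1, n1 + 1):
        cur: list[np.ndarray] = [np.ones(1, dtype=float)]
        for j in range(1, n2 + 1):
            size = i * j + 1
            arr = np.zeros(size, dtype=float)
            # add an x as the largest element: contributes j to U
            arr[j:j + (i - 1) * j + 1] += prev[j]
            # add a y as the largest element: contributes 0
            arr[: i * (j - 1) + 1] += cur[j - 1]
            cur.append(arr)
        prev = cur
    counts = prev[n2]
    assert counts.size == max_u + 1
    return counts


def _ranks_with_ties(pooled: np.ndarray) -> np.ndarray:
    """Average ranks (midranks) of a 1-d array."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    n = len(pooled)
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    ``auto`` uses the exact null distribution when both samples have at most
    10 observations and the pooled data carry no ties, else the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size

    if np.all(pooled == pooled[0]):
        return TestResult(statistic=n1 * n2 / 2.0, p_value=1.0,
                          method="wilcoxon_rank_sum", n_used=(n1, n2), direction=0)

    ranks = _ranks_with_ties(pooled)
    w = ranks[:n1].sum()
    u = w - n1 * (n1 + 1) / 2.0  # Mann-Whitney U for x
    mean_u = n1 * n2 / 2.0

    if mode == "auto":
        mode = "exact" if (n1 <= 10 and n2 <= 10 and not has_ties) else "normal_tie_corrected"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        counts = _mw_null_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        p_lo = counts[: ui + 1].sum() / total
        p_hi = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    elif mode == "normal_tie_corrected":
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1.0))
        var_u = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
        if var_u <= 0:
            return TestResult(statistic=u, p_value=1.0, method="wilcoxon_rank_sum",
                              n_used=(n1, n2), direction=0)
        diff = u - mean_u
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var_u)  # continuity corrected
        p = min(1.0, 2.0 * _dist.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    med_diff = np.median(x) - np.median(y)
    direction = int(np.sign(med_diff)) if med_diff != 0 else int(np.sign(u - mean_u))
    return TestResult(statistic=float(u), p_value=float(p),
                      method=f"wilcoxon_rank_sum[{mode}]", n_used=(n1, n2),
                      direction=direction)


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Paired signed-rank variant (off by default downstream; the study's
    captions use the rank-sum test even for paired structures)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", (len(x), len(y)), 0)
    ranks = _ranks_with_ties(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var_w -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    z = (w_plus - mean_w - 0.5 * np.sign(w_plus - mean_w)) / np.sqrt(var_w)
    p = min(1.0, 2.0 * _dist.norm.sf(abs(z)))
    return TestResult(float(w_plus), float(p), "wilcoxon_signed_rank",
                      (len(x), len(y)), int(np.sign(w_plus - mean_w)))


# ---------------------------------------------------------------------------
# Fisher's exact test (2x2)
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test by the sum-of-small-probabilities rule.

    p = sum of hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative cell count")
    if not np.allclose(t, np.round(t)):
        raise ValueError("cell counts must be integers")
    a, b, c, d = (int(v) for v in np.round(t).ravel())
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        raise ValueError("all margins zero")
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = _dist.hypergeom.pmf(support, n, col1, row1)
    p_obs = _dist.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds_dir = int(np.sign(a * d - b * c))
    return TestResult(statistic=float(a), p_value=min(1.0, p),
                      method="fisher_exact", n_used=(row1, n - row1),
                      direction=odds_dir)


def fisher_exact_rxc_mc(table, n_draws: int = 9999, seed: int = 0) -> TestResult:
    """Monte-Carlo extension of Fisher's exact test to 2×k tables.

    Samples tables with the observed margins (via permutation of cluster
    labels) and counts how often the table probability is no larger than the
    observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    col_labels = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))

    def log_prob(tab: np.ndarray) -> float:
        from scipy.special import gammaln
        return float(gammaln(tab.sum(axis=1) + 1).sum()
                     + gammaln(tab.sum(axis=0) + 1).sum()
                     - gammaln(tab.sum() + 1) - gammaln(tab + 1).sum())

    obs = log_prob(t)
    hits = 0
    cols = col_labels.copy()
    for _ in range(n_draws):
        rng.shuffle(cols)
        tab = np.zeros_like(t)
        np.add.at(tab, (row_labels, cols), 1)
        if log_prob(tab) <= obs + 1e-9:
            hits += 1
    p = (1 + hits) / (1 + n_draws)
    return TestResult(statistic=obs, p_value=p, method="fisher_exact_mc",
                      n_used=tuple(t.sum(axis=1)), direction=0)


# ---------------------------------------------------------------------------
# pooled two-sample t from summary statistics
# ---------------------------------------------------------------------------

def pooled_t_from_summary(mean1: float, sd1: float, n1: int,
                          mean2: float, sd2: float, n2: int) -> TestResult:
    """Student's pooled-variance two-sample t-test from printed summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative standard deviation")
    direction = int(np.sign(mean1 - mean2))
    if sd1 == 0 and sd2 == 0:
        p = 1.0 if mean1 == mean2 else 0.0
        return TestResult(0.0 if mean1 == mean2 else np.inf, p,
                          "pooled_t", (n1, n2), direction)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = min(1.0, 2.0 * _dist.t.sf(abs(t), df))
    return TestResult(float(t), float(p), "pooled_t", (n1, n2), direction)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation on complete pairs (ties midranked).

    Pairs with a missing value in either vector are removed first; a
    constant vector yields an undefined (NaN) result flagged for exclusion.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        return TestResult(np.nan, np.nan, "spearman", (n,), 0)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(np.nan, np.nan, "spearman[degenerate]", (n,), 0)
    rx = _ranks_with_ties(x)
    ry = _ranks_with_ties(y)
    rx -= rx.mean()
    ry -= ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        p = min(1.0, 2.0 * _dist.t.sf(abs(t), n - 2))
    return TestResult(rho, float(p), "spearman", (n,), int(np.sign(rho)))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra
# ---------------------------------------------------------------------------

def _jt_statistic(groups: list[np.ndarray]) -> float:
    j = 0.0
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            a = groups[gi][:, None]
            b = groups[gj][None, :]
            j += float((a < b).sum()) + 0.5 * float((a == b).sum())
    return j


def jonckheere_terpstra(groups, mode: str = "normal",
                        alternative: str = "two_sided",
                        n_permutations: int = 9999,
                        seed: int = 0) -> TestResult:
    """Jonckheere–Terpstra test for a monotone trend across ordered groups.

    J sums, over all ordered group pairs, the Mann–Whitney counts
    #(a < b) + ½#(a = b).  ``normal`` mode uses the tie-adjusted mean and
    variance of J; ``exact_mc`` permutes pooled observations among groups
    (seeded) preserving group sizes.  The two-sided p doubles the smaller
    one-sided tail, capped at 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 ordered groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("empty group")
    sizes = np.array([g.size for g in gs], dtype=float)
    n = sizes.sum()
    pooled = np.concatenate(gs)
    j = _jt_statistic(gs)
    mean_j = (n ** 2 - (sizes ** 2).sum()) / 4.0

    if np.all(pooled == pooled[0]):
        return TestResult(j, 1.0, "jonckheere_terpstra", tuple(int(s) for s in sizes), 0)

    if mode == "normal":
        _, t_counts = np.unique(pooled, return_counts=True)
        t = t_counts.astype(float)
        term1 = (n * (n - 1) * (2 * n + 5)
                 - (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
                 - (t * (t - 1) * (2 * t + 5)).sum()) / 72.0
        term2 = ((sizes * (sizes - 1) * (sizes - 2)).sum()
                 * (t * (t - 1) * (t - 2)).sum()) / (36.0 * n * (n - 1) * (n - 2))
        term3 = ((sizes * (sizes - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * n * (n - 1))
        var_j = term1 + term2 + term3
        if var_j <= 0:
            return TestResult(j, 1.0, "jonckheere_terpstra",
                              tuple(int(s) for s in sizes), 0)
        z = (j - mean_j) / np.sqrt(var_j)
        p_inc = float(_dist.norm.sf(z))
        p_dec = float(_dist.norm.cdf(z))
        method = "jonckheere_terpstra[normal]"
    elif mode == "exact_mc":
        rng = np.random.default_rng(seed)
        splits = np.cumsum(sizes.astype(int))[:-1]
        ge = le = 0
        work = pooled.copy()
        for _ in range(n_permutations):
            rng.shuffle(work)
            jp = _jt_statistic(np.split(work, splits))
            if jp >= j - 1e-9:
                ge += 1
            if jp <= j + 1e-9:
                le += 1
        p_inc = (1 + ge) / (1 + n_permutations)
        p_dec = (1 + le) / (1 + n_permutations)
        method = "jonckheere_terpstra[exact_mc]"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if alternative == "increasing":
        p = p_inc
    elif alternative == "decreasing":
        p = p_dec
    elif alternative == "two_sided":
        p = min(1.0, 2.0 * min(p_inc, p_dec))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(j, float(p), method, tuple(int(s) for s in sizes),
                      int(np.sign(j - mean_j)))
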