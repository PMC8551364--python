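"""Unit and oracle tests for the core statistical machinery.

Every test statistic has an independent route: exhaustive enumeration for
the exact tests, scipy/statsmodels for the approximations.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from ragut.stats import (bh_fdr, fisher_exact_2x2, fisher_exact_rxc_mc,
                         jonckheere_terpstra, pooled_t_from_summary,
                         spearman_rho, wilcoxon_rank_sum)


# ---------------------------------------------------------------------------
# enumeration oracles (independent of the implementations they check)
# ---------------------------------------------------------------------------

def enumerate_wilcoxon_p(x, y):
    """Two-sided exact rank-sum p by enumerating every group assignment."""
    pooled = sorted(list(x) + list(y))
    n1 = len(x)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = [sum(r for r in comb) - n1 * (n1 + 1) / 2
          for comb in itertools.combinations(range(1, len(pooled) + 1), n1)]
    total = len(us)
    p_lo = sum(u <= u_obs for u in us) / total
    p_hi = sum(u >= u_obs for u in us) / total
    return min(1.0, 2 * min(p_lo, p_hi))


def enumerate_jt(groups):
    """Exact one-sided (increasing) JT p over all distinct permutations."""
    def jt_stat(gs):
        j = 0.0
        for a in range(len(gs)):
            for b in range(a + 1, len(gs)):
                for xa in gs[a]:
                    for xb in gs[b]:
                        j += (xa < xb) + 0.5 * (xa == xb)
        return j

    sizes = [len(g) for g in groups]
    pooled = [v for g in groups for v in g]
    j_obs = jt_stat(groups)
    cuts = np.cumsum(sizes)[:-1]
    count = total = 0
    for perm in set(itertools.permutations(pooled)):
        gs = np.split(np.array(perm), cuts)
        total += 1
        count += jt_stat(gs) >= j_obs - 1e-9
    return j_obs, count / total


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

class TestWilcoxonRankSum:
    def test_separated_groups_exact_p(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2/20 assignments as extreme
        assert res.direction == -1

    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0
        assert res.statistic == pytest.approx(9 / 2)  # null mean of U

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 7, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        res = wilcoxon_rank_sum(x, y, mode="exact")
        assert res.p_value == pytest.approx(enumerate_wilcoxon_p(x, y))

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_mode_close_to_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        x, y = rng.normal(size=8), rng.normal(size=8)
        p_exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
        p_norm = wilcoxon_rank_sum(x, y, mode="normal_tie_corrected").p_value
        assert abs(p_exact - p_norm) < 0.02

    def test_tie_corrected_matches_scipy(self):
        rng = np.random.default_rng(7)
        x = np.round(rng.normal(size=15), 1)
        y = np.round(rng.normal(0.5, size=12), 1)
        ours = wilcoxon_rank_sum(x, y, mode="normal_tie_corrected")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)
        assert ours.statistic == pytest.approx(ref.statistic)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_enterotype_contingency_value(self):
        res = fisher_exact_2x2([[3, 19], [6, 16]])
        assert round(res.p_value, 4) == 0.4566

    def test_symmetric_table(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]).p_value == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_on_random_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            t = rng.integers(0, 9, size=(2, 2))
            if t.sum() <= 30 and t.sum() > 0:
                break
        ours = fisher_exact_2x2(t)
        assert ours.p_value == pytest.approx(sps.fisher_exact(t).pvalue, abs=1e-12)

    def test_mc_extension_agrees_on_2x2(self):
        t = [[3, 19], [6, 16]]
        exact = fisher_exact_2x2(t).p_value
        mc = fisher_exact_rxc_mc(t, n_draws=20000, seed=1).p_value
        assert abs(mc - exact) < 0.02


# ---------------------------------------------------------------------------
# pooled t from summary statistics
# ---------------------------------------------------------------------------

class TestPooledT:
    def test_weight_row(self):
        res = pooled_t_from_summary(58.1, 4.4, 13, 52.6, 7.6, 9)
        assert round(res.p_value, 3) == 0.044

    def test_ast_row(self):
        res = pooled_t_from_summary(20.7, 7.1, 22, 15.2, 2.9, 22)
        assert round(res.p_value, 3) == 0.002

    def test_equal_means(self):
        res = pooled_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 10)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_degenerate_zero_sds(self):
        assert pooled_t_from_summary(5, 0, 5, 5, 0, 5).p_value == 1.0
        assert pooled_t_from_summary(5, 0, 5, 6, 0, 5).p_value == 0.0


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]).statistic == -1.0

    def test_hand_case(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4, rho = 1 - 6*4/(5*24) = 0.8
        res = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.statistic == pytest.approx(0.8)
        ref = sps.spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_missing_values_dropped_pairwise(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 3, 9, 5, np.nan, 7]
        res = spearman_rho(x, y)
        assert res.n_used == (4,)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        res = spearman_rho([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert not res.valid

    def test_ties_match_scipy(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.normal(size=20), 1)
        y = np.round(x + rng.normal(size=20), 1)
        ours = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_equal_ps_unchanged(self):
        assert bh_fdr([0.03] * 5) == pytest.approx([0.03] * 5)

    def test_step_up_by_hand(self):
        # q_i = min over j>=i of p_(j) * n / j = 0.04 for every rank here
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_monotone_in_p_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = rng.permutation(50)
        assert bh_fdr(p[perm]) == pytest.approx(q[perm])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        ref = multipletests(p, method="fdr_bh")[1]
        assert bh_fdr(p) == pytest.approx(ref)


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra
# ---------------------------------------------------------------------------

class TestJonckheereTerpstra:
    def test_maximal_trend_exact_enumeration(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        j_obs, p_exact = enumerate_jt(groups)
        assert j_obs == 12.0  # every cross-group pair ordered
        assert p_exact == pytest.approx(1 / 90)
        res = jonckheere_terpstra(groups, mode="exact_mc",
                                  alternative="increasing",
                                  n_permutations=20000, seed=0)
        assert res.statistic == 12.0
        assert abs(res.p_value - 1 / 90) < 0.01

    @pytest.mark.parametrize("seed", range(3))
    def test_monte_carlo_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        sizes = (3, 2, 2)
        groups = [list(np.round(rng.normal(size=s), 2)) for s in sizes]
        _, p_exact = enumerate_jt(groups)
        res = jonckheere_terpstra(groups, mode="exact_mc",
                                  alternative="increasing",
                                  n_permutations=10000, seed=seed)
        assert abs(res.p_value - p_exact) < 0.02

    def test_two_groups_reduce_to_mann_whitney(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=6), rng.normal(0.8, size=7)
        jt = jonckheere_terpstra([list(x), list(y)], mode="normal")
        # J for two groups counts pairs x < y: the Mann-Whitney U of y over x
        u_y = sum((xa < yb) + 0.5 * (xa == yb) for xa in x for yb in y)
        assert jt.statistic == pytest.approx(u_y)

    @pytest.mark.parametrize("seed", range(3))
    def test_normal_close_to_monte_carlo_small_groups(self, seed):
        rng = np.random.default_rng(40 + seed)
        groups = [list(rng.normal(0.2 * i, size=8)) for i in range(3)]
        p_norm = jonckheere_terpstra(groups, mode="normal").p_value
        p_mc = jonckheere_terpstra(groups, mode="exact_mc",
                                   n_permutations=20000, seed=seed).p_value
        assert abs(p_norm - p_mc) < 0.03

    def test_all_equal_observations(self):
        res = jonckheere_terpstra([[1, 1], [1, 1], [1, 1]])
        assert res.p_value == 1.0
        assert res.statistic == pytest.approx(6.0)  # null mean of J

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1, 2], [], [3]])

    def test_trend_antisymmetry(self):
        rng = np.random.default_rng(2)
        groups = [list(rng.normal(0.5 * i, size=5)) for i in range(4)]
        fwd = jonckheere_terpstra(groups, mode="normal")
        rev = jonckheere_terpstra(groups[::-1], mode="normal")
        assert fwd.direction == -rev.direction
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-9)
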