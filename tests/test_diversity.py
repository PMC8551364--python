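"""Diversity indices, distances, ordination, PERMANOVA — with geometric and
library oracles (scikit-bio, scipy) cross-checking the implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ragut.diversity import (DistanceMatrix, bray_curtis_matrix,
                             jsd_distance_matrix, observed_richness, pca_embed,
                             pcoa_embed, permanova, shannon_index,
                             _permanova_f)
from ragut.tables import AbundanceTable


def _table(matrix, prefix="f"):
    m = np.asarray(matrix, dtype=float)
    return AbundanceTable(
        pd.DataFrame(m, index=[f"{prefix}{i}" for i in range(m.shape[0])],
                     columns=[f"S{j}" for j in range(m.shape[1])]),
        "gene_family")


class TestShannon:
    def test_uniform(self):
        assert shannon_index([25, 25, 25, 25]) == pytest.approx(np.log(4))

    def test_single_feature(self):
        assert shannon_index([0, 7, 0]) == 0.0

    def test_hand_value(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.5 ln 2 ≈ 1.0397
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])

    def test_uniform_maximises_at_fixed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(0.01, 1, size=8)
            assert shannon_index(v) <= shannon_index(np.ones(8)) + 1e-12


class TestRichness:
    def test_counts_nonzero(self):
        assert observed_richness([0, 0.1, 0, 3]) == 2
        assert observed_richness([0, 0]) == 0

    def test_invariant_to_rescaling(self):
        v = np.array([0, 1.5, 2, 0, 0.3])
        assert observed_richness(v) == observed_richness(10 * v)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = _table([[10, 10, 0], [5, 5, 0], [0, 0, 7]])
        d = bray_curtis_matrix(t).values
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_hand_value(self):
        t = _table([[60, 40], [40, 60]])
        assert bray_curtis_matrix(t).values[0, 1] == pytest.approx(0.2)

    def test_matches_scipy_pdist(self, small_cohort):
        from scipy.spatial.distance import pdist, squareform
        sub = AbundanceTable(small_cohort.species.data.iloc[:, :8], "species")
        ours = bray_curtis_matrix(sub).values
        ref = squareform(pdist(sub.values().T, "braycurtis"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(size=(6, 4))
        d1 = bray_curtis_matrix(_table(m)).values
        perm = rng.permutation(6)
        d2 = bray_curtis_matrix(_table(m[perm])).values
        np.testing.assert_allclose(d1, d2)


class TestJsdDistance:
    def test_identical_distributions_zero(self):
        t = _table([[10, 20], [30, 60], [60, 120]])
        assert jsd_distance_matrix(t).values[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_supports_approach_one(self):
        t = _table([[100, 0], [0, 100]])
        d = jsd_distance_matrix(t, pseudocount=1e-12).values[0, 1]
        assert d == pytest.approx(1.0, abs=1e-3)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 5, size=(10, 9))
        d = jsd_distance_matrix(_table(m)).values
        for i, j, k in itertools.permutations(range(9), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_zero_pseudocount_with_zeros_rejected(self):
        with pytest.raises(ValueError):
            jsd_distance_matrix(_table([[1, 0], [0, 1]]), pseudocount=0)


def _euclidean_dm(points):
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix([f"S{i}" for i in range(len(pts))], d, "euclidean")


class TestPcoa:
    def test_line_geometry_recovered_on_first_axis(self):
        dm = _euclidean_dm([[x, 0.0] for x in (0, 1, 2, 5, 9)])
        with pytest.warns(UserWarning):
            res = pcoa_embed(dm, k=2)
        axis1 = res.coordinates[:, 0]
        assert np.all(np.diff(axis1) > 0) or np.all(np.diff(axis1) < 0)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(3)
        pts = rng.random((7, 3))
        dm = _euclidean_dm(pts)
        res = pcoa_embed(dm, k=3)
        rec = np.sqrt(((res.coordinates[:, None] - res.coordinates[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, dm.values, atol=1e-8)

    def test_duplicated_sample_same_coordinates(self):
        pts = [[0, 0], [1, 1], [1, 1], [3, 0]]
        res = pcoa_embed(_euclidean_dm(pts), k=2)
        np.testing.assert_allclose(res.coordinates[1], res.coordinates[2],
                                   atol=1e-10)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        pts = rng.random((9, 4))
        dm = _euclidean_dm(pts)
        ours = pcoa_embed(dm, k=3)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, dm.sample_ids))
        np.testing.assert_allclose(np.sort(ours.eigenvalues)[::-1],
                                   np.sort(ref.eigvals.values)[::-1][:3],
                                   atol=1e-8)
        np.testing.assert_allclose(np.abs(ours.coordinates),
                                   np.abs(ref.samples.values[:, :3]), atol=1e-6)


class TestPca:
    def test_rank_one_data(self):
        t = _table(np.outer([1, 2, 3], [1, 2, 3, 4]))
        res = pca_embed(t, k=2)
        assert res.eigenvalues[0] > 1e-8
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_proportions_sum_below_one(self, small_cohort):
        res = pca_embed(small_cohort.species, k=3)
        assert 0 < res.proportion_explained.sum() <= 1 + 1e-12

    def test_agrees_with_pcoa_on_euclidean_distances(self):
        rng = np.random.default_rng(5)
        m = rng.random((6, 8))  # features x samples
        t = _table(m)
        pca = pca_embed(t, k=2)
        dm = _euclidean_dm(m.T)
        pcoa = pcoa_embed(dm, k=2)
        np.testing.assert_allclose(np.abs(pca.coordinates),
                                   np.abs(pcoa.coordinates), atol=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_embed(_table(np.ones((4, 5))), k=2)


class TestPermanova:
    def test_separated_clusters_attain_minimal_p(self):
        pts = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 50])
        pts += np.random.default_rng(0).normal(scale=0.1, size=pts.shape)
        dm = _euclidean_dm(pts)
        res = permanova(dm, ["a"] * 10 + ["b"] * 10, n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_matches_exhaustive_enumeration_n6(self):
        d = np.abs(np.subtract.outer(np.arange(6.0), np.arange(6.0)))
        dm = DistanceMatrix(list("abcdef"), d, "euclidean")
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        d2 = d ** 2
        f_obs = _permanova_f(d2, labels, np.array(["A", "B"]))
        count = total = 0
        for comb in itertools.combinations(range(6), 3):
            lab = np.array(["B"] * 6)
            lab[list(comb)] = "A"
            total += 1
            count += _permanova_f(d2, lab, np.array(["A", "B"])) >= f_obs - 1e-12
        p_exact = count / total
        res = permanova(dm, labels, n_permutations=9999, seed=0)
        assert abs(res.p_value - p_exact) < 0.02

    def test_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        pts = rng.random((12, 3))
        dm = _euclidean_dm(pts)
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(dm, labels, n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, dm.sample_ids), labels,
            permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"])

    def test_invariant_to_consistent_reordering(self):
        rng = np.random.default_rng(6)
        pts = rng.random((10, 2))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        dm = _euclidean_dm(pts)
        perm = rng.permutation(10)
        dm2 = DistanceMatrix([dm.sample_ids[i] for i in perm],
                             dm.values[np.ix_(perm, perm)], "euclidean")
        r1 = permanova(dm, labels, n_permutations=199, seed=3)
        r2 = permanova(dm2, labels[perm], n_permutations=199, seed=3)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_singleton_group_rejected(self):
        dm = _euclidean_dm(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ValueError):
            permanova(dm, ["a", "a", "a", "a", "b"])
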