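from itertools import combinations

import numpy as np
import pytest
from scipy.stats import f_oneway, mannwhitneyu

from rarebench import DistanceMatrix, permanova, wilcoxon_rank_sum
from rarebench.inference import _pseudo_f


class TestWilcoxon:
    def test_identical_small_groups_give_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_fully_separated_triples_exact_p(self):
        # rank sum 6 is 1 of C(6,3)=20 assignments per tail → p = 2/20
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "wilcoxon-exact"
        assert np.isclose(res.p_value, 0.1)

    def test_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=9)
            ours = wilcoxon_rank_sum(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert np.isclose(ours.p_value, ref.pvalue, atol=1e-12)

    def test_normal_approximation_close_to_exact(self):
        # just past the enumeration cutoff (11+10) the approximation must
        # sit within 0.02 of scipy's complete enumeration
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=11)
            y = rng.normal(0.3, size=10)
            exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            approx = wilcoxon_rank_sum(x, y)
            assert approx.method == "wilcoxon-normal"
            assert abs(approx.p_value - exact) < 0.02

    def test_tied_data_uses_corrected_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 4, size=8).astype(float)
        y = rng.integers(0, 4, size=8).astype(float)
        ours = wilcoxon_rank_sum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.method == "wilcoxon-normal"
        assert np.isclose(ours.p_value, ref.pvalue, atol=1e-9)

    def test_large_sample_approximation_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = rng.normal(0.5, size=25)
        ours = wilcoxon_rank_sum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.method == "wilcoxon-normal"
        assert np.isclose(ours.p_value, ref.pvalue, atol=1e-9)

    def test_constant_data_p_one(self):
        res = wilcoxon_rank_sum([2.0] * 12, [2.0] * 12)
        assert res.p_value == 1.0


def _euclidean_dm(points):
    points = np.asarray(points, dtype=float).reshape(len(points), -1)
    diff = points[:, None, :] - points[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(tuple(f"s{i}" for i in range(len(points))), values, "euclidean")


def _enumerate_permanova_p(dm, labels):
    """Complete enumeration over distinct equal-size splits (test oracle)."""
    labels = np.asarray(labels)
    n = labels.size
    n_a = int((labels == labels[0]).sum())
    d2 = dm.values**2
    obs = _pseudo_f(d2, [labels == g for g in np.unique(labels)])
    count = 0
    total = 0
    for combo in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        f = _pseudo_f(d2, [mask, ~mask])
        total += 1
        if f >= obs - 1e-12:
            count += 1
    return count / total


class TestPermanova:
    def test_pseudo_f_invariant_under_reordering(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(10, 3))
        labels = np.array(["A"] * 5 + ["B"] * 5)
        dm = _euclidean_dm(points)
        f1 = permanova(dm, labels, n_permutations=99, seed=0).statistic
        order = rng.permutation(10)
        dm2 = DistanceMatrix(
            tuple(f"s{i}" for i in range(10)), dm.values[np.ix_(order, order)]
        )
        f2 = permanova(dm2, labels[order], n_permutations=99, seed=0).statistic
        assert np.isclose(f1, f2)

    def test_well_separated_clusters_reach_minimum_p(self):
        # within ≈0.1, between ≈10, 4+4: enumeration gives p = 1/35
        rng = np.random.default_rng(4)
        points = np.concatenate([rng.normal(0, 0.05, (4, 2)), rng.normal(10, 0.05, (4, 2))])
        dm = _euclidean_dm(points)
        labels = ["A"] * 4 + ["B"] * 4
        assert np.isclose(_enumerate_permanova_p(dm, labels), 1 / 35)
        res = permanova(dm, labels, n_permutations=999, seed=5)
        assert 0.001 <= res.p_value <= 0.05

    def test_agrees_with_complete_enumeration_on_moderate_signal(self):
        rng = np.random.default_rng(6)
        points = np.concatenate([rng.normal(0, 1, (4, 2)), rng.normal(1.2, 1, (4, 2))])
        dm = _euclidean_dm(points)
        labels = ["A"] * 4 + ["B"] * 4
        exact = _enumerate_permanova_p(dm, labels)
        res = permanova(dm, labels, n_permutations=9999, seed=7)
        assert abs(res.p_value - exact) < 0.03

    def test_equals_anova_f_on_one_dimensional_data(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=7)
        y = rng.normal(1.0, size=6)
        dm = _euclidean_dm(np.concatenate([x, y]))
        labels = ["A"] * 7 + ["B"] * 6
        res = permanova(dm, labels, n_permutations=99, seed=9)
        ref = f_oneway(x, y)
        assert np.isclose(res.statistic, ref.statistic, rtol=1e-10)

    def test_pseudo_f_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(10)
        points = rng.normal(size=(12, 4))
        dm = _euclidean_dm(points)
        labels = ["A"] * 6 + ["B"] * 6
        res = permanova(dm, labels, n_permutations=99, seed=11)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm.values, ids=list(dm.sample_ids)),
            grouping=list(labels),
            permutations=99,
        )
        assert np.isclose(res.statistic, ref["test statistic"], rtol=1e-10)

    def test_null_calibration(self):
        # randomly labelled homogeneous data: rejection at 0.05 stays near 5%
        rng = np.random.default_rng(12)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            points = rng.normal(size=(12, 3))
            dm = _euclidean_dm(points)
            labels = np.array(["A"] * 6 + ["B"] * 6)
            rng.shuffle(labels)
            res = permanova(dm, labels, n_permutations=199, seed=rng)
            if res.p_value < 0.05:
                rejections += 1
        assert 0.01 * n_sims <= rejections <= 0.11 * n_sims

    def test_all_zero_distances_give_p_one(self):
        dm = DistanceMatrix(("a", "b", "c", "d"), np.zeros((4, 4)))
        res = permanova(dm, ["A", "A", "B", "B"], n_permutations=99, seed=0)
        assert res.p_value == 1.0

    def test_permutation_p_never_zero(self):
        rng = np.random.default_rng(13)
        points = np.concatenate([rng.normal(0, 0.01, (5, 2)), rng.normal(50, 0.01, (5, 2))])
        dm = _euclidean_dm(points)
        res = permanova(dm, ["A"] * 5 + ["B"] * 5, n_permutations=999, seed=14)
        assert res.p_value >= 1 / 1000
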