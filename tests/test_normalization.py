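import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import chisquare, hypergeom

from rarebench import (
    ClrScheme,
    OtuTable,
    clr_transform,
    css_normalize,
    rarefaction_mean,
    relative_abundance,
    richness,
    srs_normalize,
    subsample,
)
from rarebench import _engine


def _table(rows, n=None, k=None):
    arr = np.array(rows)
    return OtuTable(
        tuple(f"s{i}" for i in range(arr.shape[0])),
        tuple(f"Otu{j}" for j in range(arr.shape[1])),
        arr,
    )


class TestSubsample:
    def test_full_depth_returns_input(self):
        counts = np.array([4, 0, 7, 1])
        assert (subsample(counts, 12, seed=0) == counts).all()

    def test_single_otu_sample(self):
        assert subsample(np.array([0, 9]), 4, seed=1).tolist() == [0, 4]

    def test_depth_above_total_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            subsample(np.array([2, 2]), 5, seed=0)

    def test_marginal_matches_hypergeometric_pmf(self):
        # counts (5,5), depth 5: OTU1's subsampled count ~ Hypergeom(10,5,5)
        rng = np.random.default_rng(42)
        draws = np.array([subsample(np.array([5, 5]), 5, rng)[0] for _ in range(10000)])
        observed = np.bincount(draws, minlength=6)
        expected = hypergeom(10, 5, 5).pmf(np.arange(6)) * 10000
        assert chisquare(observed, expected).pvalue > 1e-3


class TestFastEngine:
    """The numba subsampler against numpy's hypergeometric sampler (oracle)."""

    def test_marginal_matches_hypergeometric_pmf(self):
        draws = _engine.subsample_draws(np.array([5, 5]), 5, 10000, seed=7)
        observed = np.bincount(draws[:, 0], minlength=6)
        expected = hypergeom(10, 5, 5).pmf(np.arange(6)) * 10000
        assert chisquare(observed, expected).pvalue > 1e-3

    def test_subsets_are_uniform(self):
        # 6 singleton OTUs, depth 3: all C(6,3)=20 subsets equally likely
        draws = _engine.subsample_draws(np.ones(6, dtype=int), 3, 20000, seed=8)
        keys = (draws * (1 << np.arange(6))).sum(axis=1)
        observed = np.bincount(keys, minlength=64)
        observed = observed[observed > 0]
        assert observed.size == 20
        assert chisquare(observed).pvalue > 1e-3

    def test_row_sums_equal_depth(self):
        counts = np.array([10, 3, 0, 25, 1])
        draws = _engine.subsample_draws(counts, 17, 50, seed=9)
        assert (draws.sum(axis=1) == 17).all()
        assert (draws <= counts).all()

    def test_alpha_draws_agree_with_dense_metrics(self):
        # same statistics computed from per-draw count vectors must match
        # the streaming run-length accumulation in distribution
        counts = np.array([40, 20, 10, 5, 3, 1, 1])
        stats = _engine.rarefied_alpha_draws(counts, 20, 4000, seed=10)
        dense = _engine.subsample_draws(counts, 20, 4000, seed=11)
        rich_dense = (dense > 0).sum(axis=1)
        assert abs(stats["richness"].mean() - rich_dense.mean()) < 3 * (
            stats["richness"].std() / np.sqrt(4000) + rich_dense.std() / np.sqrt(4000)
        )

    def test_deterministic_given_seed(self):
        counts = np.array([8, 2, 4])
        a = _engine.subsample_draws(counts, 6, 10, seed=3)
        b = _engine.subsample_draws(counts, 6, 10, seed=3)
        assert (a == b).all()


class TestRelativeAbundance:
    def test_hand_values(self):
        at = relative_abundance(_table([[2, 2], [1, 3]]))
        assert np.allclose(at.values, [[0.5, 0.5], [0.25, 0.75]])

    def test_zero_depth_row_is_an_error(self):
        with pytest.raises(ValueError, match="zero-depth"):
            relative_abundance(_table([[0, 0], [1, 1]]))

    def test_rows_sum_to_one(self, small_table):
        assert np.allclose(relative_abundance(small_table).values.sum(axis=1), 1.0)


class TestSrs:
    def test_hand_example_with_tie_broken_by_scaled_value(self):
        # (5,3,2) to depth 5: scaled (2.5,1.5,1.0), one leftover unit,
        # fractional tie between OTU1/OTU2 goes to the larger scaled value
        out = srs_normalize(_table([[5, 3, 2]]), 5)
        assert out.counts.tolist() == [[3, 1, 1]]

    def test_target_equal_depth_is_identity(self):
        table = _table([[7, 0, 3]])
        assert srs_normalize(table, 10) == table

    def test_rows_sum_to_target(self, small_table):
        target = int(small_table.depths.min())
        out = srs_normalize(small_table, target)
        assert (out.depths == target).all()

    def test_shallow_samples_dropped_with_warning(self):
        table = _table([[10, 10], [1, 1]])
        with pytest.warns(UserWarning, match="dropping"):
            out = srs_normalize(table, 10)
        assert out.n_samples == 1

    def test_richness_never_increases(self, small_table):
        target = int(small_table.depths.min())
        out = srs_normalize(small_table, target)
        for before, after in zip(small_table.counts, out.counts):
            assert richness(after) <= richness(before)


class TestCss:
    def test_uniform_sample_hand_value(self):
        at = css_normalize(_table([[1, 1, 1, 1]]))
        assert np.allclose(at.values, [[250.0] * 4])

    def test_scalar_multiples_normalize_identically(self):
        at = css_normalize(_table([[2, 4, 6, 0], [1, 2, 3, 0]]))
        assert np.allclose(at.values[0], at.values[1])

    def test_invariant_to_column_order(self):
        a = css_normalize(_table([[5, 1, 3]]))
        b = css_normalize(_table([[3, 5, 1]]))
        assert np.allclose(np.sort(a.values[0]), np.sort(b.values[0]))


class TestClr:
    def test_uniform_sample_maps_to_zero(self):
        at = clr_transform(_table([[1, 1, 1, 1]]), "one")
        assert np.allclose(at.values, 0.0)

    def test_hand_value_scheme_one(self):
        # (3,1) + 1 → (4,2); g = √8; ln(4/√8) = ln√2 = 0.34657
        at = clr_transform(_table([[3, 1]]), "one")
        assert np.allclose(at.values, [[0.3465736, -0.3465736]], atol=1e-6)

    def test_nudge_scheme_adds_reciprocal_depth(self):
        scheme = ClrScheme("nudge")
        row = np.array([3, 1, 0])
        assert np.allclose(scheme.pseudo_counted(row), [3.25, 1.25, 0.25])

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(st.integers(0, 100), min_size=2, max_size=8).filter(
            lambda c: sum(c) > 0
        ),
        st.sampled_from(["one", "nudge"]),
    )
    def test_rows_sum_to_zero(self, counts, kind):
        at = clr_transform(_table([counts]), kind)
        assert abs(at.values.sum()) < 1e-9

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            ClrScheme("robust")


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Closed form E[S] = Σ_i (1 − C(N−n_i, d)/C(N, d))."""
    counts = counts[counts > 0]
    total = counts.sum()

    def lncomb(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    with np.errstate(invalid="ignore"):
        terms = np.where(
            total - counts >= depth,
            np.exp(lncomb(total - counts, depth) - lncomb(total, depth)),
            0.0,
        )
    return float((1.0 - terms).sum())


class TestRarefactionMean:
    def test_total_count_statistic_is_depth(self):
        value = rarefaction_mean(
            np.array([5, 8, 2]), lambda c: float(c.sum()), depth=6, n_iter=5, seed=0
        )
        assert value == 6.0

    def test_full_depth_equals_plug_in_statistic(self):
        counts = np.array([5, 8, 2])
        value = rarefaction_mean(
            counts, lambda c: float((c > 0).sum()), depth=15, n_iter=3, seed=0
        )
        assert value == 3.0

    def test_mean_richness_matches_closed_form(self):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(400, np.linspace(1, 20, 30) / np.linspace(1, 20, 30).sum())
        depth = 60
        n_iter = 1000
        mc = rarefaction_mean(
            counts, lambda c: float((c > 0).sum()), depth=depth, n_iter=n_iter, seed=1
        )
        exact = expected_rarefied_richness(counts, depth)
        # per-draw richness sd here is ≈1.5, so 3 SEs at 1,000 draws ≈ 0.15;
        # allow a conservative margin on top
        assert abs(mc - exact) < 0.3

    def test_pair_semantics_subsample_both(self):
        a = np.array([10, 0])
        b = np.array([0, 10])
        value = rarefaction_mean(
            (a, b),
            lambda x, y: float(abs(x - y).sum() / (x.sum() + y.sum())),
            depth=5,
            n_iter=4,
            seed=2,
        )
        assert value == 1.0

    def test_fast_engine_mean_matches_closed_form(self):
        # the numba path must agree with the same closed form
        rng = np.random.default_rng(3)
        counts = rng.multinomial(5000, np.ones(100) / 100)
        stats = _engine.rarefied_alpha_draws(counts, 500, 1000, seed=4)
        exact = expected_rarefied_richness(counts, 500)
        se = stats["richness"].std() / np.sqrt(1000)
        assert abs(stats["richness"].mean() - exact) < 3 * max(se, 0.05)
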