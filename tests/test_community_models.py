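from itertools import permutations

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

from rarebench import (
    EffectModel,
    OtuTable,
    assign_treatments,
    null_community,
    richness,
    richness_adjusted_pair,
    skewed_abundance_pair,
)
from rarebench.community_models import TreatmentDesign


class TestNullCommunity:
    def test_conserves_both_margins_exactly(self, small_table):
        null = null_community(small_table, seed=1)
        assert (null.depths == small_table.depths).all()
        assert (null.counts.sum(axis=0) == small_table.counts.sum(axis=0)).all()

    def test_single_sample_table_is_returned_unchanged(self):
        table = OtuTable(("only",), ("o1", "o2", "o3"), np.array([[4, 0, 6]]))
        assert null_community(table, seed=0) == table

    def test_deterministic_given_seed(self, small_table):
        assert null_community(small_table, seed=9) == null_community(small_table, seed=9)

    def test_cell_distribution_is_hypergeometric(self):
        # 2 samples × 2 OTUs with margins (2,2)/(2,2): enumerating all
        # distinct shuffles of the 4-label pool gives P(n11=0)=1/6,
        # P(n11=1)=4/6, P(n11=2)=1/6
        pool = [0, 0, 1, 1]
        counts = {0: 0, 1: 0, 2: 0}
        for perm in set(permutations(pool)):
            counts[sum(1 for x in perm[:2] if x == 0)] += 1
        total = sum(counts.values())
        expected_probs = np.array([counts[0], counts[1], counts[2]]) / total
        assert np.allclose(expected_probs, [1 / 6, 4 / 6, 1 / 6])

        table = OtuTable(("a", "b"), ("o1", "o2"), np.array([[1, 1], [1, 1]]))
        rng = np.random.default_rng(123)
        observed = np.zeros(3)
        n_draws = 10000
        for _ in range(n_draws):
            observed[null_community(table, rng).counts[0, 0]] += 1
        stat = chisquare(observed, expected_probs * n_draws)
        assert stat.pvalue > 1e-3


class TestAssignTreatments:
    def test_unbiased_split_is_balanced(self):
        design = assign_treatments(np.arange(10) + 1, "unbiased", seed=0)
        assert sorted(design.group_sizes()) == [5, 5]

    def test_median_split_follows_the_rule(self):
        depths = np.arange(1, 11)
        design = assign_treatments(depths, "median_split", seed=0)
        labels = np.array(design.labels)
        assert set(labels[depths > np.median(depths)]) == {"A"}
        assert set(labels[depths <= np.median(depths)]) == {"B"}

    def test_median_split_impossible_when_all_equal(self):
        with pytest.raises(ValueError, match="median split"):
            assign_treatments(np.full(6, 100), "median_split", seed=0)

    def test_tails_are_pinned_and_middle_randomized(self):
        depths = np.arange(1, 101)
        design = assign_treatments(depths, "tail_5_95", seed=1)
        labels = np.array(design.labels)
        assert set(labels[:5]) == {"B"}  # smallest 5 share a group
        assert set(labels[95:]) == {"A"}  # largest 5 share the other
        assert {"A", "B"} <= set(labels[5:95])  # middle 90 randomized

    def test_deterministic_given_seed(self):
        a = assign_treatments(np.arange(20), "tail_5_95", seed=5)
        b = assign_treatments(np.arange(20), "tail_5_95", seed=5)
        assert a.labels == b.labels


class TestEffectModels:
    def _design(self, table):
        half = table.n_samples // 2
        labels = ("A",) * half + ("B",) * (table.n_samples - half)
        return TreatmentDesign(table.sample_ids, labels, "unbiased")

    def test_skewed_renormalization_matches_hand_value(self):
        # p=(0.5,0.5), perturb OTU2 by 5%: p' = (0.5, 0.525)/1.025
        p = np.array([0.5, 0.5])
        p2 = p.copy()
        p2[1] *= 1.05
        p2 /= p2.sum()
        assert np.allclose(p2, [0.5 / 1.025, 0.525 / 1.025])
        assert np.allclose(p2, [0.48780487, 0.51219512], atol=1e-7)

    def test_pair_preserves_observed_depths(self, small_table):
        model = EffectModel("skewed_abundance", seed=2)
        pair = skewed_abundance_pair(small_table, self._design(small_table), model)
        assert (pair.depths == small_table.depths).all()

    def test_richness_adjusted_removes_three_percent_of_otus(self):
        # uniform table, 100 OTUs, deep samples: the 3 removed OTUs are the
        # only ones that can be absent from every group-B sample
        table = OtuTable(
            tuple(f"s{i}" for i in range(6)),
            tuple(f"Otu{j}" for j in range(100)),
            np.full((6, 100), 200),
        )
        model = EffectModel("richness_adjusted", seed=3)
        pair = richness_adjusted_pair(table, self._design(table), model)
        mask = np.array([lab == "B" for lab in self._design(table).labels])
        absent_in_b = (pair.counts[mask].sum(axis=0) == 0).sum()
        assert absent_in_b == 3  # round(0.03 × 100)

    def test_richness_adjusted_lowers_group_b_richness(self):
        # with ~3% of the profile removed, group B samples observe fewer
        # OTUs on average; equal depths isolate the effect from sampling
        # (Monte-Carlo over replicate pair draws)
        rng = np.random.default_rng(1)
        p = rng.lognormal(0, 2, 200)
        p /= p.sum()
        table = OtuTable(
            tuple(f"s{i}" for i in range(10)),
            tuple(f"Otu{j}" for j in range(200)),
            rng.multinomial(5000, p, size=10),
        )
        design = self._design(table)
        mask = np.array([lab == "A" for lab in design.labels])
        diffs = []
        for rep in range(30):
            model = EffectModel("richness_adjusted", seed=rep)
            pair = richness_adjusted_pair(table, design, model)
            rich = np.array([richness(r) for r in pair.counts])
            diffs.append(rich[mask].mean() - rich[~mask].mean())
        assert np.mean(diffs) > 0

    def test_null_effect_is_exchangeable(self):
        # effect_size=0 makes the two generating profiles identical; on an
        # equal-depth table the two groups' richness values are then draws
        # from one distribution (two-sample KS over many replicates)
        rng = np.random.default_rng(0)
        p = rng.lognormal(0, 2, 200)
        p /= p.sum()
        table = OtuTable(
            tuple(f"s{i}" for i in range(10)),
            tuple(f"Otu{j}" for j in range(200)),
            rng.multinomial(2000, p, size=10),
        )
        design = self._design(table)
        mask = np.array([lab == "A" for lab in design.labels])
        a_vals, b_vals = [], []
        for rep in range(30):
            model = EffectModel("skewed_abundance", effect_size=0.0, seed=rep)
            pair = skewed_abundance_pair(table, design, model)
            rich = np.array([richness(r) for r in pair.counts])
            a_vals.extend(rich[mask])
            b_vals.extend(rich[~mask])
        assert ks_2samp(a_vals, b_vals).pvalue > 1e-3

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            EffectModel("skewed_abundance", frac_otus_perturbed=0.0)
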