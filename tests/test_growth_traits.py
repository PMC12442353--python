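"""Trait computation: rarefaction, normalization, fold changes, latency,
rank tests, diversity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from mwsip.exceptions import AnalysisError, DomainError, InvalidDesignError
from mwsip.growth_traits import (
    alpha_diversity,
    baseline_with_pseudo,
    incorporator_diversity,
    latency,
    max_l2fc,
    normalize_abundance,
    normalize_table,
    rarefy,
    wilcoxon_rank_sum,
)


class TestRarefy:
    def test_sample_at_depth_returned_unchanged(self):
        counts = pd.DataFrame({"s1": [100, 400, 1067]}, index=["a", "b", "c"])
        out = rarefy(counts, depth=1567, seed=0)
        assert out["s1"].tolist() == [100, 400, 1067]

    def test_shallow_sample_dropped(self):
        counts = pd.DataFrame({"deep": [2000, 0], "shallow": [10, 5]}, index=["a", "b"])
        out = rarefy(counts, depth=100, seed=0)
        assert list(out.columns) == ["deep"]
        assert out["deep"].sum() == 100

    def test_deterministic_under_seed(self, rng):
        counts = pd.DataFrame({"s": rng.poisson(50, 30)})
        a = rarefy(counts, depth=500, seed=9)
        b = rarefy(counts, depth=500, seed=9)
        assert a.equals(b)

    def test_composition_converges_to_input_proportions(self, rng):
        """Near-total depth, subsampled proportions match input (chi-square)."""
        from scipy.stats import chisquare

        col = rng.poisson(200, 20) + 10
        counts = pd.DataFrame({"s": col})
        total = int(col.sum())
        stats = []
        for seed in range(10):
            out = rarefy(counts, depth=total - 50, seed=seed)["s"].to_numpy()
            expected = col / total * (total - 50)
            stats.append(chisquare(out, expected).pvalue)
        assert np.median(stats) > 0.2


class TestNormalizeAbundance:
    def test_stated_formula(self):
        assert normalize_abundance(0.2, 4, 2, 10) == pytest.approx(0.25)

    def test_zero_abundance_maps_to_zero(self):
        assert normalize_abundance(0.0, 4, 2, 10) == 0.0

    def test_linear_in_dna_yield(self):
        assert normalize_abundance(0.2, 4, 2, 20) == pytest.approx(
            2 * normalize_abundance(0.2, 4, 2, 10)
        )

    def test_nonpositive_rrn_rejected(self):
        with pytest.raises(DomainError):
            normalize_abundance(0.2, 0, 2, 10)

    def test_table_scale_invariance(self, rng):
        """Rescaling all counts jointly leaves normalized abundances unchanged."""
        counts = pd.DataFrame(rng.poisson(100, size=(8, 3)) + 1,
                              index=[f"t{i}" for i in range(8)])
        rrn = pd.Series(rng.uniform(1, 10, 8), index=counts.index)
        dy = pd.Series(5.0, index=counts.columns)
        a = normalize_table(counts, rrn, dy)
        b = normalize_table(counts * 7, rrn, dy)
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestMaxL2fc:
    def test_fourfold_increase(self):
        assert max_l2fc([6, 16, 8], 4.0) == pytest.approx(2.0)

    def test_decline_floored_at_zero(self):
        assert max_l2fc([1, 2], 4.0) == 0.0

    def test_boundary_equal_to_baseline(self):
        assert max_l2fc([4.0], 4.0) == 0.0

    def test_empty_series_is_undefined(self):
        assert np.isnan(max_l2fc([], 4.0))

    def test_zero_floor_on_random_inputs(self, rng):
        for _ in range(50):
            series = rng.uniform(0, 10, size=5)
            assert max_l2fc(series, rng.uniform(0.1, 10)) >= 0.0

    def test_pseudo_baseline_uses_smallest_nonzero(self):
        base = pd.Series([0.0, 0.4, 0.1], index=["a", "b", "c"])
        out = baseline_with_pseudo(base)
        assert out["a"] == pytest.approx(0.1)
        assert out["b"] == pytest.approx(0.4)


class TestLatency:
    @pytest.mark.parametrize(
        "first,peak,expected", [(7, 2, 5.0), (1, 2, 0.0), (14, 6, 8.0), (2, 2, 0.0)]
    )
    def test_worked_examples(self, first, peak, expected):
        assert latency(first, peak) == expected

    def test_unlabeled_taxon_is_undefined(self):
        assert np.isnan(latency(float("nan"), 2))
        assert np.isnan(latency(None, 2))

    def test_negative_days_rejected(self):
        with pytest.raises(DomainError):
            latency(-1, 2)


class TestWilcoxon:
    def test_fully_separated_small_groups_exact_p(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert res["p"] == pytest.approx(1 / 20)

    def test_identical_groups_p_near_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res["p"] > 0.9

    def test_matches_brute_force_enumeration(self):
        """Exact p equals the proportion of label assignments with U ≤ observed."""
        a, b = [1.2, 3.4, 2.2], [5.0, 4.1, 6.3]
        obs = wilcoxon_rank_sum(a, b, alternative="less")
        pooled = a + b
        u_obs = sum(x > y for x in a for y in b)  # U of the first group
        splits = list(itertools.combinations(range(6), 3))
        count = 0
        for combo in splits:
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            count += sum(x > y for x in ga for y in gb) <= u_obs
        assert obs["p"] == pytest.approx(count / len(splits))

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.8, 1, 40)
        res = wilcoxon_rank_sum(a, b)
        assert 0 < res["p"] < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidDesignError):
            wilcoxon_rank_sum([], [1, 2])


def star_tree(k: int) -> TreeNode:
    root = TreeNode(name="root")
    for i in range(k):
        tip = TreeNode(name=f"t{i}", length=1.0)
        root.append(tip)
    return root


class TestDiversity:
    def test_uniform_abundance_has_unit_evenness(self):
        counts = pd.DataFrame({"s": [5, 5, 5, 5]}, index=list("abcd"))
        out = alpha_diversity(counts)
        assert out.loc["s", "pielou_evenness"] == pytest.approx(1.0)
        assert out.loc["s", "richness"] == 4

    def test_single_taxon_evenness_undefined(self):
        counts = pd.DataFrame({"s": [9, 0]}, index=["a", "b"])
        assert np.isnan(alpha_diversity(counts).loc["s", "pielou_evenness"])

    def test_star_tree_faith_pd_counts_present_tips(self):
        tree = star_tree(5)
        counts = pd.DataFrame({"s": [1, 1, 1, 0, 0]}, index=[f"t{i}" for i in range(5)])
        out = alpha_diversity(counts, tree=tree)
        assert out.loc["s", "faith_pd"] == pytest.approx(3.0)

    def test_faith_pd_matches_skbio_on_binary_tree(self):
        """Cross-check against the independent implementation on a rooted tree."""
        from skbio.diversity.alpha import faith_pd as skbio_faith_pd

        from mwsip.growth_traits import faith_pd

        tree = TreeNode.read(["((a:1,b:2):0.5,(c:0.7,d:0.3):1.1);"])
        counts = [3, 0, 2, 5]
        ours = faith_pd(["a", "c", "d"], tree)
        theirs = float(skbio_faith_pd(counts, taxa=list("abcd"), tree=tree))
        assert ours == pytest.approx(theirs)

    def test_missing_tip_raises_named_error(self):
        tree = star_tree(2)
        counts = pd.DataFrame({"s": [1, 1]}, index=["t0", "zzz"])
        with pytest.raises(AnalysisError, match="zzz"):
            alpha_diversity(counts, tree=tree)

    def test_incorporator_subset_used(self):
        tree = star_tree(4)
        counts = pd.DataFrame({"s": [3, 3, 3, 3]}, index=[f"t{i}" for i in range(4)])
        calls = pd.DataFrame(
            {"is_incorporator": [True, True, False, False]},
            index=[f"t{i}" for i in range(4)],
        )
        out = incorporator_diversity(calls, counts, tree=tree)
        assert out.loc["s", "richness"] == 2
        assert out.loc["s", "faith_pd"] == pytest.approx(2.0)
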