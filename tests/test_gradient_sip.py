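"""Incorporator identification: pruning, normalization, testing, windows."""

import numpy as np
import pandas as pd
import pytest

from mwsip.exceptions import AnalysisError, InvalidDesignError
from mwsip.gradient_sip import (
    DEFAULT_WINDOWS,
    FractionTable,
    bh_adjust,
    degree_of_assimilation,
    mw_hr_sip,
    nb_wald_enrichment,
    prune_rare,
    size_factors,
    sparsity_sweep,
)
from mwsip.synthetic_data import GradientDesign, simulate_community, simulate_gradient


def brute_force_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Independent median-of-ratios: per-taxon log-mean reference, explicit loops."""
    refs = {}
    for taxon, row in counts.iterrows():
        if (row > 0).all():
            refs[taxon] = np.exp(np.mean([np.log(v) for v in row]))
    factors = {}
    for sample in counts.columns:
        ratios = [counts.loc[t, sample] / r for t, r in refs.items()]
        factors[sample] = float(np.median(ratios))
    return pd.Series(factors)


class TestPruneRare:
    def test_singleton_taxon_removed(self):
        counts = pd.DataFrame({"a": [1, 1], "b": [0, 1]}, index=["t1", "t2"])
        kept = prune_rare(counts)
        assert list(kept.index) == ["t2"]  # total 2 retained, total 1 removed

    def test_two_singleton_occurrences_retained(self):
        counts = pd.DataFrame({"a": [1], "b": [1]}, index=["t1"])
        assert list(prune_rare(counts).index) == ["t1"]

    def test_all_zero_table_keeps_nothing(self):
        counts = pd.DataFrame({"a": [0, 0], "b": [0, 0]}, index=["t1", "t2"])
        assert prune_rare(counts).empty
        assert prune_rare(pd.DataFrame()).empty


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 2], "b": [5, 10, 2]})
        assert size_factors(counts).tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_column_doubles_factor_ratio(self):
        counts = pd.DataFrame({"a": [5, 10, 2], "b": [10, 20, 4]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(5):
            counts = pd.DataFrame(
                rng.poisson(50, size=(20, 6)) + 1,
                index=[f"t{i}" for i in range(20)],
                columns=[f"s{j}" for j in range(6)],
            )
            sf = size_factors(counts)
            oracle = brute_force_size_factors(counts)
            assert np.allclose(sf.to_numpy(), oracle.reindex(sf.index).to_numpy())

    def test_fallback_when_no_taxon_spans_all_samples(self):
        counts = pd.DataFrame({"a": [4, 0], "b": [0, 9]}, index=["t1", "t2"])
        sf = size_factors(counts)
        assert (sf > 0).all()


class TestNbWald:
    def test_strong_enrichment_detected(self, rng):
        a = pd.DataFrame(rng.poisson(800, size=(1, 4)), index=["t0"])
        b = pd.DataFrame(rng.poisson(100, size=(1, 4)), index=["t0"])
        res = nb_wald_enrichment(a, b)
        assert res.loc["t0", "p"] < 1e-4
        assert res.loc["t0", "l2fc"] == pytest.approx(3.0, abs=0.5)

    def test_equal_means_give_large_one_sided_p(self, rng):
        ps = []
        for _ in range(50):
            a = pd.DataFrame(rng.poisson(200, size=(5, 4)))
            b = pd.DataFrame(rng.poisson(200, size=(5, 4)))
            ps.append(nb_wald_enrichment(a, b)["p"].to_numpy())
        assert np.mean(np.concatenate(ps)) > 0.5  # null l2fc=0 < 0.25 threshold

    def test_eightfold_enrichment_power(self, rng):
        """8-fold enriched taxon, n=3 vs 3 at depth 1e4: detected in ≥95% of reps."""
        hits = 0
        n_reps = 200
        base = np.full(20, 1 / 20)
        pa = base.copy()
        pa[0] *= 8
        pa /= pa.sum()
        for _ in range(n_reps):
            a = pd.DataFrame(rng.multinomial(10_000, pa, size=3).T)
            b = pd.DataFrame(rng.multinomial(10_000, base, size=3).T)
            pooled = pd.concat([a, b], axis=1, keys=["x", "y"])
            sf = size_factors(pooled)
            norm = pooled / sf
            res = nb_wald_enrichment(norm["x"], norm["y"])
            hits += res["p"].iloc[0] < 0.05
        assert hits / n_reps >= 0.95

    def test_both_zero_taxa_excluded(self):
        a = pd.DataFrame({"s1": [0, 5], "s2": [0, 6]}, index=["t1", "t2"])
        b = pd.DataFrame({"s3": [0, 5], "s4": [0, 4]}, index=["t1", "t2"])
        res = nb_wald_enrichment(a, b)
        assert list(res.index) == ["t2"]


class TestSparsitySweep:
    def _table(self, rng, n_noise=30):
        """Signal in prevalent taxa; rare noise taxa dilute BH power."""
        sig13 = rng.poisson(400, size=(5, 6))
        sig12 = rng.poisson(100, size=(5, 6))
        noise13 = rng.binomial(1, 0.12, size=(n_noise, 6)) * rng.poisson(2, (n_noise, 6))
        noise12 = rng.binomial(1, 0.12, size=(n_noise, 6)) * rng.poisson(2, (n_noise, 6))
        idx = [f"sig{i}" for i in range(5)] + [f"noise{i}" for i in range(n_noise)]
        c13 = pd.DataFrame(np.vstack([sig13, noise13]), index=idx,
                           columns=[f"a{j}" for j in range(6)])
        c12 = pd.DataFrame(np.vstack([sig12, noise12]), index=idx,
                           columns=[f"b{j}" for j in range(6)])
        return c13, c12

    def test_filtering_increases_rejections(self, rng):
        c13, c12 = self._table(rng)
        res = sparsity_sweep(c13, c12, (0.0, 0.5))
        n_at = {}
        for thr in (0.0, 0.5):
            r = sparsity_sweep(c13, c12, (thr,))
            n_at[thr] = int(r.results["significant"].sum())
        assert res.threshold == max(n_at, key=lambda t: (n_at[t], -t))
        assert n_at[0.5] >= n_at[0.0]

    def test_single_candidate_returned_unchanged(self, rng):
        c13, c12 = self._table(rng)
        assert sparsity_sweep(c13, c12, (0.15,)).threshold == 0.15

    def test_tie_breaks_to_smallest_threshold(self, rng):
        c13 = pd.DataFrame(rng.poisson(100, size=(4, 6)))
        c12 = pd.DataFrame(rng.poisson(100, size=(4, 6)))
        assert sparsity_sweep(c13, c12, (0.0, 0.15, 0.30)).threshold == 0.0

    def test_empty_candidate_list_rejected(self, rng):
        c13, c12 = self._table(rng)
        with pytest.raises(InvalidDesignError):
            sparsity_sweep(c13, c12, ())


class TestMwHrSip:
    def test_default_windows_are_the_three_heavy_intervals(self):
        assert DEFAULT_WINDOWS == ((1.70, 1.73), (1.72, 1.75), (1.74, 1.77))

    def test_incorporator_set_is_union_of_window_positives(self, community, design):
        ft13 = simulate_gradient(community, design, "13C", "xylose", 30, seed=1)
        ft12 = simulate_gradient(community, design, "12C", "xylose", 30, seed=2)
        calls, wres = mw_hr_sip([ft13], [ft12])
        union = set(wres.loc[wres["significant"], "taxon_id"])
        assert set(calls.index[calls["is_incorporator"]]) == union

    def test_calls_invariant_to_column_rescaling(self, community, design):
        """Size-factor normalization absorbs per-sample scale changes."""
        ft13 = simulate_gradient(community, design, "13C", "xylose", 30, seed=1)
        ft12 = simulate_gradient(community, design, "12C", "xylose", 30, seed=2)
        calls, _ = mw_hr_sip([ft13], [ft12])
        scaled = ft13.counts.copy()
        scaled.iloc[:, 3] = scaled.iloc[:, 3] * 10
        ft13s = FractionTable(scaled, ft13.fraction_bd, ft13.gradient_id)
        calls2, _ = mw_hr_sip([ft13s], [ft12])
        assert calls["is_incorporator"].equals(calls2["is_incorporator"])

    def test_first_label_day_is_earliest_positive_day(self, design):
        truth = simulate_community(40, 0.15, seed=21)
        t13, t12 = {}, {}
        for j, day in enumerate([1, 7]):
            t13[day] = [simulate_gradient(truth, design, "13C", "xylose", day, seed=60 + j)]
            t12[day] = [simulate_gradient(truth, design, "12C", "xylose", day, seed=80 + j)]
        calls, wres = mw_hr_sip(t13, t12)
        sig = wres[wres["significant"]]
        for taxon in calls.index[calls["is_incorporator"]]:
            assert calls.loc[taxon, "first_label_day"] == sig.loc[
                sig["taxon_id"] == taxon, "day"
            ].min()

    def test_all_windows_empty_is_an_error(self, community, design):
        ft13 = simulate_gradient(community, design, "13C", "xylose", 1, seed=1)
        ft12 = simulate_gradient(community, design, "12C", "xylose", 1, seed=2)
        with pytest.raises(AnalysisError):
            mw_hr_sip([ft13], [ft12], windows=[(2.0, 2.1)])


class TestBhAndDegree:
    def test_bh_adjustment_is_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        padj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()
        assert (padj >= p - 1e-12).all()

    def test_degree_is_max_l2fc_over_tested_windows(self):
        wres = pd.DataFrame(
            {"taxon_id": ["t1", "t1", "t1", "t2"], "l2fc": [0.1, 0.9, 0.4, -0.3]}
        )
        deg = degree_of_assimilation(wres)
        assert deg["t1"] == pytest.approx(0.9)
        assert deg["t2"] == pytest.approx(-0.3)
        assert np.isnan(deg.reindex(["t3"]).iloc[0])  # untested taxon
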