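import json

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import tlscope as t
from oracles import (
    enum_ranksum_p,
    hypergeom_tail_exact,
    logrank_oe_v,
    product_limit,
    stepup_bh,
)


class TestWilcoxon:
    def test_degenerate_ties_give_p_one(self):
        w, p = t.wilcoxon_rank_sum([1, 1, 1], [1, 1, 1])
        assert p == 1.0

    def test_fully_separated_three_vs_three(self):
        # W = 6 is the extreme rank sum: two-sided p = 2 * 1/C(6,3) = 0.1
        w, p = t.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_mode_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(1, 7))
        ny = int(rng.integers(1, 7))
        x = rng.integers(0, 6, size=nx).astype(float)  # many ties
        y = rng.integers(0, 6, size=ny).astype(float)
        if np.all(np.concatenate([x, y]) == x[0] if nx else False):
            y = y + 1.0
        for alt in ("two-sided", "greater", "less"):
            _, p = t.wilcoxon_rank_sum(x, y, alt)
            if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
                continue
            assert p == pytest.approx(enum_ranksum_p(x, y, alt), abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        # 8 vs 8 with continuity correction: close to enumeration; the
        # residual is bounded by the largest atom of the discrete null
        for _ in range(5):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 8)
            _, p_exact = t.wilcoxon_rank_sum(x, y)  # total 16 <= 20: exact path
            mu = 8 * 17 / 2.0
            ranks = scipy.stats.rankdata(np.concatenate([x, y]))
            w = ranks[:8].sum()
            sd = np.sqrt(8 * 8 / 12.0 * 17)
            p_approx = 2 * scipy.stats.norm.sf((abs(w - mu) - 0.5) / sd)
            assert abs(p_exact - min(p_approx, 1.0)) < 0.015

    def test_empty_group_is_error(self):
        with pytest.raises(t.ParameterError):
            t.wilcoxon_rank_sum([], [1.0])


class TestBH:
    def test_single_p_unchanged(self):
        assert t.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_uniform_ladder_collapses(self):
        out = t.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_stepup_definition_and_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 40)))
        mine = t.bh_adjust(p)
        assert np.allclose(mine, stepup_bh(p), atol=1e-12)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(mine, ref, atol=1e-12)
        assert np.all(mine >= p) and np.all(mine <= 1.0)

    def test_order_preserving_on_sorted_input(self, rng):
        # step-up adjustment never swaps the order of sorted p-values, and
        # reapplication keeps every value a valid (possibly larger) bound
        p = np.sort(rng.uniform(1e-6, 1, size=20))
        once = t.bh_adjust(p)
        assert np.all(np.diff(once) >= -1e-15)
        twice = t.bh_adjust(once)
        assert np.all(twice >= once - 1e-15) and np.all(twice <= 1.0)

    def test_out_of_domain_rejected(self):
        for bad in ([0.0], [1.2], [-0.1]):
            with pytest.raises(t.ParameterError):
                t.bh_adjust(bad)


class TestDifferentialExpression:
    def _norm(self, values):
        values = np.asarray(values, dtype=float)
        return t.NormalizedMatrix(
            values, [f"G{j}" for j in range(values.shape[1])],
            [f"c{i}" for i in range(values.shape[0])],
        )

    def test_identical_groups_retain_nothing(self, rng):
        block = rng.uniform(0, 2, size=(10, 6))
        norm = self._norm(np.vstack([block, block]))
        mask = np.array([True] * 10 + [False] * 10)
        for preset in ("go-deg", "aucell-deg", "marker-set"):
            _, retained = t.differential_expression(norm, mask, preset)
            assert len(retained) == 0

    def test_preset_thresholds_equal_direct_filter(self, rng):
        df = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(200)],
                "log2fc": rng.uniform(-2, 2, 200),
                "p": rng.uniform(1e-6, 1, 200),
            }
        )
        df["p_adj"] = t.bh_adjust(df["p"])
        df["direction"] = np.where(df["log2fc"] >= 0, "up", "down")
        from tlscope.stats import apply_de_preset

        expected = {
            "go-deg": (df["p"] < 0.05) & (df["log2fc"] > 0.2),
            "aucell-deg": (df["p_adj"] < 0.01) & (df["log2fc"] > 0.8),
            "marker-set": (df["p_adj"] < 0.05) & (df["log2fc"].abs() > 0.1),
        }
        for preset, mask in expected.items():
            got = apply_de_preset(df, preset)
            assert list(got["gene"]) == list(df.loc[mask, "gene"])

    def test_planted_tls_genes_recovered(self, annotated_sim):
        _, cells, _, truth, norm, _ = annotated_sim
        mask = truth.cell_region_id > 0
        results, retained = t.differential_expression(norm, mask, preset="go-deg")
        assert {"MKI67", "CXCR5", "CCL2"} <= set(retained["gene"])
        assert (results["p_adj"] >= results["p"] - 1e-15).all()

    def test_small_group_is_error(self, rng):
        norm = self._norm(rng.uniform(0, 1, (5, 3)))
        with pytest.raises(t.ParameterError):
            t.differential_expression(norm, [True] + [False] * 4)


class TestHypergeom:
    def _collection(self, sets):
        return t.GeneSetCollection([t.GeneSet(n, "", g) for n, g in sets.items()])

    def test_zero_overlap_gives_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        coll = self._collection({"S": universe[10:15]})
        rows = t.hypergeom_enrich(t.GeneSet("q", "", universe[:5]), coll, universe)
        assert rows[0].k == 0
        assert rows[0].p == pytest.approx(1.0)

    def test_complete_overlap_exact_value(self):
        universe = [f"G{i}" for i in range(20)]
        coll = self._collection({"S": universe[:5]})
        rows = t.hypergeom_enrich(t.GeneSet("q", "", universe[:5]), coll, universe)
        assert rows[0].p == pytest.approx(1 / 15504, rel=1e-12)

    def test_partial_overlap_equals_summation(self):
        universe = [f"G{i}" for i in range(20)]
        coll = self._collection({"S": universe[:5]})
        query = t.GeneSet("q", "", universe[2:7])  # overlap k=3
        rows = t.hypergeom_enrich(query, coll, universe)
        assert rows[0].k == 3
        assert rows[0].p == pytest.approx(hypergeom_tail_exact(20, 5, 5, 3), rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_instances_match_exact_tail(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 61))
        universe = [f"G{i}" for i in range(N)]
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        coll = self._collection({"S": list(rng.choice(universe, K, replace=False))})
        query = t.GeneSet("q", "", list(rng.choice(universe, n, replace=False)))
        rows = t.hypergeom_enrich(query, coll, universe)
        assert rows[0].p == pytest.approx(
            hypergeom_tail_exact(N, K, n, rows[0].k), rel=1e-10
        )

    def test_empty_query_after_intersection_is_error(self):
        coll = self._collection({"S": ["G1"]})
        with pytest.raises(t.ParameterError):
            t.hypergeom_enrich(t.GeneSet("q", "", ["ZZ"]), coll, ["G1", "G2"])


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        table = pd.DataFrame({"time": [3.0, 5.0, 9.0], "event": [0, 0, 0]})
        curve = t.km_curve(table)
        assert curve.times.size == 0
        assert curve.evaluate(100.0) == 1.0

    def test_single_event_step(self):
        table = pd.DataFrame({"time": [5.0], "event": [1]})
        curve = t.km_curve(table)
        assert curve.evaluate(4.999) == 1.0
        assert curve.evaluate(5.0) == 0.0

    def test_mixed_fixture_matches_product_limit(self):
        table = pd.DataFrame(
            {"time": [1.0, 2.0, 2.0, 3.0, 4.0, 5.0], "event": [1, 1, 0, 1, 0, 1]}
        )
        curve = t.km_curve(table)
        expected = product_limit(table["time"], table["event"])
        assert len(expected) == curve.times.size
        for (tt, ss), ct, cs in zip(expected, curve.times, curve.survival):
            assert ct == tt
            assert cs == pytest.approx(ss, abs=1e-12)

    def test_no_censoring_equals_empirical_survivor(self, rng):
        times = rng.exponential(10, size=30).round(1)
        table = pd.DataFrame({"time": times, "event": 1})
        curve = t.km_curve(table)
        for tt, ss in zip(curve.times, curve.survival):
            assert ss == pytest.approx((times > tt).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=40).round(1)
        events = (rng.random(40) > 0.3).astype(int)
        table = pd.DataFrame({"time": times, "event": events})
        curve = t.km_curve(table)
        kmf = KaplanMeierFitter().fit(times, events)
        for tt, ss in zip(curve.times, curve.survival):
            assert ss == pytest.approx(kmf.predict(tt), abs=1e-9)

    def test_negative_time_is_error(self):
        with pytest.raises(t.ParameterError):
            t.km_curve(pd.DataFrame({"time": [-1.0], "event": [1]}))


class TestLogRank:
    def test_identical_groups_give_chi2_zero(self):
        table = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0]})
        res = t.logrank_test(table, table.copy())
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_symmetric_under_label_swap(self, rng):
        a = pd.DataFrame({"time": rng.exponential(10, 20), "event": 1})
        b = pd.DataFrame({"time": rng.exponential(20, 20), "event": 1})
        r1 = t.logrank_test(a, b)
        r2 = t.logrank_test(b, a)
        assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_eight_subject_fixture_matches_manual_oev(self):
        a = pd.DataFrame({"time": [1.0, 3.0, 5.0, 7.0], "event": [1, 1, 0, 1]})
        b = pd.DataFrame({"time": [2.0, 3.0, 6.0, 8.0], "event": [1, 1, 1, 0]})
        res = t.logrank_test(a, b)
        O, E, V = logrank_oe_v(a["time"], a["event"], b["time"], b["event"])
        assert res.chi2 == pytest.approx((O - E) ** 2 / V, abs=1e-9)
        assert res.observed.sum() == pytest.approx(res.expected.sum(), abs=1e-9)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta = rng.exponential(10, 25)
        tb = rng.exponential(18, 25)
        ea = (rng.random(25) > 0.2).astype(int)
        eb = (rng.random(25) > 0.2).astype(int)
        res = t.logrank_test(
            pd.DataFrame({"time": ta, "event": ea}),
            pd.DataFrame({"time": tb, "event": eb}),
        )
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert res.chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.p_value, abs=1e-9)

    def test_no_events_is_error(self):
        a = pd.DataFrame({"time": [1.0], "event": [0]})
        with pytest.raises(t.ParameterError):
            t.logrank_test(a, a.copy())


class TestMedianSplit:
    def test_two_point_split(self):
        labels = t.median_split(pd.Series([2.0, 6.0]))
        assert list(labels) == ["low", "high"]

    def test_value_at_median_goes_low_under_strict_rule(self):
        labels = t.median_split(pd.Series([1.0, 4.0, 9.0]))
        assert labels.iloc[1] == "low"
        labels_gte = t.median_split(pd.Series([1.0, 4.0, 9.0]), rule="gte")
        assert labels_gte.iloc[1] == "high"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = pd.Series(rng.uniform(0, 10, size=int(rng.integers(2, 30))))
        labels = t.median_split(values)
        med = float(np.sort(values)[(len(values) - 1) // 2 : (len(values) + 2) // 2].mean())
        for v, lab in zip(values, labels):
            assert lab == ("high" if v > med else "low")

    def test_single_sample_is_error(self):
        with pytest.raises(t.ParameterError):
            t.median_split(pd.Series([1.0]))
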