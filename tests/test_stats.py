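import numpy as np
import pandas as pd
import pytest

from _oracles import (anova_type3_oracle, mann_whitney_enumeration,
                      student_t_oracle)
from amyquant.stats import (DEFAULT_COMPARISONS, analyze_metric_table,
                            mann_whitney, sidak_pairwise, two_way_anova,
                            unpaired_t)


def _cells(cells):
    y, a, b = [], [], []
    for (ai, bi), vals in cells.items():
        for v in vals:
            y.append(v)
            a.append(ai)
            b.append(bi)
    return np.array(y), np.array(a), np.array(b)


class TestTwoWayAnova:
    def test_equal_cell_means_zero_F(self):
        y, a, b = _cells({("WT", "HEM"): [5, 7], ("WT", "KO"): [5, 7],
                          ("APPPS1", "HEM"): [5, 7],
                          ("APPPS1", "KO"): [5, 7]})
        tab = two_way_anova(y, a, b)
        for eff in ("factorA", "factorB", "interaction"):
            assert tab.effects[eff]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_matches_model_comparison_oracle(self):
        y, a, b = _cells({("WT", "HEM"): [10, 12], ("WT", "KO"): [20, 22],
                          ("APPPS1", "HEM"): [30, 32],
                          ("APPPS1", "KO"): [40, 42]})
        tab = two_way_anova(y, a, b)
        oracle = anova_type3_oracle(y, a, b)
        for eff in ("factorA", "factorB", "interaction"):
            F, p = oracle[eff]
            assert tab.effects[eff]["F"] == pytest.approx(F, abs=1e-10)
            assert tab.effects[eff]["p"] == pytest.approx(p, abs=1e-10)

    def test_unbalanced_matches_oracle(self, rng):
        ns = {("WT", "HEM"): 3, ("WT", "KO"): 5,
              ("APPPS1", "HEM"): 4, ("APPPS1", "KO"): 6}
        cells = {}
        for (ai, bi), n in ns.items():
            mu = 1 + 2 * (ai == "APPPS1") + 1.5 * (bi == "KO")
            cells[(ai, bi)] = mu + rng.normal(size=n)
        y, a, b = _cells(cells)
        tab = two_way_anova(y, a, b)
        oracle = anova_type3_oracle(y, a, b)
        for eff in ("factorA", "factorB", "interaction"):
            F, p = oracle[eff]
            assert tab.effects[eff]["F"] == pytest.approx(F, abs=1e-10)
            assert tab.effects[eff]["p"] == pytest.approx(p, abs=1e-10)

    def test_level_relabelling_invariance(self, rng):
        y = rng.normal(size=14)
        a = np.array(["WT"] * 7 + ["APPPS1"] * 7)
        b = np.tile(["HEM", "KO"], 7)
        t1 = two_way_anova(y, a, b)
        swap = {"WT": "zWT", "APPPS1": "aAPP"}
        t2 = two_way_anova(y, np.vectorize(swap.get)(a), b)
        for eff in ("factorA", "factorB", "interaction"):
            assert t1.effects[eff]["ss"] == pytest.approx(
                t2.effects[eff]["ss"], rel=1e-10)

    def test_empty_cell_rejected(self):
        y, a, b = _cells({("WT", "HEM"): [1, 2], ("WT", "KO"): [3, 4],
                          ("APPPS1", "HEM"): [5, 6]})
        with pytest.raises(ValueError):
            two_way_anova(y, a, b)

    def test_zero_residual_flagged(self):
        y, a, b = _cells({("WT", "HEM"): [1, 1], ("WT", "KO"): [2, 2],
                          ("APPPS1", "HEM"): [3, 3],
                          ("APPPS1", "KO"): [4, 4]})
        tab = two_way_anova(y, a, b)
        assert tab.zero_residual
        assert np.isnan(tab.effects["factorA"]["p"])

    def test_residual_df(self):
        y, a, b = _cells({("WT", "HEM"): [1, 2, 3], ("WT", "KO"): [3, 4],
                          ("APPPS1", "HEM"): [5, 6],
                          ("APPPS1", "KO"): [7, 8]})
        assert two_way_anova(y, a, b).df_residual == 9 - 4


class TestSidak:
    def _fit(self, rng):
        ns = {("WT", "HEM"): 5, ("WT", "KO"): 5,
              ("APPPS1", "HEM"): 5, ("APPPS1", "KO"): 5}
        cells = {k: 3 * (k[0] == "APPPS1") + rng.normal(size=n)
                 for k, n in ns.items()}
        y, a, b = _cells(cells)
        return y, list(zip(a, b)), two_way_anova(y, a, b)

    def test_single_comparison_identity(self, rng):
        y, g, tab = self._fit(rng)
        res = sidak_pairwise(y, g, [DEFAULT_COMPARISONS[0]], tab)
        assert res[0].m == 1
        assert res[0].p_adj == res[0].p_raw

    def test_closed_form_family_of_four(self, rng):
        y, g, tab = self._fit(rng)
        res = sidak_pairwise(y, g, DEFAULT_COMPARISONS, tab)
        for r in res:
            assert r.m == 4
            assert r.p_adj == pytest.approx(1 - (1 - r.p_raw) ** 4, abs=1e-15)
            assert r.p_raw <= r.p_adj <= 1.0

    def test_adjustment_monotone_in_m(self, rng):
        y, g, tab = self._fit(rng)
        p1 = sidak_pairwise(y, g, DEFAULT_COMPARISONS[:2], tab)[0].p_adj
        p2 = sidak_pairwise(y, g, DEFAULT_COMPARISONS, tab)[0].p_adj
        assert p2 >= p1

    def test_identical_groups_p_one(self):
        y, a, b = _cells({("WT", "HEM"): [1.0, 2.0], ("WT", "KO"): [1.0, 2.0],
                          ("APPPS1", "HEM"): [1.0, 2.0],
                          ("APPPS1", "KO"): [1.0, 2.0]})
        tab = two_way_anova(y, a, b)
        res = sidak_pairwise(y, list(zip(a, b)),
                             [(("APPPS1", "KO"), ("APPPS1", "HEM"))], tab)
        assert res[0].mean_diff == 0.0
        assert res[0].p_raw == pytest.approx(1.0)
        assert res[0].p_adj == pytest.approx(1.0)

    def test_unknown_group_rejected(self, rng):
        y, g, tab = self._fit(rng)
        with pytest.raises(ValueError, match="unknown group"):
            sidak_pairwise(y, g, [(("APPPS1", "XX"), ("WT", "HEM"))], tab)


class TestUnpairedT:
    def test_identical_samples(self):
        t, df, p = unpaired_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        t, df, p = unpaired_t([1, 2, 3], [4, 5, 6])
        to, dfo, po = student_t_oracle([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(to, abs=1e-12)
        assert df == dfo
        assert p == pytest.approx(po, abs=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=8) + 1
        t1, _, p1 = unpaired_t(x, y)
        t2, _, p2 = unpaired_t(10 * x, 10 * y)
        assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)

    def test_welch_df_not_integer(self, rng):
        x = rng.normal(scale=1, size=5)
        y = rng.normal(scale=5, size=12)
        _, df_w, _ = unpaired_t(x, y, welch=True)
        assert df_w < 15  # Satterthwaite df below pooled df

    def test_zero_variance_flagged(self):
        t, df, p = unpaired_t([1.0, 1.0], [2.0, 2.0])
        assert np.isnan(t)


class TestMannWhitney:
    def test_complete_separation_small(self):
        U, p = mann_whitney([1, 2], [3, 4])
        assert U == 0.0
        assert p == pytest.approx(1 / 3)

    def test_single_tied_pair(self):
        U, p = mann_whitney([1.0], [1.0])
        assert U == 0.5 and p == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(3):
            x = np.round(rng.normal(size=5), 1)
            y = np.round(rng.normal(loc=0.5, size=5), 1)
            U, p = mann_whitney(x, y)
            Uo, po = mann_whitney_enumeration(x, y)
            assert U == Uo and p == pytest.approx(po, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        from scipy.stats import mannwhitneyu
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        U, p = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert U == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation(self, rng):
        from scipy.stats import mannwhitneyu
        x = rng.normal(size=25)
        y = rng.normal(loc=0.8, size=25)
        U, p = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestAnalyzeMetricTable:
    def _table(self, rng, effect=0.0):
        rows = []
        for i, (app, apo) in enumerate(
                [("WT", "HEM"), ("WT", "KO"),
                 ("APPPS1", "HEM"), ("APPPS1", "KO")]):
            for j in range(6):
                v = rng.normal() + effect * (app == "APPPS1")
                rows.append({"animal_id": f"A{i}{j}", "app_genotype": app,
                             "apoa1_genotype": apo, "region": "cortex",
                             "metric": "m", "value": v})
        return pd.DataFrame(rows)

    def test_gate_blocks_null_metric(self, rng):
        # constructed null with tiny spread around equal means
        df = self._table(np.random.default_rng(5), effect=0.0)
        # force non-significance deterministically: identical cell patterns
        df["value"] = np.tile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 4)
        anova, comps = analyze_metric_table(df, posthoc_gate=True)
        assert len(anova) == 4
        assert comps.empty

    def test_gate_open_for_large_effect(self, rng):
        df = self._table(rng, effect=50.0)
        anova, comps = analyze_metric_table(df, posthoc_gate=True)
        assert len(comps) == 4
        assert (comps["m"] == 4).all()

    def test_gate_override(self):
        df = self._table(np.random.default_rng(5))
        df["value"] = np.tile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 4)
        _, comps = analyze_metric_table(df, posthoc_gate=False)
        assert len(comps) == 4
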