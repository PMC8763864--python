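"""t-test, two-way ANOVA + Tukey, ddCt: oracle equivalence and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from mechanoquant import quant_stats as qs
from mechanoquant import synthetic_data as synth


def _hand_anova_balanced(df):
    """Independent oracle: textbook sums-of-squares two-way ANOVA for a
    balanced design (type I = type III there)."""
    grand = df.value.mean()
    n = df.groupby(["factorA", "factorB"]).size().iloc[0]
    means_a = df.groupby("factorA").value.mean()
    means_b = df.groupby("factorB").value.mean()
    means_ab = df.groupby(["factorA", "factorB"]).value.mean()
    a_levels, b_levels = means_a.index, means_b.index
    ss_a = n * len(b_levels) * ((means_a - grand) ** 2).sum()
    ss_b = n * len(a_levels) * ((means_b - grand) ** 2).sum()
    ss_ab = n * sum(
        (means_ab[(a, b)] - means_a[a] - means_b[b] + grand) ** 2
        for a in a_levels for b in b_levels)
    ss_err = sum(
        ((df[(df.factorA == a) & (df.factorB == b)].value
          - means_ab[(a, b)]) ** 2).sum()
        for a in a_levels for b in b_levels)
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = len(df) - len(a_levels) * len(b_levels)
    ms_err = ss_err / df_err
    out = {}
    for name, ss, d in (("A", ss_a, df_a), ("B", ss_b, df_b),
                        ("AB", ss_ab, df_ab)):
        f = (ss / d) / ms_err
        out[f"F_{name}"] = f
        out[f"p_{name}"] = sps.f.sf(f, d, df_err)
    return out


class TestTTest:
    def test_identical_groups(self):
        res = qs.two_sided_t_test([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert res.statistic["t"] == 0.0
        assert res.p_value["p"] == 1.0

    def test_matches_scipy_to_1e8(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(3, 20))
            b = rng.normal(0.5, 2, rng.integers(3, 20))
            mine = qs.two_sided_t_test(a, b)
            ref = sps.ttest_ind(a, b)
            assert abs(mine.statistic["t"] - ref.statistic) < 1e-8
            assert abs(mine.p_value["p"] - ref.pvalue) < 1e-8
            mw = qs.two_sided_t_test(a, b, welch=True)
            rw = sps.ttest_ind(a, b, equal_var=False)
            assert abs(mw.statistic["t"] - rw.statistic) < 1e-8
            assert abs(mw.p_value["p"] - rw.pvalue) < 1e-8

    def test_swapping_groups_negates_t(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]
        r1 = qs.two_sided_t_test(a, b)
        r2 = qs.two_sided_t_test(b, a)
        assert r1.statistic["t"] == pytest.approx(-r2.statistic["t"])
        assert r1.p_value["p"] == pytest.approx(r2.p_value["p"])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            qs.two_sided_t_test([1.0], [2.0, 3.0])


@pytest.fixture(scope="module")
def balanced_table():
    return synth.gen_group_table(
        {("a1", "b1"): 0.0, ("a1", "b2"): 1.0,
         ("a2", "b1"): 0.5, ("a2", "b2"): 2.0},
        noise_sd=1.0, n_per_group=8, seed=11)


class TestTwoWayAnova:
    def test_matches_hand_computed_sums_of_squares(self, balanced_table):
        res = qs.two_way_anova_tukey(balanced_table)
        oracle = _hand_anova_balanced(balanced_table)
        for key in ("F_A", "F_B", "F_AB"):
            assert abs(res.statistic[key] - oracle[key]) < 1e-8
        for key in ("p_A", "p_B", "p_AB"):
            assert abs(res.p_value[key] - oracle[key]) < 1e-8

    def test_tukey_matches_statsmodels(self, balanced_table):
        res = qs.two_way_anova_tukey(balanced_table)
        cells = (balanced_table.factorA + ":"
                 + balanced_table.factorB).to_numpy()
        ref = pairwise_tukeyhsd(balanced_table.value.to_numpy(), cells)
        mine = res.post_hoc.sort_values(["group1", "group2"])
        assert np.allclose(np.sort(mine.p_adj.to_numpy()),
                           np.sort(ref.pvalues), atol=1e-8)
        assert np.allclose(np.sort(np.abs(mine.mean_difference.to_numpy())),
                           np.sort(np.abs(ref.meandiffs)), atol=1e-10)

    def test_tukey_matches_statsmodels_unbalanced(self):
        df = synth.gen_group_table(
            {("a1", "b1"): 0.0, ("a1", "b2"): 1.0,
             ("a2", "b1"): 0.5, ("a2", "b2"): 2.0},
            noise_sd=1.0, n_per_group=9, seed=13)
        df = df.iloc[:-4]              # unbalance the last cell
        res = qs.two_way_anova_tukey(df)
        cells = (df.factorA + ":" + df.factorB).to_numpy()
        ref = pairwise_tukeyhsd(df.value.to_numpy(), cells)
        assert np.allclose(np.sort(res.post_hoc.p_adj.to_numpy()),
                           np.sort(ref.pvalues), atol=1e-8)

    def test_pure_main_effect_isolated(self):
        df = synth.gen_group_table(
            {("a1", "b1"): 0.0, ("a1", "b2"): 0.0,
             ("a2", "b1"): 5.0, ("a2", "b2"): 5.0},
            noise_sd=1e-4, n_per_group=5, seed=1)
        res = qs.two_way_anova_tukey(df)
        assert res.p_value["p_A"] < 1e-10
        assert res.p_value["p_B"] > 0.1
        assert res.p_value["p_AB"] > 0.1

    def test_tukey_adjusted_p_not_below_pairwise_p(self, balanced_table):
        res = qs.two_way_anova_tukey(balanced_table)
        df = balanced_table
        df = df.assign(cell=df.factorA + ":" + df.factorB)
        for _, row in res.post_hoc.iterrows():
            a = df.loc[df.cell == row.group1, "value"]
            b = df.loc[df.cell == row.group2, "value"]
            raw = qs.two_sided_t_test(a, b).p_value["p"]
            assert row.p_adj >= raw - 1e-12

    def test_type_three_equals_type_one_when_balanced(self, balanced_table):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        model = smf.ols("value ~ C(factorA, Sum) * C(factorB, Sum)",
                        data=balanced_table).fit()
        t1 = anova_lm(model, typ=1)
        res = qs.two_way_anova_tukey(balanced_table)
        assert res.statistic["F_A"] == pytest.approx(t1["F"].iloc[0])
        assert res.statistic["F_B"] == pytest.approx(t1["F"].iloc[1])
        assert res.statistic["F_AB"] == pytest.approx(t1["F"].iloc[2])

    def test_empty_design_cell_named(self):
        df = synth.gen_group_table(
            {("a1", "b1"): 0.0, ("a1", "b2"): 1.0, ("a2", "b1"): 0.5},
            noise_sd=1.0, n_per_group=4, seed=2)
        with pytest.raises(ValueError, match="a2.*b2"):
            qs.two_way_anova_tukey(df)


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(rows,
                            columns=["sample", "condition", "gene", "ct"])

    def test_calibrator_fold_is_one(self):
        tbl = self._table([("s1", "ctrl", "T", 20.0),
                           ("s1", "ctrl", "GAPDH", 15.0)])
        out = qs.ddct(tbl, "GAPDH", "ctrl")
        assert out.fold_change.iloc[0] == 1.0

    def test_worked_example_fold_quarter(self):
        # control dCt = 20 - 15 = 5; treated dCt = 22 - 15 = 7
        # ddCt = 2 -> fold = 2^-2 = 0.25
        tbl = self._table([("c1", "ctrl", "T", 20.0),
                           ("c1", "ctrl", "GAPDH", 15.0),
                           ("t1", "trt", "T", 22.0),
                           ("t1", "trt", "GAPDH", 15.0)])
        out = qs.ddct(tbl, "GAPDH", "ctrl")
        trt = out[out.condition == "trt"]
        assert trt.delta_delta_ct.iloc[0] == 2.0
        assert trt.fold_change.iloc[0] == 0.25

    def test_negative_ddct_doubles(self):
        assert 2.0 ** -(-1.0) == 2.0
        tbl = self._table([("c1", "ctrl", "T", 20.0),
                           ("c1", "ctrl", "GAPDH", 15.0),
                           ("t1", "trt", "T", 19.0),
                           ("t1", "trt", "GAPDH", 15.0)])
        out = qs.ddct(tbl, "GAPDH", "ctrl")
        assert out[out.condition == "trt"].fold_change.iloc[0] == 2.0

    def test_fold_strictly_decreasing_in_ddct(self):
        ddcts = np.linspace(-3, 3, 13)
        folds = 2.0 ** (-ddcts)
        assert np.all(np.diff(folds) < 0)

    def test_replicates_averaged_before_delta(self):
        tbl = self._table([("c1", "ctrl", "T", 20.0),
                           ("c1", "ctrl", "T", 21.0),
                           ("c1", "ctrl", "GAPDH", 15.0),
                           ("c1", "ctrl", "GAPDH", 16.0)])
        out = qs.ddct(tbl, "GAPDH", "ctrl")
        assert out.delta_ct.iloc[0] == pytest.approx(5.0)

    def test_missing_reference_gene_rejected(self):
        tbl = self._table([("s1", "ctrl", "T", 20.0),
                           ("s1", "ctrl", "GAPDH", 15.0),
                           ("s2", "trt", "T", 21.0)])
        with pytest.raises(ValueError, match="GAPDH.*s2"):
            qs.ddct(tbl, "GAPDH", "ctrl")


class TestTypeIError:
    @staticmethod
    def _null_ttest(rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        return qs.two_sided_t_test(a, b).p_value["p"]

    def test_alpha_extremes(self):
        assert qs.type_i_error_check(self._null_ttest, 50, alpha=0.0) == 0.0
        assert qs.type_i_error_check(self._null_ttest, 50, alpha=1.0) == 1.0

    def test_nominal_level_roughly_held(self):
        rate = qs.type_i_error_check(self._null_ttest, 500, alpha=0.05,
                                     seed=3)
        assert 0.03 <= rate <= 0.07

    def test_stars_mapping(self):
        assert qs.significance_stars(0.2) == "ns"
        assert qs.significance_stars(0.03) == "*"
        assert qs.significance_stars(0.005) == "**"
        assert qs.significance_stars(0.0005) == "***"
        assert qs.significance_stars(0.00005) == "****"
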