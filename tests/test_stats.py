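"""Oracle-driven validation of the statistics module.

Each procedure is checked against an independent route: closed forms,
exhaustive enumeration, explicit risk-set tabulation, and the reference
implementations in scipy / statsmodels / lifelines.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from flyquant import stats as st


class TestWelchT:
    def test_closed_form_example(self):
        # s² = 1 in both groups, SE = sqrt(2/3), diff = −1
        res = st.welch_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.0 / math.sqrt(2.0 / 3.0), abs=1e-12)
        assert res.statistic == pytest.approx(-1.224744871391589, abs=1e-9)
        assert res.df == pytest.approx(4.0, abs=1e-9)

    def test_identical_groups(self):
        res = st.welch_t([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_variance_degenerate(self):
        res = st.welch_t([2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0 and res.p_value == 1.0
        res = st.welch_t([3.0, 3.0], [2.0, 2.0])
        assert res.p_value == 0.0 and res.extra.get("degenerate")

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            st.welch_t([1.0], [2.0, 3.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(4, 12))
        y = rng.normal(0.5, 2.0, size=rng.integers(4, 12))
        mine = st.welch_t(x, y)
        ref = ttest_ind(x, y, equal_var=False)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_against_permutation_oracle(self):
        # moderately sized normal samples: the t reference distribution and
        # the permutation null agree to a couple of percent
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        obs = abs(x.mean() - y.mean())
        pooled = np.concatenate([x, y])
        draws = 200_000
        idx = np.argsort(rng.random((draws, 20)), axis=1)[:, :10]
        xs = pooled[idx]
        perm_diff = np.abs(xs.mean(axis=1) - (pooled.sum() - xs.sum(axis=1)) / 10)
        p_perm = float((perm_diff >= obs - 1e-12).mean())
        assert st.welch_t(x, y).p_value == pytest.approx(p_perm, abs=0.02)


class TestWilcoxonRankSum:
    def test_exact_enumeration_example(self):
        # all C(4,2)=6 rank assignments; only {1,2} is as extreme low,
        # doubled for the two-sided test: p = 2/6
        res = st.wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert res.extra["method"] == "exact"

    def test_identical_values(self):
        res = st.wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_scipy_enumeration(self, seed):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(0.8, size=7)
        mine = st.wilcoxon_rank_sum(x, y)
        assert mine.extra["method"] == "exact"
        ref = mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_near_exact(self):
        # tie/continuity-corrected approximation vs enumeration at n = 8
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(40):
            x = rng.normal(size=8)
            y = rng.normal(0.3, size=8)
            pooled = np.concatenate([x, y])
            w = st._midranks(pooled)[:8].sum()
            exact = st._exact_rank_sum_p(w, 8, 8)
            approx = st._approx_rank_sum_p(w, 8, 8, pooled)
            worst = max(worst, abs(exact - approx))
        assert worst < 0.02

    def test_tie_handling_matches_scipy(self):
        from scipy.stats import mannwhitneyu

        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0, 9.0]
        y = [2.0, 2.0, 4.0, 5.0, 6.0, 6.0, 7.0, 7.0, 7.0, 10.0]
        mine = st.wilcoxon_rank_sum(x, y)
        assert mine.extra["method"] == "normal_approx"
        ref = mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def _balanced_closed_form_ss(df, response, fa, fb):
    """Classical balanced two-way decomposition, computed from cell means."""
    y = df[response].to_numpy(dtype=float)
    grand = y.mean()
    a_levels = sorted(df[fa].unique())
    b_levels = sorted(df[fb].unique())
    n_cell = len(df) // (len(a_levels) * len(b_levels))
    ss_a = sum(
        (df.loc[df[fa] == a, response].mean() - grand) ** 2
        for a in a_levels) * n_cell * len(b_levels)
    ss_b = sum(
        (df.loc[df[fb] == b, response].mean() - grand) ** 2
        for b in b_levels) * n_cell * len(a_levels)
    ss_ab = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = df.loc[(df[fa] == a) & (df[fb] == b), response].mean()
            ma = df.loc[df[fa] == a, response].mean()
            mb = df.loc[df[fb] == b, response].mean()
            ss_ab += n_cell * (cell - ma - mb + grand) ** 2
    return ss_a, ss_b, ss_ab


class TestTwoWayAnova:
    @staticmethod
    def _random_table(seed, balanced=True, ka=2, kb=3):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(ka):
            for j in range(kb):
                n = 5 if balanced else int(rng.integers(3, 8))
                mu = 0.7 * i + 0.4 * j + 0.5 * i * j
                for v in rng.normal(mu, 1.0, size=n):
                    rows.append({"a": f"a{i}", "b": f"b{j}", "y": v})
        return pd.DataFrame(rows)

    def test_identical_cells_give_zero_f(self):
        df = pd.DataFrame({
            "a": ["x"] * 4 + ["y"] * 4,
            "b": ["u", "u", "v", "v"] * 2,
            "y": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0],
        })
        res = st.two_way_anova(df, "y", "a", "b")
        for eff in res.effects.values():
            assert eff.statistic == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_balanced_conservation_and_closed_form(self, seed):
        df = self._random_table(seed, balanced=True)
        res = st.two_way_anova(df, "y", "a", "b")
        total = sum(res.ss.values()) + res.ss_error
        assert total == pytest.approx(res.ss_total, rel=1e-9)
        ss_a, ss_b, ss_ab = _balanced_closed_form_ss(df, "y", "a", "b")
        assert res.ss["a"] == pytest.approx(ss_a, rel=1e-8)
        assert res.ss["b"] == pytest.approx(ss_b, rel=1e-8)
        assert res.ss["interaction"] == pytest.approx(ss_ab, rel=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_type3_matches_statsmodels_on_unbalanced_design(self, seed):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = self._random_table(seed, balanced=False)
        res = st.two_way_anova(df, "y", "a", "b", ss_type="III")
        ref = anova_lm(smf.ols("y ~ C(a, Sum)*C(b, Sum)", data=df).fit(), typ=3)
        assert res.ss["a"] == pytest.approx(ref.loc["C(a, Sum)", "sum_sq"], rel=1e-8)
        assert res.ss["b"] == pytest.approx(ref.loc["C(b, Sum)", "sum_sq"], rel=1e-8)
        assert res.ss["interaction"] == pytest.approx(
            ref.loc["C(a, Sum):C(b, Sum)", "sum_sq"], rel=1e-8)
        for mine, name in [(res.effects["a"], "C(a, Sum)"),
                           (res.effects["b"], "C(b, Sum)")]:
            assert mine.p_value == pytest.approx(ref.loc[name, "PR(>F)"], rel=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_type2_matches_statsmodels(self, seed):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = self._random_table(seed + 10, balanced=False)
        res = st.two_way_anova(df, "y", "a", "b", ss_type="II")
        ref = anova_lm(smf.ols("y ~ C(a)*C(b)", data=df).fit(), typ=2)
        assert res.ss["a"] == pytest.approx(ref.loc["C(a)", "sum_sq"], rel=1e-8)
        assert res.ss["b"] == pytest.approx(ref.loc["C(b)", "sum_sq"], rel=1e-8)

    def test_type3_equals_type2_when_balanced(self):
        df = self._random_table(5, balanced=True)
        r3 = st.two_way_anova(df, "y", "a", "b", ss_type="III")
        r2 = st.two_way_anova(df, "y", "a", "b", ss_type="II")
        for k in r3.ss:
            assert r3.ss[k] == pytest.approx(r2.ss[k], rel=1e-9)

    def test_empty_and_thin_cells_rejected(self):
        df = self._random_table(0, balanced=True)
        with pytest.raises(ValueError, match="empty cell"):
            st.two_way_anova(df[~((df.a == "a0") & (df.b == "b1"))], "y", "a", "b")
        thin = df[~((df.a == "a0") & (df.b == "b1"))].copy()
        extra = pd.DataFrame([{"a": "a0", "b": "b1", "y": 0.0}])
        with pytest.raises(ValueError, match="fewer than 2"):
            st.two_way_anova(pd.concat([thin, extra]), "y", "a", "b")

    def test_pairwise_contrasts_use_pooled_error(self):
        df = self._random_table(2, balanced=True)
        res = st.two_way_anova(df, "y", "a", "b")
        con = st.pairwise_contrasts(res, within="b", compare=("a1", "a0"))
        assert len(con) == 3 and (con["m"] == 3).all()
        row = con.iloc[0]
        s1 = res.cell_stats[("a1", row["b"])]
        s2 = res.cell_stats[("a0", row["b"])]
        se = math.sqrt(res.mse * (1 / s1["n"] + 1 / s2["n"]))
        assert row["t"] == pytest.approx((s1["mean"] - s2["mean"]) / se, rel=1e-12)
        assert (con["p_adj"] >= con["p"] - 1e-15).all()


class TestSidak:
    def test_closed_form(self):
        assert st.sidak_adjust(0.01, 5) == pytest.approx(0.04900995, abs=1e-8)
        assert st.sidak_adjust(0.0, 7) == 0.0
        assert st.sidak_adjust(0.2, 1) == pytest.approx(0.2, abs=1e-15)
        assert st.sidak_adjust(1.0, 3) == 1.0

    @given(p=hs.floats(0.0, 1.0), m=hs.integers(1, 50))
    @settings(deadline=None, max_examples=200)
    def test_adjustment_never_below_raw(self, p, m):
        adj = st.sidak_adjust(p, m)
        assert 0.0 <= adj <= 1.0
        assert adj >= p - 1e-12

    @given(p=hs.floats(0.001, 0.999), m=hs.integers(1, 20))
    @settings(deadline=None, max_examples=200)
    def test_monotone_in_p_and_m(self, p, m):
        assert st.sidak_adjust(p, m + 1) >= st.sidak_adjust(p, m)
        assert st.sidak_adjust(min(p * 1.1, 1.0), m) >= st.sidak_adjust(p, m)


def _logrank_risk_set_oracle(durations, groups):
    """Explicit two-group risk-set tabulation of the log-rank statistic."""
    durations = np.asarray(durations, float)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(durations)):
        at_risk = durations >= t
        n = at_risk.sum()
        n0 = (at_risk & (groups == g0)).sum()
        d = (durations == t).sum()
        d0 = ((durations == t) & (groups == g0)).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n - d) / (n - 1) * n0 * (n - n0) / n ** 2
    return o_minus_e ** 2 / var


class TestMantelCox:
    def test_identical_death_times(self):
        res = st.mantel_cox([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_small_instance_against_risk_set_oracle(self):
        # G1 dies at {1,2}, G2 at {3,4}: every risk set tabulated by hand
        d = [1.0, 2.0, 3.0, 4.0]
        g = ["g1", "g1", "g2", "g2"]
        res = st.mantel_cox(d, g)
        assert res.statistic == pytest.approx(_logrank_risk_set_oracle(d, g), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_five_subject_instances_against_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.exponential(5.0, 5).round(1) + 1.0
        g = np.array(["a", "a", "a", "b", "b"])
        res = st.mantel_cox(d, g)
        assert res.statistic == pytest.approx(_logrank_risk_set_oracle(d, g), rel=1e-10)

    @pytest.mark.parametrize("k,seed", [(2, 0), (3, 1)])
    def test_matches_lifelines(self, k, seed):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(seed)
        n = 30
        d = np.concatenate([rng.exponential(8.0 / (1 + i), n) for i in range(k)])
        g = np.repeat([f"g{i}" for i in range(k)], n)
        res = st.mantel_cox(d, g)
        ref = multivariate_logrank_test(d, g)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_censoring_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(3)
        d1, d2 = rng.exponential(8, 25), rng.exponential(4, 25)
        c1, c2 = rng.random(25) > 0.2, rng.random(25) > 0.3
        res = st.mantel_cox(np.concatenate([d1, d2]),
                            ["a"] * 25 + ["b"] * 25,
                            np.concatenate([c1, c2]))
        ref = logrank_test(d1, d2, event_observed_A=c1, event_observed_B=c2)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.mantel_cox([1.0, 2.0], ["a", "a"])

    def test_detects_strong_hazard_ratio(self):
        rng = np.random.default_rng(0)
        rej = 0
        for _ in range(50):
            d = np.concatenate([rng.exponential(10.0, 90),
                                rng.exponential(10.0 / 3.0, 90)])
            g = ["NF"] * 90 + ["HSD"] * 90
            rej += st.mantel_cox(d, g).p_value < 0.05
        assert rej == 50  # hazard ratio 3 at n=90/group is essentially certain
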