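import math

import numpy as np
import pytest
from scipy import stats

from tgskit.compare import (
    compare_groups,
    omnibus_f,
    pairwise_t,
    tertile_or,
    tertile_split,
)
from tgskit.errors import DegenerateGroupError, UndefinedStatisticError

from .oracles import anova_f_bruteforce, pooled_t_bruteforce


class TestOmnibusF:
    def test_hand_anova_two_groups(self):
        res = omnibus_f({"a": [1, 2, 3], "b": [4, 5, 6]})
        f_oracle, df1, df2 = anova_f_bruteforce([[1, 2, 3], [4, 5, 6]])
        assert (res.df1, res.df2) == (df1, df2) == (1, 4)
        assert res.F == pytest.approx(13.5, abs=1e-12)
        assert res.F == pytest.approx(f_oracle, abs=1e-12)

    def test_df_convention_for_three_groups(self):
        rng = np.random.default_rng(7)
        groups = {g: rng.normal(size=n) for g, n in [("a", 86), ("b", 73), ("c", 240)]}
        res = omnibus_f(groups)
        assert (res.df1, res.df2) == (2, 396)
        # cross-check against scipy's one-way ANOVA
        f, p = stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(float(f), rel=1e-12)
        assert res.p == pytest.approx(float(p), rel=1e-9)

    def test_identical_constant_groups_give_f0_p1(self):
        res = omnibus_f({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
        assert (res.F, res.p) == (0.0, 1.0)

    def test_tiny_group_rejected(self):
        with pytest.raises(DegenerateGroupError, match="'b'"):
            omnibus_f({"a": [1, 2], "b": [3]})

    def test_equals_regression_on_group_indicators(self):
        """The omnibus F is the F of an OLS fit on group dummies."""
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        y = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.5, 1, 25),
                            rng.normal(0.2, 1, 40)])
        g = np.repeat([0, 1, 2], [30, 25, 40])
        X = statsmodels.add_constant(np.column_stack([(g == 1), (g == 2)]).astype(float))
        fit = statsmodels.OLS(y, X).fit()
        res = omnibus_f({"a": y[g == 0], "b": y[g == 1], "c": y[g == 2]})
        assert res.F == pytest.approx(float(fit.fvalue), rel=1e-10)
        assert res.p == pytest.approx(float(fit.f_pvalue), rel=1e-8)


class TestPairwiseT:
    def test_hand_pooled_t(self):
        res = pairwise_t([1, 2, 3], [2, 3, 4])
        t_oracle, df = pooled_t_bruteforce([1, 2, 3], [2, 3, 4])
        assert res.df == df == 4
        assert res.t == pytest.approx(-math.sqrt(1.5), abs=1e-12)
        assert res.t == pytest.approx(t_oracle, abs=1e-12)

    def test_df_convention(self):
        rng = np.random.default_rng(3)
        res = pairwise_t(rng.normal(size=86), rng.normal(size=73))
        assert res.df == 157

    def test_identical_samples(self):
        res = pairwise_t([3, 3, 3], [3, 3, 3])
        assert (res.t, res.p) == (0.0, 1.0)
        assert res.zero_variance

    def test_zero_variance_unequal_means(self):
        res = pairwise_t([4, 4], [3, 3])
        assert res.t == math.inf and res.p == 0.0 and res.zero_variance

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=20), rng.normal(0.4, 1.2, size=15)
        t = pairwise_t(a, b)
        f = omnibus_f({"a": a, "b": b})
        assert f.F == pytest.approx(t.t ** 2, abs=1e-9)
        assert f.p == pytest.approx(t.p, abs=1e-12)

    def test_p_agrees_with_permutation_test(self):
        """Two-sided pooled-t p matches a label-permutation null on small n."""
        rng = np.random.default_rng(17)
        a = [2.1, 3.4, 1.8, 4.0, 2.9, 3.3]
        b = [3.9, 4.4, 5.1, 3.2, 4.8]
        res = pairwise_t(a, b)
        pooled = np.array(a + b)
        t_obs = abs(res.t)
        n_perm, hits = 10_000, 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t_p, _ = pooled_t_bruteforce(list(perm[:6]), list(perm[6:]))
            hits += abs(t_p) >= t_obs - 1e-12
        p_perm = hits / n_perm
        # Monte-Carlo tolerance: 4 * sqrt(p(1-p)/n) plus normal-vs-permutation gap
        assert res.p == pytest.approx(p_perm, abs=0.02)


class TestTertileSplit:
    def test_scores_1_to_9_split_into_equal_thirds(self):
        scores = {f"s{i}": float(i) for i in range(1, 10)}
        split = tertile_split(scores)
        assert sorted(split.members("low")) == ["s1", "s2", "s3"]
        assert sorted(split.members("middle")) == ["s4", "s5", "s6"]
        assert sorted(split.members("high")) == ["s7", "s8", "s9"]
        assert split.lower_cut == pytest.approx(np.quantile(np.arange(1, 10), 1 / 3))

    def test_all_equal_scores_go_middle(self, caplog):
        with caplog.at_level("WARNING"):
            split = tertile_split({f"s{i}": 5.0 for i in range(5)})
        assert set(split.assignment.values()) == {"middle"}

    def test_ties_at_cut_go_middle(self):
        scores = {"a": 1.0, "b": 2.0, "c": 2.0, "d": 2.0, "e": 2.0, "f": 3.0}
        split = tertile_split(scores)
        assert split.assignment["a"] == "low" or split.assignment["a"] == "middle"
        for s in "bcde":
            assert split.assignment[s] == "middle"

    def test_large_pool_produces_near_equal_thirds(self):
        rng = np.random.default_rng(23)
        scores = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=399))}
        split = tertile_split(scores)
        sizes = [len(split.members(c)) for c in ("low", "middle", "high")]
        assert sum(sizes) == 399
        for size in sizes:
            assert abs(size - 133) <= 2  # continuous scores: ties are rare

    def test_requires_three_samples(self):
        with pytest.raises(UndefinedStatisticError):
            tertile_split({"a": 1.0, "b": 2.0})


class TestTertileOr:
    @staticmethod
    def _make(a_high, a_low, b_high, b_low):
        assignment, groups = {}, {}
        idx = 0
        for grp, cat, n in [("A", "high", a_high), ("A", "low", a_low),
                            ("B", "high", b_high), ("B", "low", b_low)]:
            for _ in range(n):
                sid = f"s{idx}"; idx += 1
                assignment[sid] = cat
                groups[sid] = grp
        from tgskit.compare import TertileSplit
        return TertileSplit(0.0, 1.0, assignment), groups

    def test_hand_arithmetic(self):
        split, groups = self._make(10, 5, 5, 10)
        res = tertile_or(split, groups, "A", "B")
        assert res.or_value == pytest.approx(4.0)
        assert res.ci_low < 4.0 < res.ci_high
        assert not res.corrected

    def test_symmetric_table_is_exactly_one(self):
        split, groups = self._make(7, 7, 7, 7)
        assert tertile_or(split, groups, "A", "B").or_value == 1.0

    def test_group_swap_inverts_or_and_ci(self):
        split, groups = self._make(12, 4, 6, 9)
        ab = tertile_or(split, groups, "A", "B")
        ba = tertile_or(split, groups, "B", "A")
        assert ba.or_value == pytest.approx(1.0 / ab.or_value, rel=1e-12)
        assert ba.ci_low == pytest.approx(1.0 / ab.ci_high, rel=1e-12)
        assert ba.ci_high == pytest.approx(1.0 / ab.ci_low, rel=1e-12)

    def test_woolf_ci_hand_check(self):
        split, groups = self._make(10, 5, 5, 10)
        res = tertile_or(split, groups, "A", "B")
        se = math.sqrt(1 / 10 + 1 / 5 + 1 / 5 + 1 / 10)
        z = stats.norm.ppf(0.975)
        assert res.ci_low == pytest.approx(math.exp(math.log(4.0) - z * se), rel=1e-12)
        assert res.ci_high == pytest.approx(math.exp(math.log(4.0) + z * se), rel=1e-12)

    def test_zero_cell_triggers_haldane_anscombe(self):
        split, groups = self._make(8, 0, 4, 6)
        res = tertile_or(split, groups, "A", "B")
        assert res.corrected
        assert res.or_value == pytest.approx((8.5 * 6.5) / (0.5 * 4.5), rel=1e-12)
        assert res.ci_low <= res.or_value <= res.ci_high

    def test_wider_alpha_narrows_ci(self):
        split, groups = self._make(10, 5, 5, 10)
        wide = tertile_or(split, groups, "A", "B", alpha=0.01)
        narrow = tertile_or(split, groups, "A", "B", alpha=0.10)
        assert wide.ci_low < narrow.ci_low and wide.ci_high > narrow.ci_high

    def test_group_absent_from_extremes_is_undefined(self):
        split, groups = self._make(5, 5, 0, 0)
        with pytest.raises(UndefinedStatisticError, match="'B'"):
            tertile_or(split, groups, "A", "B")

    def test_middle_third_excluded_from_table(self):
        split, groups = self._make(6, 3, 4, 5)
        split.assignment["extra"] = "middle"
        groups["extra"] = "A"
        res = tertile_or(split, groups, "A", "B")
        assert (res.a_high + res.a_low, res.b_high + res.b_low) == (9, 9)


def test_compare_groups_assembles_all_pairs():
    rng = np.random.default_rng(29)
    vals = {g: rng.normal(size=20) for g in ("a", "b", "c")}
    res = compare_groups(vals, score_field="tgs")
    assert {(t.group_a, t.group_b) for t in res.pairwise} == {
        ("a", "b"), ("a", "c"), ("b", "c")}
    assert res.omnibus.df2 == 57
    assert len(res.groups) == 3
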