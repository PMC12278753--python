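"""Association statistics against brute-force oracles and worked tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import hypergeom
from scipy.stats import t as t_dist

from lipotrace.stats import (
    assign_quintiles,
    focus_quintile_size,
    goal_attainment,
    mann_whitney,
    odds_ratio,
    r_squared,
    spearman,
    stratified_analysis,
)

# ---------------------------------------------------------------------------
# independent oracles


def rank_average(values):
    """Average ranks (1-based) computed by brute force."""
    values = np.asarray(values, dtype=float)
    ranks = np.empty(len(values))
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x, y):
    """Rank-then-Pearson with the asymptotic t-based p-value."""
    rx, ry = rank_average(x), rank_average(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))
    n = len(rx)
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    return rho, float(2 * t_dist.sf(abs(t), n - 2))


def fisher_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    n1, k_total, n = a + b, a + c, a + b + c + d
    rv = hypergeom(n, k_total, n1)
    lo, hi = max(0, n1 + k_total - n), min(n1, k_total)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(k) for k in range(lo, hi + 1)
                     if rv.pmf(k) <= p_obs * (1 + 1e-9)))


def mann_whitney_oracle(a, b):
    """Exact two-sided U-test p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = rank_average(pooled)
    u_obs = float(np.sum(ranks[:na]) - na * (na + 1) / 2)
    mean_u = na * len(b) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        u = float(np.sum(ranks[list(idx)]) - na * (na + 1) / 2)
        count += abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9
        total += 1
    return count / total


# ---------------------------------------------------------------------------


class TestSpearman:
    def test_perfect_monotone_association(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_worked_rank_example(self):
        # d = (-1, 1, -1, 1, 0): rho = 1 - 6*4 / (5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for n in (5, 10, 25, 50):
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            rho, p = spearman(x, y)
            rho_o, p_o = spearman_oracle(x, y)
            assert rho == pytest.approx(rho_o, abs=1e-12)
            assert p == pytest.approx(p_o, rel=1e-9)

    def test_ties_use_average_ranks(self):
        x = [1, 1, 2, 3, 4, 4]
        y = [2, 3, 3, 5, 8, 8]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y)[0], abs=1e-12)

    def test_constant_vector_flagged_undefined(self):
        with pytest.warns(UserWarning):
            rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho)

    def test_requires_four_pairs(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


class TestRSquared:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        assert r_squared(x, 2 * x) == pytest.approx(1.0)

    def test_orthogonal_sample(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])  # empirically uncorrelated
        assert r_squared(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_square_of_constructed_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=2000)
        y = 0.4 * x + np.sqrt(1 - 0.16) * rng.normal(size=2000)
        assert r_squared(x, y) == pytest.approx(0.16, abs=0.04)


class TestMannWhitney:
    def test_identical_groups(self):
        u, p = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_fully_separated_tiny_groups(self):
        # all a < all b with 3 vs 3: U = 0, exact p = 2 / C(6,3) = 0.1
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=6)
        u_ab, p_ab = mann_whitney(a, b)
        u_ba, p_ba = mann_whitney(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba)

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(6):
            a = rng.normal(size=5)
            b = rng.normal(0.8, 1.0, size=5)
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(mann_whitney_oracle(a, b), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestQuintiles:
    @pytest.mark.parametrize("n, expected",
                             [(135, 27), (134, 27), (133, 27), (131, 27), (39, 8)])
    def test_focus_quintile_sizes_from_figure_legends(self, n, expected):
        assert focus_quintile_size(n) == expected
        q = assign_quintiles(pd.Series(np.random.default_rng(n).normal(size=n)))
        assert int(q["is_lowest"].sum()) == expected
        assert int(q["is_highest"].sum()) == expected

    def test_quintiles_partition_all_subjects(self):
        for n in range(39, 136, 7):
            q = assign_quintiles(pd.Series(np.random.default_rng(n).normal(size=n)))
            sizes = q["quintile"].value_counts()
            assert sizes.sum() == n
            assert set(sizes.index) == {"Q1", "Q2", "Q3", "Q4", "Q5"}
            k = focus_quintile_size(n)
            assert sizes["Q1"] == k and sizes["Q5"] == k

    def test_ties_broken_by_stable_input_order(self):
        s = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0], index=list("abcde"))
        q = assign_quintiles(s)
        assert q.loc["a", "is_lowest"] and not q.loc["b", "is_lowest"]

    def test_small_or_missing_input_rejected(self):
        with pytest.raises(ValueError):
            assign_quintiles(pd.Series([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError):
            assign_quintiles(pd.Series([1.0, 2.0, np.nan, 4.0, 5.0]))


class TestOddsRatio:
    def test_balanced_table(self):
        res = odds_ratio([[1, 1], [1, 1]])
        assert res.or_value == pytest.approx(1.0)
        assert not res.is_estimated
        # CI symmetric about 1 in log space
        assert res.ci95[0] * res.ci95[1] == pytest.approx(1.0)

    def test_reciprocal_and_transpose_identities(self):
        t = [[7, 20], [65, 39]]
        res = odds_ratio(t)
        flipped = odds_ratio([[20, 7], [39, 65]])
        assert res.or_value * flipped.or_value == pytest.approx(1.0)
        transposed = odds_ratio([[7, 65], [20, 39]])
        assert transposed.or_value == pytest.approx(res.or_value)

    def test_zero_cell_triggers_haldane_anscombe(self):
        res = odds_ratio([[8, 0], [16, 15]])
        assert res.is_estimated
        assert res.or_value == pytest.approx(8.5 * 15.5 / (0.5 * 16.5))

    def test_fisher_p_matches_enumeration_on_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() == 0 or t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            res = odds_ratio(t.tolist())
            assert 0 < res.fisher_p <= 1
            assert res.fisher_p == pytest.approx(fisher_oracle(t.tolist()), rel=1e-6)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            odds_ratio([[1, -2], [3, 4]])


class TestGoalAttainment:
    @pytest.mark.parametrize("ldl, goal, expected",
                             [(2.49, 2.5, True), (2.50, 2.5, False), (1.79, 1.8, True)])
    def test_strict_threshold(self, ldl, goal, expected):
        assert goal_attainment(ldl, goal) is expected

    def test_vector_with_missing(self):
        out = goal_attainment(pd.Series([2.4, np.nan, 2.6]), 2.5)
        assert out[0] is np.True_ or out[0] == True  # noqa: E712
        assert pd.isna(out[1])


class TestStratifiedAnalysis:
    @staticmethod
    def _fixture(n, n_focus_yes, n_rest_yes, group="statin"):
        """Group of n with ordered scores; outcome planted per stratum."""
        k = focus_quintile_size(n)
        outcome = np.zeros(n, dtype=bool)
        outcome[:n_focus_yes] = True                     # within lowest quintile
        outcome[k:k + n_rest_yes] = True                 # within the rest
        scores = pd.DataFrame({"LT": np.arange(n, dtype=float)})
        return scores, pd.Series(outcome), pd.Series([group] * n)

    def test_equal_rates_give_or_near_one(self):
        scores, outcome, groups = self._fixture(100, 10, 40)  # both strata at 50%
        res = stratified_analysis(scores, outcome, groups)
        low = res[res["focus"] == "lowest"].iloc[0]
        assert low["or_value"] == pytest.approx(1.0, abs=0.05)

    def test_statin_goal_attainment_fixture(self):
        # 131 subjects, 72 achievers, 7 of them in the lowest-LT quintile (27)
        scores, outcome, groups = self._fixture(131, 7, 65)
        res = stratified_analysis(scores, outcome, groups)
        low = res[res["focus"] == "lowest"].iloc[0]
        assert (low["a"], low["b"], low["c"], low["d"]) == (7, 20, 65, 39)
        assert round(low["or_value"], 2) == 0.21
        assert low["fisher_p"] < 0.001

    def test_his_cvd_event_fixture(self):
        # 39 subjects, 5 events: 3 in the lowest-LiM quintile (8), 2 in the rest
        scores, outcome, groups = self._fixture(39, 3, 2, group="HIS")
        res = stratified_analysis(scores.rename(columns={"LT": "LiM"}), outcome, groups)
        low = res[res["focus"] == "lowest"].iloc[0]
        assert (low["a"], low["b"], low["c"], low["d"]) == (3, 5, 2, 29)
        assert low["or_value"] == pytest.approx(8.7)
        assert low["fisher_p"] == pytest.approx(0.049, abs=0.0005)

    def test_quintiles_assigned_within_each_group(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"LT": np.concatenate([rng.normal(size=40),
                                                     rng.normal(5.0, 1.0, size=60)])})
        outcome = pd.Series(rng.random(100) < 0.5)
        groups = pd.Series(["a"] * 40 + ["b"] * 60)
        res = stratified_analysis(scores, outcome, groups)
        n_focus = res.set_index(["group", "focus"])["n_focus"]
        assert n_focus[("a", "lowest")] == focus_quintile_size(40)
        assert n_focus[("b", "lowest")] == focus_quintile_size(60)
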