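"""Unit and property tests for the cohort statistics module."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from equomgs import stats as S


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Integer-arithmetic hypergeometric enumeration (probability-mass rule)."""
    n, r1, c1 = a + b + c + d, a + b, a + c

    def ways(x):
        return math.comb(r1, x) * math.comb(n - r1, c1 - x)

    p_obs = ways(a)
    total = sum(
        ways(x)
        for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if ways(x) <= p_obs
    )
    return total / math.comb(n, c1)


def test_fisher_degenerate_margin_gives_p_one():
    assert S.fisher_exact([[0, 10], [0, 10]]).p_value == 1.0


def test_fisher_diagonal_table_enumeration():
    # all 10 successes split 5/5: 2 of C(10,5)=252 equally extreme tables
    r = S.fisher_exact([[5, 0], [0, 5]])
    assert r.p_value == pytest.approx(2 / 252, abs=1e-12)


def test_fisher_matches_enumeration_oracle_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(300):
        a, b, c, d = rng.integers(0, 13, size=4)
        if a + b + c + d == 0:
            continue
        mine = S.fisher_exact([[a, b], [c, d]]).p_value
        oracle = fisher_enumeration_oracle(int(a), int(b), int(c), int(d))
        assert mine == pytest.approx(oracle, abs=1e-9), (a, b, c, d)


def test_fisher_reconstructed_cirrhosis_prevalence_counts():
    # detected counts from 57% of 102 healthy and 16% of 112 cirrhotic samples
    a, c = round(0.57 * 102), round(0.16 * 112)
    table = [[a, 102 - a], [c, 112 - c]]
    r = S.fisher_exact(table)
    assert r.p_value == pytest.approx(
        fisher_enumeration_oracle(*[x for row in table for x in row]), rel=1e-9
    )
    assert r.p_value < 1e-8  # strongly significant depletion


def test_fisher_rejects_bad_input():
    with pytest.raises(ValueError):
        S.fisher_exact([[0, 0], [0, 0]])
    with pytest.raises(ValueError):
        S.fisher_exact([[1, 2, 3], [4, 5, 6]])


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "table,stat,df",
    [
        ([[25, 25], [25, 25]], 0.0, 1),
        ([[50, 0], [0, 50]], 100.0, 1),
        ([[10, 20, 30, 40], [10, 20, 30, 40]], 0.0, 3),
    ],
)
def test_chi_squared_known_tables(table, stat, df):
    r = S.chi_squared(table)
    assert r.statistic == pytest.approx(stat, abs=1e-9)
    assert r.df == df
    if stat == 0.0:
        assert r.p_value == pytest.approx(1.0)


def test_chi_squared_matches_scipy():
    rng = np.random.default_rng(1)
    for _ in range(50):
        t = rng.integers(1, 40, size=(rng.integers(2, 4), rng.integers(2, 5)))
        r = S.chi_squared(t)
        stat, p, df, _ = sps.chi2_contingency(t, correction=False)
        assert r.statistic == pytest.approx(stat, rel=1e-10)
        assert r.p_value == pytest.approx(p, rel=1e-10)
        assert r.df == df


def test_chi_squared_zero_margin_errors():
    with pytest.raises(ValueError):
        S.chi_squared([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# Mann-Whitney / AUC
# ---------------------------------------------------------------------------

def brute_force_auc(x, y):
    x, y = np.asarray(x), np.asarray(y)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return (gt + 0.5 * eq) / (len(x) * len(y))


def test_auc_examples():
    assert S.mann_whitney_auc([1, 2, 3], [2, 3, 4]).effect == pytest.approx(2 / 9)
    assert S.mann_whitney_auc([5, 6], [1, 2]).effect == 1.0
    assert S.mann_whitney_auc([1, 2, 3], [1, 2, 3]).effect == 0.5


def test_auc_equals_brute_force_pair_counting():
    rng = np.random.default_rng(2)
    for _ in range(200):
        x = rng.integers(0, 6, size=rng.integers(1, 30)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(1, 30)).astype(float)
        assert S.mann_whitney_auc(x, y).effect == pytest.approx(
            brute_force_auc(x, y), abs=1e-12
        )


@settings(derandomize=True, max_examples=100)
@given(
    x=st.lists(st.integers(0, 5), min_size=1, max_size=20),
    y=st.lists(st.integers(0, 5), min_size=1, max_size=20),
)
def test_auc_complementarity(x, y):
    assert S.mann_whitney_auc(x, y).effect + S.mann_whitney_auc(y, x).effect == pytest.approx(1.0)


def test_mwu_p_matches_scipy_exact_and_asymptotic():
    rng = np.random.default_rng(3)
    for _ in range(50):
        x = rng.normal(size=rng.integers(3, 9))
        y = rng.normal(size=rng.integers(3, 9))
        assert S.mann_whitney_auc(x, y).p_value == pytest.approx(
            sps.mannwhitneyu(x, y, method="exact").pvalue, abs=1e-10
        )
    for _ in range(20):
        x = rng.normal(size=40)
        y = rng.normal(size=50) + 0.3
        assert S.mann_whitney_auc(x, y).p_value == pytest.approx(
            sps.mannwhitneyu(x, y, method="asymptotic").pvalue, rel=1e-9
        )


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kruskal_hand_example():
    r = S.kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
    assert r.statistic == pytest.approx(7.2)
    assert r.df == 2


def test_kruskal_matches_scipy_with_ties():
    rng = np.random.default_rng(4)
    for _ in range(30):
        g = {k: rng.integers(0, 10, size=rng.integers(4, 15)).astype(float) for k in "abc"}
        r = S.kruskal_wallis(g)
        ref = sps.kruskal(*g.values())
        assert r.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)


def test_kruskal_two_groups_consistent_with_mwu():
    rng = np.random.default_rng(5)
    x = rng.normal(size=40)
    y = rng.normal(size=40) + 0.6
    p_kw = S.kruskal_wallis({"x": x, "y": y}).p_value
    p_mw = S.mann_whitney_auc(x, y).p_value
    assert p_kw == pytest.approx(p_mw, rel=0.1)


def test_kruskal_all_identical_errors():
    with pytest.raises(ValueError):
        S.kruskal_wallis({"a": [1.0, 1.0], "b": [1.0, 1.0]})


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def test_ks_d_examples():
    assert S.ks_two_sample([1, 2, 3], [1, 2, 3]).statistic == 0.0
    assert S.ks_two_sample([1, 2, 3], [1, 2, 3]).p_value == 1.0
    assert S.ks_two_sample([1, 2], [10, 11]).statistic == 1.0
    assert S.ks_two_sample([1, 2], [1.5, 2.5]).statistic == pytest.approx(0.5)


def test_ks_matches_scipy_exact():
    rng = np.random.default_rng(6)
    for _ in range(80):
        x = rng.normal(size=rng.integers(3, 40))
        y = rng.normal(size=rng.integers(3, 40))
        r = S.ks_two_sample(x, y)
        ref = sps.ks_2samp(x, y, method="exact")
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-8)


def test_ks_asymptotic_reasonable_for_large_samples():
    rng = np.random.default_rng(7)
    x = rng.normal(size=300)
    y = rng.normal(size=400)
    r = S.ks_two_sample(x, y)
    ref = sps.ks_2samp(x, y, method="asymp")
    assert r.statistic == pytest.approx(ref.statistic, abs=1e-12)
    assert r.p_value == pytest.approx(ref.pvalue, rel=0.2)


def test_ks_vectorised_d_matches_scalar():
    rng = np.random.default_rng(8)
    values = rng.normal(size=(40, 10))
    is_x = np.arange(40) < 18
    d_cols = S.ks_d_columns(values, is_x)
    for j in range(10):
        assert d_cols[j] == pytest.approx(
            S.ks_two_sample(values[is_x, j], values[~is_x, j]).statistic, abs=1e-12
        )


# ---------------------------------------------------------------------------
# prevalence and the screen
# ---------------------------------------------------------------------------

def test_prevalence_by_group_counts():
    det = pd.Series([True, True, False, True, False], index=list("abcde"))
    grp = pd.Series(["h", "h", "h", "c", "c"], index=list("abcde"))
    prev, table = S.prevalence_by_group(det, grp, ["h", "c"])
    assert prev["h"] == pytest.approx(2 / 3)
    assert prev["c"] == pytest.approx(1 / 2)
    assert table.loc["detected", "h"] == 2
    assert table.sum().sum() == 5


def test_prevalence_empty_group_errors():
    det = pd.Series([True], index=["a"])
    grp = pd.Series(["h"], index=["a"])
    with pytest.raises(ValueError):
        S.prevalence_by_group(det, grp, ["h", "c"])


def test_screen_constant_columns_pass_nothing():
    profiles = pd.DataFrame(np.ones((20, 5)), columns=[f"m{i}" for i in range(5)])
    labels = pd.Series(["a"] * 10 + ["b"] * 10, index=profiles.index)
    result = S.screen_discriminating_mgs(profiles, labels)
    assert not result["passed"].any()


def test_screen_recovers_planted_shifts():
    rng = np.random.default_rng(9)
    n, n_mgs, n_planted = 30, 200, 10
    values = rng.normal(size=(2 * n, n_mgs)) * 0.5
    values[:n, :n_planted] += 1.0  # one-decade shift in the first class
    profiles = pd.DataFrame(values, columns=[f"m{i}" for i in range(n_mgs)])
    labels = pd.Series(["case"] * n + ["control"] * n, index=profiles.index)
    result = S.screen_discriminating_mgs(profiles, labels)
    planted = result.index[:n_planted]
    assert result.loc[planted, "passed"].sum() >= 9
    assert result.loc[result.index[n_planted:], "passed"].sum() <= 2
    # BH never decreases a p-value
    assert (result["wilcoxon_p_adj"] >= result["wilcoxon_p"] - 1e-15).all()
    assert (result["ks_p_adj"] >= result["ks_p"] - 1e-15).all()


def test_screen_null_false_positive_rate_without_adjustment():
    rng = np.random.default_rng(10)
    rates = []
    for _ in range(10):
        values = rng.normal(size=(60, 400))
        profiles = pd.DataFrame(values, columns=[f"m{i}" for i in range(400)])
        labels = pd.Series(["a"] * 30 + ["b"] * 30, index=profiles.index)
        res = S.screen_discriminating_mgs(profiles, labels, adjust="none")
        rates.append((res["wilcoxon_p"] < 0.05).mean())
    # ~5% Wilcoxon false positives expected without correction
    assert 0.03 < np.mean(rates) < 0.07


def test_screen_rejects_non_binary_labels():
    profiles = pd.DataFrame(np.random.default_rng(0).normal(size=(9, 2)))
    labels = pd.Series(["a", "b", "c"] * 3, index=profiles.index)
    with pytest.raises(ValueError):
        S.screen_discriminating_mgs(profiles, labels)


# ---------------------------------------------------------------------------
# clinical formulas
# ---------------------------------------------------------------------------

def test_homa_ir():
    assert S.homa_ir(22.5, 1.0) == pytest.approx(1.0)
    assert S.homa_ir(5.0, 9.0) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        S.homa_ir(0.0, 5.0)


def test_friedewald_ldl():
    assert S.friedewald_ldl(5.2, 1.0, 2.2) == pytest.approx(3.2)
    assert S.friedewald_ldl(3.0, 3.0, 0.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        S.friedewald_ldl(5.0, 1.0, 4.6)
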