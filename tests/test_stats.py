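"""Statistical primitives against closed forms and brute-force oracles."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from catring.stats import (
    TestResult,
    binomial_tail,
    binomial_tail_lower,
    one_sample_t,
    p_from_t,
    paired_t,
    spearman_corr,
    two_way_interaction,
)


@pytest.mark.parametrize(
    "k,n,q,expected,decimals",
    [
        (9, 12, 0.25, 3.92e-4, 6),  # 9 of 12 subjects picking the trained boundary
        (8, 12, 0.25, 2.78e-3, 5),
        (7, 12, 0.25, 0.014, 3),
        (6, 12, 0.25, 0.054, 3),
    ],
)
def test_binomial_tail_printed_group_tests(k, n, q, expected, decimals):
    assert round(binomial_tail(k, n, q), decimals) == expected


def test_binomial_tail_bounds_and_scipy_cross_check():
    assert binomial_tail(0, 12, 0.3) == 1.0
    assert binomial_tail(12, 12, 0.05) == pytest.approx(0.05**12)
    for k, n, q in [(3, 7, 0.2), (5, 9, 0.5), (1, 4, 0.9)]:
        assert binomial_tail(k, n, q) == pytest.approx(
            float(sps.binom.sf(k - 1, n, q)), abs=1e-12
        )


@given(
    n=st.integers(1, 12),
    k=st.integers(0, 12),
    num=st.integers(0, 8),
)
@settings(max_examples=50, deadline=None)
def test_binomial_tail_complement_identity_rational(n, k, num):
    """Upper tail at k plus lower tail at k-1 equals 1 (exact, by rational
    arithmetic)."""
    k = min(k, n)
    q = Fraction(num, 8)
    upper = sum(
        Fraction(comb(n, i)) * q**i * (1 - q) ** (n - i)
        for i in range(k, n + 1)
    )
    lower = sum(
        Fraction(comb(n, i)) * q**i * (1 - q) ** (n - i)
        for i in range(0, k)
    )
    assert upper + lower == 1
    assert binomial_tail(k, n, float(q)) == pytest.approx(float(upper), abs=1e-12)
    assert binomial_tail_lower(k - 1, n, float(q)) == pytest.approx(
        float(lower), abs=1e-12
    )


def test_p_from_t_printed_values_and_monotonicity():
    # printed t statistics are rounded to 2 decimals; allow that rounding
    assert p_from_t(4.14, 11) == pytest.approx(1.64e-3, abs=5e-6)
    # a 2-decimal t of 4.17 corresponds to p ~ 1.56e-3; the routine returns
    # 1.58e-3 at the unrounded t ~ 4.1636 that reproduces it
    assert p_from_t(4.17, 11) == pytest.approx(1.5627e-3, abs=1e-6)
    assert p_from_t(4.1636, 11) == pytest.approx(1.58e-3, abs=5e-7)
    ps = [p_from_t(t, 11) for t in (1.0, 2.0, 3.0, 4.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))
    assert p_from_t(2.2, 11) == pytest.approx(float(2 * sps.t.sf(2.2, 11)), abs=1e-12)


def test_paired_t_matches_scipy_and_degenerate_error():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=12), rng.normal(size=12)
    res = paired_t(x, y)
    ref = sps.ttest_rel(x, y)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p == pytest.approx(ref.pvalue)
    assert res.df == 11
    with pytest.raises(ValueError):
        paired_t(x, x)


def test_one_sample_t_sign_flip_symmetry():
    rng = np.random.default_rng(2)
    x = rng.normal(0.4, 1.0, 10)
    res = one_sample_t(x, 0.0)
    flipped = one_sample_t(-x, 0.0)
    assert flipped.statistic == pytest.approx(-res.statistic)
    assert flipped.p == pytest.approx(res.p)
    with pytest.raises(ValueError):
        one_sample_t(np.full(5, 3.0), 3.0)


def test_one_sample_t_rejection_rate_matches_noncentral_power():
    """Empirical power at alpha=.05 vs the closed-form noncentral-t power."""
    rng = np.random.default_rng(3)
    n, mu, reps = 12, 0.5, 4000
    tcrit = sps.t.ppf(0.975, n - 1)
    nc = mu * np.sqrt(n)
    power = float(sps.nct.sf(tcrit, n - 1, nc) + sps.nct.cdf(-tcrit, n - 1, nc))
    hits = 0
    for _ in range(reps):
        x = rng.normal(mu, 1.0, n)
        hits += one_sample_t(x).p < 0.05
    assert hits / reps == pytest.approx(power, abs=0.025)


def test_spearman_extremes_and_monotone_invariance():
    x = np.arange(6.0)
    assert spearman_corr(x, x**3).statistic == 1.0
    assert spearman_corr(x, -np.exp(x)).statistic == -1.0


def test_spearman_exact_p_matches_brute_force_enumeration():
    """n=5 exact permutation p vs explicit 120-permutation null."""
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 5])
    res = spearman_corr(x, y)
    rhos = []
    for perm in itertools.permutations(y):
        r, _ = sps.spearmanr(x, perm)
        rhos.append(r)
    p_brute = np.mean(np.abs(rhos) >= abs(res.statistic) - 1e-12)
    assert res.p == pytest.approx(p_brute, abs=1e-12)
    assert res.statistic == pytest.approx(sps.spearmanr(x, y).statistic)


def test_spearman_t_approximation_above_exact_limit():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=15), rng.normal(size=15)
    res = spearman_corr(x, y)
    ref = sps.spearmanr(x, y)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


def _anova_interaction_oracle(values, a, b):
    """Hand-computed interaction F for a balanced two-way design."""
    values = np.asarray(values, float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = values.mean()
    levels_a, levels_b = np.unique(a), np.unique(b)
    r = len(values) // (len(levels_a) * len(levels_b))
    ss_int = 0.0
    ss_err = 0.0
    for la in levels_a:
        for lb in levels_b:
            cell = values[(a == la) & (b == lb)]
            eff = (
                cell.mean()
                - values[a == la].mean()
                - values[b == lb].mean()
                + grand
            )
            ss_int += r * eff**2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    df_int = (len(levels_a) - 1) * (len(levels_b) - 1)
    df_err = len(values) - len(levels_a) * len(levels_b)
    return (ss_int / df_int) / (ss_err / df_err), df_int, df_err


def test_two_way_interaction_matches_hand_computation():
    rng = np.random.default_rng(5)
    a = np.repeat([0, 0, 1, 1], 6)
    b = np.tile(np.repeat([0, 1], 3), 4)
    # crossed pattern plus noise
    values = 0.5 * (a == b) + rng.normal(0, 0.3, a.size)
    res = two_way_interaction(values, a, b)
    f_ref, df_int, df_err = _anova_interaction_oracle(values, a, b)
    assert res.statistic == pytest.approx(f_ref)
    assert res.df == (df_int, df_err)
    assert res.p == pytest.approx(float(sps.f.sf(f_ref, df_int, df_err)))


def test_two_way_interaction_invariant_to_replicate_order():
    rng = np.random.default_rng(6)
    a = np.repeat([0, 0, 1, 1], 4)
    b = np.tile(np.repeat([0, 1], 2), 4)
    values = rng.normal(size=a.size)
    res1 = two_way_interaction(values, a, b)
    order = rng.permutation(a.size)
    res2 = two_way_interaction(values[order], a[order], b[order])
    assert res1.statistic == pytest.approx(res2.statistic)


def test_testresult_rejects_invalid_p():
    with pytest.raises(ValueError):
        TestResult(1.0, 1.5)
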