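from itertools import combinations, product

import numpy as np
import pytest
from scipy.stats import rankdata

from meanet import AnalysisError, ValidationError, mann_whitney_exact, wilcoxon_signed_rank_exact
from meanet.stats import _mw_null_counts


def mw_p_enumeration(x, y):
    """Exact two-sided p by enumerating every group assignment of the
    pooled observations: tail probabilities of U_x, doubled smaller
    tail, capped at 1."""
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = rankdata(pooled)
    stats = []
    for grp in combinations(range(n1 + n2), n1):
        r1 = ranks[list(grp)].sum()
        stats.append(r1 - n1 * (n1 + 1) / 2)
    stats = np.asarray(stats)
    ux = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    lo = np.mean(stats <= ux + 1e-9)
    hi = np.mean(stats >= ux - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def wsr_p_enumeration(d):
    """Exact two-sided p over all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = len(d)
    w_all = [np.sum(ranks[list(mask)]) if mask else 0.0
             for k in range(n + 1) for mask in combinations(range(n), k)]
    w_all = np.asarray(w_all)
    lo = np.mean(w_all <= w_plus + 1e-9)
    hi = np.mean(w_all >= w_plus - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def test_mann_whitney_complete_separation_n5():
    """Complete separation at n1 = n2 = 5: U = 0, exact two-sided
    p = 2/252 ~ 0.008, and effect size r = 0.83."""
    res = mann_whitney_exact([1.2, 1.5, 1.7, 2.0, 2.3], [5.1, 5.4, 6.0, 6.6, 7.2])
    assert res.statistic == 0
    assert res.exact
    assert round(res.p_value, 3) == 0.008
    assert round(res.effect_size_r, 2) == 0.83


def test_mann_whitney_trivial_cases():
    res = mann_whitney_exact([1.0], [2.0])
    assert res.p_value == 1.0  # only two orderings
    # U at the null center -> Z = 0, r = 0
    res = mann_whitney_exact([1, 4], [2, 3])
    assert res.statistic == 2 == 2 * 2 / 2
    assert res.z == 0.0 and res.effect_size_r == 0.0


def test_mw_null_counts_match_enumeration_all_small_n():
    for n1 in range(1, 6):
        for n2 in range(1, 6):
            if n1 + n2 > 10:
                continue
            counts = _mw_null_counts(n1, n2)
            ranks = np.arange(1, n1 + n2 + 1)
            brute = np.zeros(n1 * n2 + 1, dtype=int)
            for grp in combinations(range(n1 + n2), n1):
                u = int(ranks[list(grp)].sum() - n1 * (n1 + 1) // 2)
                brute[u] += 1
            assert list(counts) == list(brute)


def test_mw_exact_p_matches_enumeration_random_samples():
    rng = np.random.default_rng(0)
    for n1, n2 in [(2, 3), (3, 4), (4, 4), (5, 5), (2, 8)]:
        x = rng.normal(size=n1)
        y = rng.normal(loc=0.5, size=n2)
        res = mann_whitney_exact(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(mw_p_enumeration(x, y), abs=1e-12)


def test_mw_matches_scipy_exact_without_ties():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(1)
    for _ in range(20):
        n1, n2 = rng.integers(2, 9, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        res = mann_whitney_exact(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)


def test_mw_ties_fall_back_to_permutation_null():
    res = mann_whitney_exact([1, 2, 2, 3], [2, 3, 3, 4])
    assert res.exact and "permutation" in res.note
    assert 0 < res.p_value <= 1


def test_mw_validation_and_monotonicity():
    with pytest.raises(ValidationError):
        mann_whitney_exact([], [1.0])
    # fully tied data: the test is maximally non-significant
    tied = mann_whitney_exact([1.0, 1.0], [1.0, 1.0])
    assert tied.p_value == 1.0 and tied.effect_size_r == 0.0
    # p decreases as U moves away from its null mean at fixed n
    counts = _mw_null_counts(4, 4)
    total = sum(counts)
    ps = []
    for u in range(8, -1, -1):  # from center to extreme
        lo = sum(counts[: u + 1]) / total
        hi = sum(counts[u:]) / total
        ps.append(min(1.0, 2 * min(lo, hi)))
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_wilcoxon_three_same_sign_pairs():
    """Three same-sign differences: W = 0, exact p = 2/8 = 0.25, and
    the Z-based effect size r = 0.93."""
    res = wilcoxon_signed_rank_exact([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
    assert res.statistic == 0
    assert res.exact
    assert res.p_value == pytest.approx(0.25)
    assert round(res.effect_size_r, 2) == 0.93


def test_wilcoxon_four_same_sign_and_balanced():
    res = wilcoxon_signed_rank_exact([1.0, 2.0, 3.0, 4.0])
    assert res.p_value == pytest.approx(0.125)  # 2/2^4
    balanced = wilcoxon_signed_rank_exact([1.0, 4.0, -2.0, -3.0])
    assert balanced.statistic == 4 * 5 / 4  # W at the null mean
    assert balanced.z == 0.0 and balanced.effect_size_r == 0.0


def test_wilcoxon_zero_differences_dropped():
    res = wilcoxon_signed_rank_exact([1.0, 2.0, 5.0], [1.0, 1.0, 1.0])
    assert res.n1 == 2
    with pytest.raises(AnalysisError):
        wilcoxon_signed_rank_exact([1.0, 1.0], [1.0, 1.0])


def test_wsr_exact_p_matches_enumeration():
    rng = np.random.default_rng(2)
    for n in (3, 5, 8, 10):
        d = rng.normal(loc=0.4, size=n)
        res = wilcoxon_signed_rank_exact(d)
        assert res.exact
        assert res.p_value == pytest.approx(wsr_p_enumeration(d), abs=1e-12)


def test_wsr_matches_scipy_exact():
    from scipy.stats import wilcoxon

    rng = np.random.default_rng(3)
    for _ in range(15):
        n = int(rng.integers(4, 12))
        d = rng.normal(loc=0.3, size=n)
        res = wilcoxon_signed_rank_exact(d)
        ref = wilcoxon(d, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)


def test_null_rejection_rate_matches_achievable_level():
    """Simulated continuous null, n1 = n2 = 5: the empirical rejection
    rate at alpha = 0.05 stays within binomial 99% bounds of the exact
    achievable level."""
    from scipy.stats import binom

    counts = _mw_null_counts(5, 5)
    total = sum(counts)
    p_of_u = {}
    for u in range(26):
        lo = sum(counts[: u + 1]) / total
        hi = sum(counts[u:]) / total
        p_of_u[u] = min(1.0, 2 * min(lo, hi))
    achievable = sum(
        counts[u] for u in range(26) if p_of_u[min(u, 25 - u)] <= 0.05
    ) / total

    rng = np.random.default_rng(4)
    n_rep = 10_000
    data = rng.normal(size=(n_rep, 10))
    ranks = rankdata(data, axis=1)
    u_x = ranks[:, :5].sum(axis=1) - 15
    u = np.minimum(u_x, 25 - u_x)
    rej = np.mean([p_of_u[int(v)] <= 0.05 for v in u])
    lo, hi = binom.ppf([0.005, 0.995], n_rep, achievable) / n_rep
    assert lo <= rej <= hi
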