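"""Statistics engine vs enumeration oracles and library cross-checks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from pmmetab import stats

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the package's DP/combination branches)
# ---------------------------------------------------------------------------

def brute_wilcoxon_p(d):
    """Two-sided exact p for W=min(W+,W-) over all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_obs = min(w_plus, ranks.sum() - w_plus)
    count = 0
    n = len(d)
    for signs in itertools.product([1, -1], repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s > 0)
        if min(wp, ranks.sum() - wp) <= w_obs + 1e-9:
            count += 1
    return count / 2 ** n


def brute_mannwhitney_p(a, b):
    """Exact p for U=min(Ua,Ub) over all group assignments of the pool."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na, nb = len(a), len(b)
    ua = ranks[:na].sum() - na * (na + 1) / 2
    u_obs = min(ua, na * nb - ua)
    count = total = 0
    for combo in itertools.combinations(range(na + nb), na):
        u = ranks[list(combo)].sum() - na * (na + 1) / 2
        if min(u, na * nb - u) <= u_obs + 1e-9:
            count += 1
        total += 1
    return count / total


def brute_kruskal_p(groups):
    """Exact p for H over all distinct group assignments (small N)."""
    sizes = [len(g) for g in groups]
    values = np.concatenate(groups)
    h_obs = sps.kruskal(*groups).statistic

    def h_of(assignment):
        gs, start = [], 0
        for size in sizes:
            gs.append(values[list(assignment[start : start + size])])
            start += size
        return sps.kruskal(*gs).statistic

    count = total = 0
    indices = list(range(len(values)))

    def assignments(remaining, sizes_left):
        if len(sizes_left) == 1:
            yield list(remaining)
            return
        for combo in itertools.combinations(range(len(remaining)), sizes_left[0]):
            chosen = [remaining[i] for i in combo]
            rest = [remaining[i] for i in range(len(remaining))
                    if i not in set(combo)]
            for tail in assignments(rest, sizes_left[1:]):
                yield chosen + tail

    for assignment in assignments(indices, sizes):
        if h_of(assignment) >= h_obs - 1e-9:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_wilcoxon_degenerate_identical():
    res = stats.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.degenerate and res.pvalue == 1.0 and res.n_used == 0


def test_wilcoxon_single_negative_among_positives():
    """d=[1,2,3,4,5,-6]: exact p from the 64-pattern enumeration."""
    x = np.array([1.0, 2, 3, 4, 5, 0])
    y = np.array([0.0, 0, 0, 0, 0, 6])
    res = stats.wilcoxon_signed_rank(x, y)
    assert res.pvalue == pytest.approx(brute_wilcoxon_p(x - y), abs=1e-12)
    assert res.statistic == 6.0  # W- = rank of the lone negative


@pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
@pytest.mark.parametrize("rep", range(4))
def test_wilcoxon_exact_matches_enumeration(n, rep):
    """Exhaustive check against sign-pattern enumeration, ties included."""
    rng = np.random.default_rng(100 * n + rep)
    d = rng.integers(-4, 5, size=n).astype(float)
    if np.all(d == 0):
        d[0] = 1.0
    res = stats.wilcoxon_signed_rank(d, np.zeros(n))
    assert res.pvalue == pytest.approx(brute_wilcoxon_p(d), abs=1e-12)


def test_wilcoxon_matches_scipy_exact_without_ties():
    rng = np.random.default_rng(5)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    ours = stats.wilcoxon_signed_rank(x, y)
    ref = sps.wilcoxon(x, y, mode="exact")
    assert ours.statistic == pytest.approx(ref.statistic)
    assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_exact_and_normal_agree_at_crossover():
    rng = np.random.default_rng(17)
    x = rng.normal(0.3, 1.0, size=25)
    exact = stats.wilcoxon_signed_rank(x, np.zeros(25), exact_max_n=25)
    approx = stats.wilcoxon_signed_rank(x, np.zeros(25), exact_max_n=0)
    assert approx.pvalue == pytest.approx(exact.pvalue, abs=0.01)


def test_wilcoxon_length_mismatch():
    with pytest.raises(ValueError):
        stats.wilcoxon_signed_rank([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mannwhitney_identical_multisets():
    res = stats.mann_whitney([1.0, 2, 3], [1.0, 2, 3])
    assert res.pvalue == 1.0


def test_mannwhitney_complete_separation():
    res = stats.mann_whitney([1.0, 2, 3], [4.0, 5, 6])
    assert res.statistic == 0.0
    assert res.pvalue == pytest.approx(2.0 / 20.0)


@pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (4, 3), (4, 4)])
@pytest.mark.parametrize("rep", range(3))
def test_mannwhitney_exact_matches_enumeration(na, nb, rep):
    rng = np.random.default_rng(50 * na + 7 * nb + rep)
    a = rng.integers(0, 5, size=na).astype(float)
    b = rng.integers(0, 5, size=nb).astype(float)
    if len(set(np.concatenate([a, b]))) == 1:
        a[0] += 1
    res = stats.mann_whitney(a, b)
    assert res.pvalue == pytest.approx(brute_mannwhitney_p(a, b), abs=1e-12)


def test_mannwhitney_approx_matches_scipy():
    rng = np.random.default_rng(2)
    a = rng.normal(size=30)
    b = rng.normal(0.5, 1.0, size=25)
    ours = stats.mann_whitney(a, b)
    ref = sps.mannwhitneyu(a, b, method="asymptotic")
    assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


def test_mannwhitney_empty_group():
    with pytest.raises(ValueError):
        stats.mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kruskal_identical_groups_degenerate():
    res = stats.kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
    assert res.degenerate and res.pvalue == 1.0 and res.statistic == 0.0


def test_kruskal_hand_formula_and_enumeration():
    groups = [[1.0, 2, 3], [4.0, 5, 6], [7.0, 8, 9]]
    res = stats.kruskal_wallis(groups)
    assert res.statistic == pytest.approx(7.2)
    exact = stats.kruskal_wallis(groups, exact=True)
    assert exact.pvalue == pytest.approx(brute_kruskal_p(groups), abs=1e-12)


def test_kruskal_matches_scipy_with_ties():
    rng = np.random.default_rng(9)
    groups = [rng.integers(0, 6, size=n).astype(float) for n in (12, 15, 9, 11)]
    ours = stats.kruskal_wallis(groups)
    ref = sps.kruskal(*groups)
    assert ours.statistic == pytest.approx(ref.statistic)
    assert ours.pvalue == pytest.approx(ref.pvalue)


def test_kruskal_empty_group_rejected():
    with pytest.raises(ValueError):
        stats.kruskal_wallis([[1.0], []])


# ---------------------------------------------------------------------------
# Dunn's test
# ---------------------------------------------------------------------------

def test_dunn_direct_formula_oracle():
    """Three groups [1,2],[3,4],[5,6]: rank means 1.5, 3.5, 5.5; N=6."""
    z, p = stats.dunns_test([[1.0, 2], [3.0, 4], [5.0, 6]])
    var_term = 6 * 7 / 12.0  # no ties
    expected_z12 = (1.5 - 3.5) / math.sqrt(var_term * (0.5 + 0.5))
    expected_z13 = (1.5 - 5.5) / math.sqrt(var_term * (0.5 + 0.5))
    assert z[0, 1] == pytest.approx(expected_z12)
    assert z[0, 2] == pytest.approx(expected_z13)
    assert p[0, 1] == pytest.approx(2 * sps.norm.sf(abs(expected_z12)))


def test_dunn_identical_groups():
    z, p = stats.dunns_test([[1.0, 2, 3], [1.0, 2, 3]])
    assert z[0, 1] == pytest.approx(0.0)
    assert p[0, 1] == 1.0


def test_dunn_relabel_symmetry():
    groups = [[1.0, 5, 2], [4.0, 6], [9.0, 3, 8]]
    z1, _ = stats.dunns_test(groups)
    z2, _ = stats.dunns_test(groups[::-1])
    assert np.allclose(np.sort(np.abs(z1[np.triu_indices(3, 1)])),
                       np.sort(np.abs(z2[np.triu_indices(3, 1)])))


# ---------------------------------------------------------------------------
# Holm adjustment
# ---------------------------------------------------------------------------

def test_holm_examples():
    assert stats.holm_adjust([0.2]) == pytest.approx([0.2])
    assert stats.holm_adjust([0.01, 0.04, 0.03]) == pytest.approx(
        [0.03, 0.06, 0.06]
    )


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
@settings(deadline=None, derandomize=True)
def test_holm_matches_statsmodels_and_bounds(p):
    ours = stats.holm_adjust(p)
    ref = multipletests(p, method="holm")[1]
    assert np.allclose(ours, ref, atol=1e-12)
    assert np.all(ours >= np.asarray(p) - 1e-15)
    assert np.all(ours <= 1.0)


def test_holm_rejects_out_of_range():
    with pytest.raises(ValueError):
        stats.holm_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# Spearman, median CI, codes
# ---------------------------------------------------------------------------

def test_spearman_perfect_and_example():
    x = [1.0, 2, 3, 4, 5]
    assert stats.spearman(x, x).rho == pytest.approx(1.0)
    assert stats.spearman(x, [-v for v in x]).rho == pytest.approx(-1.0)
    res = stats.spearman(x, [2.0, 1, 4, 3, 5])
    assert res.rho == pytest.approx(0.8)
    ref = sps.spearmanr(x, [2.0, 1, 4, 3, 5])
    assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


def test_spearman_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        stats.spearman([1.0, 1, 1], [1.0, 2, 3])


def test_median_ci_order_statistics():
    res = stats.median_ci(np.arange(1.0, 101.0))
    assert res.median == pytest.approx(50.5)
    assert (res.low, res.high) == (40.0, 61.0)


def test_median_ci_constant_and_nested():
    const = stats.median_ci([5.0] * 20)
    assert (const.low, const.high) == (5.0, 5.0)
    rng = np.random.default_rng(1)
    v = rng.normal(size=60)
    ci95 = stats.median_ci(v, 0.95)
    ci99 = stats.median_ci(v, 0.99)
    assert ci99.low <= ci95.low <= ci95.high <= ci99.high


def test_median_ci_small_n_degenerates():
    res = stats.median_ci([1.0, 2.0, 3.0])
    assert res.degenerate and (res.low, res.high) == (1.0, 3.0)


def test_significance_codes():
    assert stats.significance_code(0.5) == "ns"
    assert stats.significance_code(0.04) == "*"
    assert stats.significance_code(0.009) == "**"
    assert stats.significance_code(0.0009) == "***"
    with pytest.raises(ValueError):
        stats.significance_code(1.5)
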