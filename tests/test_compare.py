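"""Exact tests against enumeration oracles; ECDF, correlation, summaries."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from plaquedyn.compare import (
    ecdf_difference,
    fisher_exact,
    mann_whitney,
    size_speed_correlation,
    summarize,
)
from plaquedyn.tracking import CountSeries


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def mw_exact_p_oracle(x, y):
    """Two-sided Mann–Whitney p by enumeration of all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    obs_u = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    n2 = len(y)
    mu = n1 * n2 / 2
    obs_dev = abs(obs_u - mu)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(
            1 for xi in xs for yj in ys if xi == yj
        )
        total += 1
        if abs(u - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def fisher_2x2_p_oracle(table):
    """Two-sided Fisher p: sum of hypergeometric probabilities ≤ observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa):
        return comb(c1, aa, exact=True) * comb(n - c1, r1 - aa, exact=True) / comb(n, r1, exact=True)

    p_obs = prob(a)
    return sum(prob(aa) for aa in range(max(0, r1 - (n - c1)), min(r1, c1) + 1) if prob(aa) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# Mann–Whitney
# ---------------------------------------------------------------------------


def test_mann_whitney_exact_small_sample():
    res = mann_whitney([1, 2], [3, 4])
    assert res.exact
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1 / 3, abs=1e-12)
    assert res.p_value == pytest.approx(mw_exact_p_oracle([1, 2], [3, 4]), abs=1e-12)


def test_mann_whitney_identical_samples():
    x = list(range(20))
    res = mann_whitney(x, x)
    assert res.p_value == pytest.approx(1.0, abs=1e-6)


def test_mann_whitney_exact_matches_oracle_random_cases():
    rng = np.random.default_rng(1)
    for _ in range(10):
        x = rng.permutation(24)[:5].tolist()
        y = rng.permutation(60)[:6] + 100
        y = (y + rng.random(6)).tolist()  # no ties with x
        res = mann_whitney(x, y)
        if res.exact:
            assert res.p_value == pytest.approx(mw_exact_p_oracle(x, y), abs=1e-9)


def test_mann_whitney_normal_approx_close_to_permutation():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 200)
    y = rng.normal(0.2, 1, 200)
    res = mann_whitney(x, y)
    # permutation oracle
    pooled = np.concatenate([x, y])
    obs = res.statistic
    mu = len(x) * len(y) / 2
    count = 0
    n_perm = 10_000
    for _ in range(n_perm):
        rng.shuffle(pooled)
        xs, ys = pooled[:200], pooled[200:]
        u = (xs[:, None] > ys[None, :]).sum() + 0.5 * (xs[:, None] == ys[None, :]).sum()
        if abs(u - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    assert abs(res.p_value - count / n_perm) < 0.02


def test_mann_whitney_monotone_transform_invariance():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 30)
    y = rng.normal(1, 1, 25)
    p1 = mann_whitney(x, y).p_value
    p2 = mann_whitney(np.exp(x), np.exp(y)).p_value
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_mann_whitney_nucleus_median_mode():
    x = [[1, 2, 3], [2, 3, 4]]
    y = [[10, 11, 12], [11, 12, 13]]
    res = mann_whitney(x, y, mode="nucleus_median")
    assert res.n1 == 2 and res.n2 == 2
    with pytest.raises(ValueError):
        mann_whitney([], [1])


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------


def test_fisher_2x2_worked_example():
    res = fisher_exact([[2, 0], [0, 2]])
    assert res.exact
    assert res.p_value == pytest.approx(1 / 3, abs=1e-12)


def test_fisher_identical_rows_p_one():
    res = fisher_exact([[5, 5], [5, 5]])
    assert res.p_value == pytest.approx(1.0, abs=1e-12)


def test_fisher_2x2_matches_oracle_all_small_tables():
    """Agreement with full enumeration to 1e-12 on all 2×2 tables, N ≤ 20."""
    checked = 0
    for a in range(6):
        for b in range(6):
            for c in range(6):
                for d in range(6):
                    if 0 < a + b and 0 < c + d and 0 < a + c and 0 < b + d and a + b + c + d <= 20:
                        p = fisher_exact([[a, b], [c, d]]).p_value
                        assert p == pytest.approx(fisher_2x2_p_oracle([[a, b], [c, d]]), abs=1e-12)
                        checked += 1
    assert checked > 400


def test_fisher_2xk_enumeration_matches_scipy_2x2_embedding():
    # a 2×3 table with an empty-ish column reduces to 2×2 behaviour
    res = fisher_exact([[3, 2, 1], [1, 2, 3]])
    assert res.exact and 0 <= res.p_value <= 1
    # symmetric table → p = 1
    sym = fisher_exact([[2, 2, 2], [2, 2, 2]])
    assert sym.p_value == pytest.approx(1.0, abs=1e-12)


def test_fisher_2xk_monte_carlo_close_to_enum():
    table = [[8, 6, 4], [2, 4, 6]]  # N = 30: enumeration feasible
    exact = fisher_exact(table)
    mc = fisher_exact(table, max_enumeration_n=10, n_monte_carlo=200_000, seed=1)
    assert exact.exact and not mc.exact
    assert abs(exact.p_value - mc.p_value) < 0.01


def test_fisher_rejects_bad_input():
    with pytest.raises(ValueError):
        fisher_exact([[1.5, 2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact([[0, 0], [1, 1]])


# ---------------------------------------------------------------------------
# ECDF difference and correlation
# ---------------------------------------------------------------------------


def test_ecdf_difference_worked_example():
    assert ecdf_difference([10, 20], [20, 30], [25]) == pytest.approx([0.5])


def test_ecdf_difference_identical_samples_zero():
    x = [1.0, 2.0, 5.0]
    assert np.allclose(ecdf_difference(x, x, np.linspace(0, 6, 20)), 0.0)


def test_ecdf_difference_bounds_and_supports():
    rng = np.random.default_rng(0)
    f = rng.uniform(10, 50, 40)
    p = rng.uniform(30, 90, 50)
    grid = np.linspace(-10, 120, 200)
    diff = ecdf_difference(f, p, grid)
    assert np.all(diff >= -1 - 1e-12) and np.all(diff <= 1 + 1e-12)
    assert np.allclose(diff[grid < min(f.min(), p.min())], 0.0)
    assert np.allclose(diff[grid > max(f.max(), p.max())], 0.0)


def test_size_speed_correlation_perfect_linear():
    df = pd.DataFrame(
        {"area_um2": [1, 2, 3, 4], "speed_nm_s": [10, 20, 30, 40], "morph_class": "focus"}
    )
    out = size_speed_correlation(df)
    assert out["focus"].statistic == pytest.approx(1.0)


def test_size_speed_correlation_constant_errors():
    df = pd.DataFrame({"area_um2": [1, 1, 1], "speed_nm_s": [1, 2, 3], "morph_class": "focus"})
    with pytest.raises(ValueError, match="constant"):
        size_speed_correlation(df)


def test_size_speed_correlation_null_simulation():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(
        {
            "area_um2": rng.uniform(0.5, 2.0, 500),
            "speed_nm_s": rng.rayleigh(50, 500),
            "morph_class": "focus",
        }
    )
    assert abs(size_speed_correlation(df)["focus"].statistic) < 0.1


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------


def _cs(values):
    return CountSeries(t_s=np.arange(len(values)) * 5.0, n=values)


def test_summarize_single_nucleus_sd_flag():
    rows = summarize({"wt": [_cs([3, 3, 3])]})
    assert rows[0].avg == 3.0 and rows[0].avg_sd == 0.0 and not rows[0].sd_defined


def test_summarize_two_nuclei_sample_sd():
    rows = summarize({"wt": [_cs([4, 4]), _cs([2, 2])]})
    r = rows[0]
    assert r.avg == pytest.approx(3.0)
    assert r.avg_sd == pytest.approx(math.sqrt(2), abs=1e-9)  # sample SD of {4, 2}
    assert r.n_nuclei == 2


def test_summarize_empty_group_errors():
    with pytest.raises(ValueError):
        summarize({"wt": []})
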