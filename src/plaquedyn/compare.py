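"""Genotype/condition comparison statistics.

Nonparametric comparisons mirroring the original analysis: two-sided
Mann–Whitney U on speed or arc samples, Fisher's exact test on
fusion-event and coalescence class tables (2×2 exact; 2×K by full
enumeration for small tables, Monte Carlo otherwise), ECDF subtraction
for the focus-vs-patch speed comparison, size–speed Pearson correlation
per morphology class, and genotype summary rows (across-nucleus mean ±
sample SD of per-nucleus count statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from plaquedyn.tracking import CountSeries, nucleus_summary

__all__ = [
    "TestResult",
    "SummaryRow",
    "mann_whitney",
    "fisher_exact",
    "ecdf_difference",
    "size_speed_correlation",
    "summarize",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    exact: bool


@dataclass(frozen=True)
class SummaryRow:
    """One genotype × zone row of the aggregate-count summary table."""

    genotype: str
    zone: str
    avg: float
    avg_sd: float
    min: float
    min_sd: float
    max: float
    max_sd: float
    n_nuclei: int
    sd_defined: bool = True


# ---------------------------------------------------------------------------
# Mann–Whitney
# ---------------------------------------------------------------------------


def mann_whitney(x, y, mode: str = "pooled") -> TestResult:
    """Two-sided Mann–Whitney U test.

    ``mode='pooled'`` treats ``x`` and ``y`` as flat samples (pooled
    per-step values); ``mode='nucleus_median'`` expects lists of
    per-nucleus arrays and compares their medians, for analyses where
    the nucleus is the unit of replication.  Exact enumeration is used
    when n1+n2 ≤ 12 with no ties, the tie-corrected normal approximation
    otherwise.
    """
    if mode == "nucleus_median":
        x = [float(np.median(np.asarray(a, dtype=float))) for a in x]
        y = [float(np.median(np.asarray(a, dtype=float))) for a in y]
    elif mode != "pooled":
        raise ValueError("mode must be 'pooled' or 'nucleus_median'")
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if len(xa) == 0 or len(ya) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([xa, ya]))) < len(xa) + len(ya)
    exact = (len(xa) + len(ya) <= 12) and not has_ties
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="mann_whitney_exact" if exact else "mann_whitney_normal",
        n1=len(xa),
        n2=len(ya),
        exact=exact,
    )


# ---------------------------------------------------------------------------
# Fisher's exact
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray, col_sums: np.ndarray, n: int, n1: int) -> float:
    """Log multivariate-hypergeometric probability of row-1 counts."""
    lp = -math.lgamma(n + 1) + math.lgamma(n1 + 1) + math.lgamma(n - n1 + 1)
    for a, cs in zip(table, col_sums):
        lp += (
            math.lgamma(cs + 1)
            - math.lgamma(a + 1)
            - math.lgamma(cs - a + 1)
        )
    return lp


def _enumerate_2xk(col_sums: np.ndarray, n1: int):
    """Yield all row-1 count vectors compatible with the margins."""
    k = len(col_sums)

    def rec(j: int, remaining: int, prefix: list[int]):
        if j == k - 1:
            if 0 <= remaining <= col_sums[j]:
                yield prefix + [remaining]
            return
        rest_capacity = int(col_sums[j + 1 :].sum())
        lo = max(0, remaining - rest_capacity)
        hi = min(col_sums[j], remaining)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, prefix + [a])

    yield from rec(0, n1, [])


def fisher_exact(
    table,
    max_enumeration_n: int = 30,
    n_monte_carlo: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Fisher's exact test on a 2×K contingency table.

    Two-sided p-value: the sum of probabilities (under fixed margins) of
    all tables no more probable than the observed one.  2×2 tables and
    2×K tables with total N ≤ ``max_enumeration_n`` are solved by full
    enumeration; larger 2×K tables by Monte Carlo sampling of tables
    from the margin-conditional null (``exact=False``).
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2×K")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("each margin must have at least one non-zero total")

    col_sums = t.sum(axis=0)
    n = int(t.sum())
    n1 = int(t[0].sum())
    obs_lp = _log_table_prob(t[0], col_sums, n, n1)
    tol = 1e-9  # relative tolerance on log-probabilities

    if t.shape[1] == 2:
        stat, p = stats.fisher_exact(t, alternative="two-sided")
        return TestResult(float(stat), float(p), "fisher_exact_2x2", n1, n - n1, True)

    if n <= max_enumeration_n:
        total = 0.0
        for row1 in _enumerate_2xk(col_sums, n1):
            lp = _log_table_prob(np.array(row1), col_sums, n, n1)
            if lp <= obs_lp + tol:
                total += math.exp(lp)
        return TestResult(
            math.nan, min(1.0, total), "fisher_exact_2xk_enum", n1, n - n1, True
        )

    # Monte Carlo: sample row-1 counts from the multivariate hypergeometric
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col_sums, n1, size=n_monte_carlo)
    lps = np.array([_log_table_prob(d, col_sums, n, n1) for d in draws])
    p = float((np.sum(lps <= obs_lp + tol) + 1) / (n_monte_carlo + 1))
    return TestResult(math.nan, p, "fisher_2xk_monte_carlo", n1, n - n1, False)


# ---------------------------------------------------------------------------
# ECDF subtraction and correlation
# ---------------------------------------------------------------------------


def ecdf_difference(foci_speeds, patch_speeds, grid) -> np.ndarray:
    """ECDF(foci) − ECDF(patches) evaluated on ``grid``.

    Positive values mean foci are slower (more of their mass is below
    that speed) than patches.
    """
    f = np.sort(np.asarray(foci_speeds, dtype=float).ravel())
    p = np.sort(np.asarray(patch_speeds, dtype=float).ravel())
    g = np.asarray(grid, dtype=float).ravel()
    if len(f) == 0 or len(p) == 0:
        raise ValueError("both samples must be non-empty")
    if len(g) == 0:
        raise ValueError("grid must be non-empty")
    ecdf_f = np.searchsorted(f, g, side="right") / len(f)
    ecdf_p = np.searchsorted(p, g, side="right") / len(p)
    return ecdf_f - ecdf_p


def size_speed_correlation(df: pd.DataFrame) -> dict[str, TestResult]:
    """Pearson correlation between aggregate area and speed per class.

    ``df`` needs columns area_um2, speed_nm_s, morph_class.  Raises on a
    class with fewer than 3 pairs or constant input (undefined
    correlation).
    """
    out: dict[str, TestResult] = {}
    for klass, group in df.groupby("morph_class"):
        a = group["area_um2"].to_numpy(dtype=float)
        s = group["speed_nm_s"].to_numpy(dtype=float)
        if len(a) < 3:
            raise ValueError(f"class {klass!r} has fewer than 3 pairs")
        if np.std(a) == 0 or np.std(s) == 0:
            raise ValueError(f"correlation undefined for constant input in class {klass!r}")
        r, p = stats.pearsonr(a, s)
        out[str(klass)] = TestResult(float(r), float(p), "pearson", len(a), len(a), False)
    return out


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------


def summarize(
    genotype_runs: dict[str, list[CountSeries]],
    zones: dict[str, str] | None = None,
) -> list[SummaryRow]:
    """Across-nucleus summary rows of per-nucleus count statistics.

    For each genotype, per-nucleus (mean, min, max) aggregate counts are
    averaged across nuclei with the sample (n−1) SD.  With a single
    nucleus the SD is undefined and reported as 0 with
    ``sd_defined=False``.
    """
    rows: list[SummaryRow] = []
    for genotype, series_list in genotype_runs.items():
        if len(series_list) == 0:
            raise ValueError(f"genotype {genotype!r} has no nuclei")
        stats_ = np.array([nucleus_summary(s) for s in series_list])  # (n, 3)
        n = len(series_list)
        means = stats_.mean(axis=0)
        if n > 1:
            sds = stats_.std(axis=0, ddof=1)
            sd_defined = True
        else:
            sds = np.zeros(3)
            sd_defined = False
        rows.append(
            SummaryRow(
                genotype=genotype,
                zone=(zones or {}).get(genotype, "entire"),
                avg=float(means[0]),
                avg_sd=float(sds[0]),
                min=float(means[1]),
                min_sd=float(sds[1]),
                max=float(means[2]),
                max_sd=float(sds[2]),
                n_nuclei=n,
                sd_defined=sd_defined,
            )
        )
    return rows


def summary_to_dataframe(rows: list[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
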