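"""The statistical comparisons used for cohort analysis.

Two-sided unpaired t-tests use the pooled-variance (Student) form, which
is what reproduces the reference summary-statistics comparisons; paired
t-tests, two-sample Kolmogorov-Smirnov tests and Fisher's exact test
(2x2 and RxC) round out the set. No multiple-testing adjustment is applied
anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy import stats as sps


@dataclass
class SummaryStat:
    mean: float
    sd: float  # sample standard deviation
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def t_test_from_summary(a: SummaryStat, b: SummaryStat) -> TestResult:
    """Two-sided pooled-variance (Student) t-test from summary statistics."""
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if pooled_var == 0:
        # degenerate: both groups constant
        if a.mean == b.mean:
            return TestResult(0.0, 1.0, "t (pooled)", df=df)
        return TestResult(float("inf"), 0.0, "t (pooled)", df=df)
    se = np.sqrt(pooled_var * (1 / a.n + 1 / b.n))
    t = (a.mean - b.mean) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(p), "t (pooled)", df=df)


def t_test_samples(x, y, paired: bool = False) -> TestResult:
    """Two-sided t-test on raw samples (pooled unpaired, or paired)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs equal-length samples")
        if x.size < 2:
            raise ValueError("need n >= 2")
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            p = 1.0 if d.mean() == 0 else 0.0
            t = 0.0 if d.mean() == 0 else float("inf")
            return TestResult(t, p, "t (paired)", df=x.size - 1)
        t = d.mean() / (sd / np.sqrt(d.size))
        p = 2 * sps.t.sf(abs(t), d.size - 1)
        return TestResult(float(t), float(p), "t (paired)", df=d.size - 1)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 in each group")
    return t_test_from_summary(
        SummaryStat(float(x.mean()), float(x.std(ddof=1)), int(x.size)),
        SummaryStat(float(y.mean()), float(y.std(ddof=1)), int(y.size)),
    )


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y|, with ties handled by the ECDF jumps."""
    xs, ys = np.sort(x), np.sort(y)
    grid = np.unique(np.concatenate([xs, ys]))
    fx = np.searchsorted(xs, grid, side="right") / xs.size
    fy = np.searchsorted(ys, grid, side="right") / ys.size
    return float(np.abs(fx - fy).max())


def ks_two_sample(x, y) -> TestResult:
    """Two-sided two-sample KS test.

    For very small samples (n+m <= 18) the p-value is computed by full
    permutation enumeration, which stays exact in the presence of ties;
    mid-size samples (each <= 25) use the exact no-ties distribution and
    larger ones the asymptotic approximation.
    """
    from itertools import combinations

    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test needs non-empty samples")
    n, m = x.size, y.size
    if n + m <= 18:
        d_obs = _ks_statistic(x, y)
        pooled = np.concatenate([x, y])
        hits = 0
        total = 0
        for chosen in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(chosen)] = True
            hits += _ks_statistic(pooled[mask], pooled[~mask]) >= d_obs - 1e-12
            total += 1
        return TestResult(d_obs, hits / total, "KS (two-sample, permutation)")
    method = "exact" if max(n, m) <= 25 else "asymp"
    res = sps.ks_2samp(x, y, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "KS (two-sample)")


def _table_log_prob(table: np.ndarray, log_fact_margins: float) -> float:
    return log_fact_margins - sum(lgamma(v + 1) for v in table.ravel())


def _enumerate_rxc(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    R, C = len(row_sums), len(col_sums)

    def fill_row(r, remaining_cols, rows):
        if r == R - 1:
            last = tuple(remaining_cols)
            if sum(last) == row_sums[r]:
                yield rows + [last]
            return
        target = row_sums[r]

        def compositions(c, left, current):
            if c == C - 1:
                if left <= remaining_cols[c]:
                    yield current + [left]
                return
            for v in range(min(left, remaining_cols[c]) + 1):
                yield from compositions(c + 1, left - v, current + [v])

        for comp in compositions(0, target, []):
            yield from fill_row(
                r + 1,
                [rc - v for rc, v in zip(remaining_cols, comp)],
                rows + [tuple(comp)],
            )

    yield from fill_row(0, list(col_sums), [])


def fisher_exact(table) -> TestResult:
    """Two-sided exact test of independence on an RxC count table.

    2x2 tables use hypergeometric tail summation (tables as or more
    extreme by probability); larger tables are fully enumerated over all
    tables with the observed margins.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError("degenerate table: a margin is zero")
    if t.shape == (2, 2):
        odds, p = sps.fisher_exact(t, alternative="two-sided")
        return TestResult(float(odds), float(p), "Fisher exact (2x2)")

    n = int(t.sum())
    log_fact_margins = (
        sum(lgamma(v + 1) for v in row_sums)
        + sum(lgamma(v + 1) for v in col_sums)
        - lgamma(n + 1)
    )
    lp_obs = _table_log_prob(t, log_fact_margins)
    cutoff = lp_obs + 1e-7  # tolerance for ties in table probability
    p = 0.0
    for tab in _enumerate_rxc(row_sums.tolist(), col_sums.tolist()):
        lp = _table_log_prob(np.array(tab), log_fact_margins)
        if lp <= cutoff:
            p += float(np.exp(lp))
    return TestResult(float("nan"), min(p, 1.0), "Fisher exact (RxC)")
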