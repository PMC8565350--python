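"""Condition-level inference: trend tests, rank-sum comparisons, pooling.

Trends across an experimental variable (salt concentration, membrane
cholesterol, handle count, ...) are assessed with an ordinary least squares
slope and its t-based 95% confidence interval; "increasing" / "decreasing"
calls require the whole CI to lie on one side of zero.  Pairwise condition
comparisons use the two-sided Wilcoxon/Mann-Whitney rank-sum test, exact for
small tie-free samples and tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TrendResult:
    variable: str
    slope: float
    intercept: float
    ci95: tuple[float, float]
    n: int
    decision: str  # increasing | decreasing | no_trend
    pearson_r: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float  # rank sum of group a
    p_value: float
    mean_difference: float
    method: str


@dataclass(frozen=True)
class PooledStats:
    mean: float
    sd: float
    n: int


def _ols_line(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    """Slope/intercept with t-based CI from the normal equations.

    Degenerate y (zero residual variance) yields a zero-width CI.
    """
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0:
        raise ValueError("all x values are equal; slope undefined")
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - (intercept + slope * x)
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    se = np.sqrt(s2 / sxx)
    tcrit = sps.t.ppf(1 - alpha / 2, dof) if dof > 0 else np.inf
    half = tcrit * se if se > 0 else 0.0
    return slope, intercept, (slope - half, slope + half), se


def trend_test(
    x: Sequence[float],
    y: Sequence[float],
    variable: str = "x",
) -> TrendResult:
    """OLS trend of a per-image metric against an experimental variable.

    Requires at least three distinct x values.  The decision is
    ``increasing`` iff the 95% CI lower bound is > 0, ``decreasing`` iff the
    upper bound is < 0, otherwise ``no_trend``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if np.unique(x).size < 3:
        raise ValueError("trend test requires >= 3 distinct x values")
    slope, intercept, ci, _ = _ols_line(x, y)
    if ci[0] > 0:
        decision = "increasing"
    elif ci[1] < 0:
        decision = "decreasing"
    else:
        decision = "no_trend"
    sy = y.std()
    r = float(np.corrcoef(x, y)[0, 1]) if sy > 0 else float("nan")
    return TrendResult(
        variable=variable,
        slope=slope,
        intercept=intercept,
        ci95=ci,
        n=int(x.size),
        decision=decision,
        pearson_r=r,
    )


def rank_sum_compare(
    a: Sequence[float],
    b: Sequence[float],
    name_a: str = "a",
    name_b: str = "b",
) -> PairwiseComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two groups.

    Exact enumeration is used when both groups have <= 20 observations and
    the pooled data are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction.  If every pooled value is
    identical the groups are indistinguishable and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 values")
    pooled = np.concatenate([a, b])
    rank_sum_a = float(sps.rankdata(pooled)[: a.size].sum())
    mean_diff = float(a.mean() - b.mean())
    if np.ptp(pooled) == 0:
        return PairwiseComparison(name_a, name_b, rank_sum_a, 1.0, mean_diff, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 20 and b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return PairwiseComparison(
        group_a=name_a,
        group_b=name_b,
        statistic=rank_sum_a,
        p_value=float(min(1.0, res.pvalue)),
        mean_difference=mean_diff,
        method=method,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values (optional output)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def pooled_summary(
    values_by_condition: Mapping[str, Sequence[float]] | pd.DataFrame,
    exclude: Callable[[str], bool] | Iterable[str] | None = None,
) -> PooledStats:
    """Mean, SD and n of per-image values pooled across conditions.

    Parameters
    ----------
    values_by_condition
        Either a mapping ``condition_id -> per-image values`` or a DataFrame
        with ``condition_id`` and ``C_R`` columns.
    exclude
        Condition ids to drop, as a predicate or an iterable of names
        (e.g. to exclude a denaturing pH condition from the pooled figure).

    SD is the sample SD (ddof=1); 0 for a single pooled value.
    """
    if isinstance(values_by_condition, pd.DataFrame):
        grouped = {
            str(cid): np.asarray(sub["C_R"], dtype=float)
            for cid, sub in values_by_condition.groupby("condition_id")
        }
    else:
        grouped = {str(k): np.asarray(v, dtype=float) for k, v in values_by_condition.items()}
    if exclude is None:
        pred = lambda cid: False  # noqa: E731
    elif callable(exclude):
        pred = exclude
    else:
        dropped = set(exclude)
        pred = lambda cid: cid in dropped  # noqa: E731
    kept = [v for cid, v in grouped.items() if not pred(cid)]
    if not kept or sum(v.size for v in kept) == 0:
        raise ValueError("no values remain after exclusion")
    pooled = np.concatenate(kept)
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    return PooledStats(mean=float(pooled.mean()), sd=sd, n=int(pooled.size))
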